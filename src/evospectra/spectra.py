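"""Spectral statistics of community matrices.

Closed-form eigenvalue theory for the two-species web (one producer,
one consumer) together with ensemble statistics used to compare evolved
spectra with random-matrix baselines: purely-real fractions, real-part
distributions scaled to start at -1, and two-dimensional histograms in
the complex plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from evospectra.constants import PURELY_REAL_TOL
from evospectra.web import FoodWeb

__all__ = [
    "TwoSpeciesSystem",
    "SpectrumSet",
    "two_species_eigenvalues",
    "two_species_web",
    "purely_real_condition",
    "purely_real_fraction",
    "real_part_distribution",
    "scale_to_minus_one",
    "complex_plane_histogram",
    "pool_spectra",
    "spectrum_set_from_history",
]


@dataclass
class TwoSpeciesSystem:
    """One producer (decay ``alpha1``) and one consumer (decay ``alpha2``).

    The consumer's "consumption rate" ``beta_eta`` is the product of
    efficiency and interaction strength; the community matrix (and
    hence both eigenvalues) depends on beta and eta only through it.
    ``gamma = alpha2 / (1 - alpha1/k)`` is the inverse intrinsic fitness
    of the web; feasibility requires ``beta_eta > gamma``.
    """

    alpha1: float
    alpha2: float
    beta_eta: float
    k: float = 1.0

    def __post_init__(self) -> None:
        if self.k <= self.alpha1:
            raise ValueError("need k > alpha1 for a feasible producer")

    @property
    def gamma(self) -> float:
        return self.alpha2 / (1.0 - self.alpha1 / self.k)

    @property
    def feasible(self) -> bool:
        return self.beta_eta > self.gamma


@dataclass
class SpectrumSet:
    """Eigenvalues grouped by species richness for one source of webs."""

    mode: str
    beta: float | None = None
    eigenvalues_by_richness: dict[int, np.ndarray] = field(default_factory=dict)


def two_species_web(sys: TwoSpeciesSystem) -> FoodWeb:
    """Equivalent explicit food web (with beta = 1, eta = beta_eta)."""
    eta = np.zeros((2, 2))
    eta[1, 0] = sys.beta_eta
    s1 = sys.alpha2 / sys.beta_eta
    s2 = (sys.k * (1.0 - s1) - sys.alpha1) / sys.beta_eta
    return FoodWeb(
        ids=[0, 1],
        alpha=[sys.alpha1, sys.alpha2],
        is_producer=[True, False],
        eta=eta,
        biomass=[s1, s2],
        beta=1.0,
        k=sys.k,
    )


def two_species_eigenvalues(sys: TwoSpeciesSystem) -> np.ndarray:
    """Closed-form eigenvalue pair of the two-species community matrix.

    With ``S1* = alpha2 / (beta eta)`` the community matrix has trace
    ``-k S1*`` and determinant ``beta eta S1* (k - alpha1 - k S1*)``;
    the eigenvalues follow from the quadratic characteristic polynomial.
    In the marginal-feasibility limit ``beta_eta -> gamma`` they reduce
    to ``-(k - alpha1)/2 +/- (k - alpha1)/2``, so the larger one is
    exactly zero: two-species webs are always (marginally) stable.  The
    marginal case ``beta_eta == gamma`` is accepted (the consumer sits
    exactly at zero biomass); strictly infeasible systems are rejected.
    """
    if sys.beta_eta < sys.gamma:
        raise ValueError("two-species system is infeasible (beta_eta < gamma)")
    s1 = sys.alpha2 / sys.beta_eta
    trace = -sys.k * s1
    det = sys.beta_eta * s1 * (sys.k - sys.alpha1 - sys.k * s1)
    disc = complex(trace * trace / 4.0 - det)
    root = np.sqrt(disc)
    return np.array([trace / 2.0 + root, trace / 2.0 - root])


def purely_real_condition(sys: TwoSpeciesSystem) -> bool:
    """Whether the two-species eigenvalue pair is purely real.

    Both eigenvalues are real iff
    ``beta_eta <= (gamma + sqrt(gamma**2 + k*gamma)) / 2``:
    consumption must stay moderate relative to the intrinsic fitness of
    the resource (the over-damped regime).  As ``k -> infinity`` the
    bound diverges and every admissible system has real eigenvalues.
    """
    if not sys.feasible:
        raise ValueError("two-species system is infeasible (beta_eta <= gamma)")
    g = sys.gamma
    return sys.beta_eta <= 0.5 * (g + np.sqrt(g * g + sys.k * g))


def purely_real_fraction(eigs: np.ndarray, tol: float = PURELY_REAL_TOL) -> float:
    """Fraction of eigenvalues with |Im| below the tolerance."""
    eigs = np.asarray(eigs)
    if eigs.size == 0:
        raise ValueError("empty spectrum")
    return float(np.mean(np.abs(eigs.imag) < tol))


def scale_to_minus_one(values: np.ndarray) -> np.ndarray:
    """Divide by |min| so the support starts at -1 (idempotent)."""
    values = np.asarray(values, dtype=float)
    m = values.min()
    if m >= 0.0:
        raise ValueError("scaling requires a negative minimum")
    return values / abs(m)


def real_part_distribution(
    eigs: np.ndarray, bins: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Normalised histogram of eigenvalue real parts scaled to start at -1.

    Returns ``(edges, mass)`` with ``len(edges) == bins + 1`` and
    ``mass.sum() == 1``.  Real parts are divided by the magnitude of the
    most negative one, so the support begins at exactly -1; positive
    real parts (unstable eigenvalues) extend the support beyond zero.
    """
    eigs = np.asarray(eigs)
    if eigs.size == 0:
        raise ValueError("empty spectrum")
    scaled = scale_to_minus_one(eigs.real)
    hi = max(scaled.max(), 0.0)
    counts, edges = np.histogram(scaled, bins=bins, range=(-1.0, hi if hi > -1.0 else 0.0))
    return edges, counts / counts.sum()


def complex_plane_histogram(
    eigs: np.ndarray, re_bins: int = 100, im_bins: int = 100
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-dimensional eigenvalue histogram over the complex plane.

    Returns ``(counts, re_edges, im_edges)``; counts are raw (the
    logarithmic colouring of published heat maps is a plotting choice).
    """
    eigs = np.asarray(eigs)
    if eigs.size == 0:
        raise ValueError("empty spectrum")
    counts, re_edges, im_edges = np.histogram2d(eigs.real, eigs.imag, bins=(re_bins, im_bins))
    return counts, re_edges, im_edges


def pool_spectra(sets: list[SpectrumSet]) -> dict[int, np.ndarray]:
    """Pool eigenvalues across spectrum sets (e.g. across beta values)."""
    pooled: dict[int, list[np.ndarray]] = {}
    for s in sets:
        for richness, eigs in s.eigenvalues_by_richness.items():
            pooled.setdefault(richness, []).append(np.asarray(eigs))
    return {r: np.concatenate(chunks) for r, chunks in sorted(pooled.items())}


def spectrum_set_from_history(history, min_richness: int = 1) -> SpectrumSet:
    """Group the recorded spectra of an assembly run by species richness."""
    by_richness: dict[int, list[np.ndarray]] = {}
    for rec in history.recorded_webs:
        if rec.richness >= min_richness:
            by_richness.setdefault(rec.richness, []).append(rec.eigenvalues)
    return SpectrumSet(
        mode=history.config.mode,
        beta=history.config.beta,
        eigenvalues_by_richness={
            r: np.concatenate(chunks) for r, chunks in sorted(by_richness.items())
        },
    )
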