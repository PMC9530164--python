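"""Connectivity-matched random-matrix null ensemble.

Random community matrices with diagonal self-regulation ``d = -1`` and
off-diagonal entries drawn from a standard normal with probability
``p(N) = (N^2 + 21N - 28) / (9N(N-1))``, the expected connectivity of
an omnivorous web of richness N assembled without extinctions.  Their
pooled spectra are uni-modal (approaching the circular law, centred on
``d``) and serve as the null against which the bi-modal spectra of
evolved webs are contrasted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from evospectra.spectra import SpectrumSet

__all__ = ["RandomEnsembleSpec", "connectivity", "sample_matrix", "ensemble_spectrum"]


@dataclass
class RandomEnsembleSpec:
    """Size, diagonal, connectivity and sample count of one ensemble.

    ``connectivity=None`` selects the matched value ``p(size)``.
    """

    size: int
    diagonal: float = -1.0
    connectivity: float | None = None
    samples: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("size must be at least 2")
        if self.samples < 1:
            raise ValueError("samples must be positive")
        if self.connectivity is None:
            self.connectivity = connectivity(self.size)
        if not (0.0 <= self.connectivity <= 1.0):
            raise ValueError("connectivity must lie in [0, 1]")


def connectivity(N: int) -> float:
    """Matched connectivity ``p(N)``, clipped into [0, 1].

    The rational expression can exceed 1 for small N (it equals 1
    exactly at N = 2), hence the defensive clip.
    """
    if N <= 1:
        raise ValueError("connectivity is defined for N > 1")
    p = (N * N + 21 * N - 28) / (9 * N * (N - 1))
    return float(min(p, 1.0))


def sample_matrix(spec: RandomEnsembleSpec, rng: np.random.Generator) -> np.ndarray:
    """One random matrix: diagonal ``d``, thinned standard-normal off-diagonal."""
    N = spec.size
    present = rng.random((N, N)) < spec.connectivity
    values = rng.standard_normal((N, N))
    M = np.where(present, values, 0.0)
    np.fill_diagonal(M, spec.diagonal)
    return M


def ensemble_spectrum(spec: RandomEnsembleSpec) -> SpectrumSet:
    """Pooled eigenvalues of ``spec.samples`` independent matrices."""
    rng = np.random.default_rng(spec.seed)
    eigs = np.concatenate(
        [np.linalg.eigvals(sample_matrix(spec, rng)) for _ in range(spec.samples)]
    )
    return SpectrumSet(mode="random", beta=None, eigenvalues_by_richness={spec.size: eigs})
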