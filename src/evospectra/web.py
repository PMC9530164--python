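"""Food-web state and generalised Lotka-Volterra (GLV) algebra.

A food web couples one implicit basic nutrient source, ``n1`` primary
producers and ``n - n1`` consumers.  Producer per-capita growth follows
logistic competition for the shared nutrient, and consumers gain from
their resources with efficiency ``beta``:

    producers:  dS_i/dt / S_i = k (1 - sum_j producers S_j) - alpha_i
                                - sum_k eta_{ki} S_k
    consumers:  dS_k/dt / S_k = sum_m beta eta_{km} S_m - alpha_k
                                - sum_p eta_{pk} S_p

The right-hand sides are affine in the biomasses, so the interior fixed
point solves a linear system ``R S* = K`` and the community matrix (the
Jacobian at ``S*``) is available in closed form.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from evospectra.constants import (
    COND_LIMIT,
    FEASIBILITY_THRESHOLD,
    STABILITY_TOL,
)

__all__ = [
    "SpeciesParams",
    "FoodWeb",
    "SteadyState",
    "CommunityMatrix",
    "per_capita_growth",
    "assemble_linear_system",
    "steady_state",
    "community_matrix",
    "spectrum",
    "is_stable",
    "trophic_levels",
]


@dataclass
class SpeciesParams:
    """Intrinsic parameters of one species.

    Parameters
    ----------
    decay_rate
        Mortality not caused by consumption (``alpha``), in units of the
        producer growth rate ``k``.
    growth_rate
        Maximal reproduction rate at unlimited nutrient (``k``);
        meaningful for producers only.
    is_producer
        Whether the species feeds on the basic nutrient source.
    efficiency
        Consumption efficiency ``beta`` in (0, 1], shared across the web.
    biomass
        Current population density, normalised to carrying capacity.
    """

    decay_rate: float
    growth_rate: float = 1.0
    is_producer: bool = False
    efficiency: float = 1.0
    biomass: float = 0.0

    def __post_init__(self) -> None:
        if self.decay_rate <= 0:
            raise ValueError("decay_rate must be positive")
        if not (0.0 < self.efficiency <= 1.0):
            raise ValueError("efficiency must lie in (0, 1]")
        if self.biomass < 0:
            raise ValueError("biomass must be non-negative")


class FoodWeb:
    """Full state of an evolving ecosystem.

    Species are stored in arrival order in flat arrays; ``eta`` is the
    dense consumer-by-resource interaction matrix, ``eta[c, r] > 0`` iff
    consumer ``c`` eats resource ``r``.  Producer rows of ``eta`` are
    identically zero (producers consume only the nutrient), and the
    diagonal is zero (no cannibalism).  Webs stay small (n of order 10)
    so a dense matrix is the natural representation.
    """

    __slots__ = ("ids", "alpha", "is_producer", "eta", "biomass", "beta", "k")

    def __init__(
        self,
        ids: Sequence[int],
        alpha: Sequence[float],
        is_producer: Sequence[bool],
        eta: np.ndarray,
        biomass: Sequence[float],
        beta: float,
        k: float = 1.0,
    ) -> None:
        self.ids = np.asarray(ids, dtype=np.int64)
        self.alpha = np.asarray(alpha, dtype=np.float64)
        self.is_producer = np.asarray(is_producer, dtype=np.bool_)
        self.eta = np.asarray(eta, dtype=np.float64)
        self.biomass = np.asarray(biomass, dtype=np.float64)
        self.beta = float(beta)
        self.k = float(k)
        n = self.ids.size
        if not (self.alpha.size == n == self.is_producer.size == self.biomass.size):
            raise ValueError("species array lengths disagree")
        if self.eta.shape != (n, n):
            raise ValueError("eta must be n x n")

    # -- basic queries ---------------------------------------------------

    @property
    def n(self) -> int:
        """Species richness (the nutrient source is not counted)."""
        return int(self.ids.size)

    @property
    def total_count(self) -> int:
        return self.n

    @property
    def producer_count(self) -> int:
        return int(np.count_nonzero(self.is_producer))

    def resources_of(self, index: int) -> np.ndarray:
        """Indices of species that species ``index`` consumes."""
        return np.flatnonzero(self.eta[index] > 0.0)

    def is_treelike(self) -> bool:
        """True when no consumer has more than one resource."""
        return bool(np.all(np.count_nonzero(self.eta > 0.0, axis=1) <= 1))

    def validate(self) -> None:
        """Check the structural invariants; raise ``ValueError`` on breach."""
        if np.any(np.diag(self.eta) != 0.0):
            raise ValueError("self-loops (eta_kk != 0) are not allowed")
        if np.any(self.eta < 0.0):
            raise ValueError("interaction strengths must be non-negative")
        if np.any(self.eta[self.is_producer] != 0.0):
            raise ValueError("producers must not consume other species")
        if not (0.0 < self.beta <= 1.0):
            raise ValueError("beta must lie in (0, 1]")
        if np.any(self.alpha <= 0.0):
            raise ValueError("decay rates must be positive")
        consumers = ~self.is_producer
        if np.any(np.count_nonzero(self.eta[consumers] > 0.0, axis=1) == 0):
            raise ValueError("every consumer needs at least one resource")

    def copy(self) -> "FoodWeb":
        return FoodWeb(
            self.ids.copy(),
            self.alpha.copy(),
            self.is_producer.copy(),
            self.eta.copy(),
            self.biomass.copy(),
            self.beta,
            self.k,
        )

    def subset(self, keep: np.ndarray) -> "FoodWeb":
        """Web restricted to the boolean/index mask ``keep`` (links pruned)."""
        idx = np.asarray(keep)
        if idx.dtype == np.bool_:
            idx = np.flatnonzero(idx)
        return FoodWeb(
            self.ids[idx],
            self.alpha[idx],
            self.is_producer[idx],
            self.eta[np.ix_(idx, idx)],
            self.biomass[idx],
            self.beta,
            self.k,
        )

    # -- serialization ---------------------------------------------------

    def to_json(self) -> str:
        """Serialise to the snapshot JSON document (lossless floats)."""
        levels = trophic_levels(self) if self.n else np.empty(0)
        species = [
            {
                "id": int(self.ids[i]),
                "alpha": float(self.alpha[i]),
                **({"k": self.k} if self.is_producer[i] else {}),
                "is_producer": bool(self.is_producer[i]),
                "biomass": float(self.biomass[i]),
                "trophic_level": float(levels[i]),
            }
            for i in range(self.n)
        ]
        links = [
            {
                "consumer_id": int(self.ids[c]),
                "resource_id": int(self.ids[r]),
                "eta": float(self.eta[c, r]),
            }
            for c in range(self.n)
            for r in range(self.n)
            if self.eta[c, r] > 0.0
        ]
        return json.dumps({"beta": self.beta, "species": species, "links": links})

    @classmethod
    def from_json(cls, text: str, k: float = 1.0) -> "FoodWeb":
        doc = json.loads(text)
        species = doc["species"]
        ids = [s["id"] for s in species]
        index = {sid: i for i, sid in enumerate(ids)}
        n = len(ids)
        eta = np.zeros((n, n))
        for link in doc["links"]:
            eta[index[link["consumer_id"]], index[link["resource_id"]]] = link["eta"]
        ks = [s.get("k") for s in species if s["is_producer"]]
        if ks:
            k = ks[0]
        return cls(
            ids,
            [s["alpha"] for s in species],
            [s["is_producer"] for s in species],
            eta,
            [s["biomass"] for s in species],
            doc["beta"],
            k,
        )


@dataclass
class SteadyState:
    """Solution of the linear fixed-point system ``R S* = K``.

    ``populations`` may contain non-positive entries; the web is
    ``feasible`` only when every entry exceeds the feasibility
    threshold.  ``unique`` is False when ``R`` is singular or so badly
    conditioned that no unique steady state exists; callers treat that
    as infeasible and fall back on numerical relaxation.
    """

    populations: np.ndarray
    feasible: bool
    residual: float
    unique: bool = True


@dataclass
class CommunityMatrix:
    """Jacobian of the GLV dynamics evaluated at a fixed point."""

    entries: np.ndarray
    eigenvalues: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.eigenvalues is None:
            self.eigenvalues = np.linalg.eigvals(self.entries)


def per_capita_growth(web: FoodWeb, biomasses: np.ndarray) -> np.ndarray:
    """Per-capita growth rate of every species at the given biomasses.

    The total derivative of the biomass vector is
    ``biomasses * per_capita_growth(web, biomasses)``.
    """
    S = np.asarray(biomasses, dtype=np.float64)
    if S.shape != (web.n,):
        raise ValueError(f"biomass vector must have length {web.n}")
    producer_total = float(S[web.is_producer].sum())
    loss = web.eta.T @ S  # consumption pressure on each species
    gain = web.beta * (web.eta @ S)  # consumer gain from resources
    f = np.where(
        web.is_producer,
        web.k * (1.0 - producer_total) - web.alpha - loss,
        gain - web.alpha - loss,
    )
    return f


def assemble_linear_system(web: FoodWeb) -> tuple[np.ndarray, np.ndarray]:
    """Coefficients ``(R, K)`` with ``R S* = K`` at the interior fixed point.

    Convention: producer rows read ``k * [j is producer] + eta[j, i]`` with
    ``K_i = k - alpha_i``; consumer rows read ``beta eta[i, j] - eta[j, i]``
    with ``K_i = alpha_i``.
    """
    n = web.n
    prod = web.is_producer
    R = np.empty((n, n))
    # producer rows: k on every producer column, plus predation pressure
    R[prod] = (web.k * prod.astype(float))[None, :] + web.eta.T[prod]
    # consumer rows: gains minus losses
    cons = ~prod
    R[cons] = web.beta * web.eta[cons] - web.eta.T[cons]
    K = np.where(prod, web.k - web.alpha, web.alpha)
    return R, K


def steady_state(
    web: FoodWeb,
    feasibility_threshold: float = FEASIBILITY_THRESHOLD,
    cond_limit: float = COND_LIMIT,
) -> SteadyState:
    """Analytic steady state of the web.

    Returns ``unique=False`` (and ``feasible=False``) when the
    interaction matrix is singular or its condition number exceeds
    ``cond_limit``, in which case no unique steady state exists.
    """
    if web.n == 0:
        return SteadyState(np.empty(0), False, 0.0, unique=True)
    R, K = assemble_linear_system(web)
    if web.n == 1:
        if abs(R[0, 0]) < 1.0 / cond_limit:
            return SteadyState(np.full(1, np.nan), False, np.inf, unique=False)
        S = K / R[0, 0]
    else:
        if np.linalg.cond(R) > cond_limit:
            return SteadyState(np.full(web.n, np.nan), False, np.inf, unique=False)
        S = np.linalg.solve(R, K)
    surviving = S > feasibility_threshold
    if surviving.any():
        residual = float(np.max(np.abs(per_capita_growth(web, S)[surviving])))
    else:
        residual = 0.0
    feasible = bool(np.all(surviving))
    return SteadyState(S, feasible, residual, unique=True)


def community_matrix(web: FoodWeb, fixed_point: SteadyState) -> CommunityMatrix:
    """Community matrix ``C_ij = d(dS_i/dt)/dS_j`` at the fixed point.

    ``C = diag(S*) G + diag(f(S*))`` where ``G`` is the (constant)
    gradient of the per-capita growth; the diagonal correction vanishes
    up to the fixed-point residual.
    """
    if not fixed_point.feasible:
        raise ValueError("community matrix requires a feasible fixed point")
    S = fixed_point.populations
    R, _ = assemble_linear_system(web)
    # per-capita growth is  +/- (K - R S): gradient is -R on producer rows,
    # +R on consumer rows.
    sign = np.where(web.is_producer, -1.0, 1.0)
    G = sign[:, None] * R
    C = S[:, None] * G + np.diag(per_capita_growth(web, S))
    return CommunityMatrix(C)


def spectrum(cm: CommunityMatrix) -> np.ndarray:
    """All eigenvalues of the community matrix (conjugate-closed)."""
    return cm.eigenvalues


def is_stable(eigenvalues: np.ndarray, tol: float = STABILITY_TOL) -> bool:
    """True iff every eigenvalue has real part below the tolerance.

    The marginal two-species case has an eigenvalue at exactly zero and
    is treated as stable, hence the small positive tolerance.
    """
    eigenvalues = np.asarray(eigenvalues)
    if eigenvalues.size == 0:
        raise ValueError("empty spectrum")
    return bool(np.max(eigenvalues.real) <= tol)


def trophic_levels(web: FoodWeb) -> np.ndarray:
    """Trophic level of every species (producers exactly 1).

    A consumer sits one level above the unweighted mean of its
    resources' levels; the defining relations are solved as a linear
    system so webs with undirected loops are handled uniformly.
    """
    n = web.n
    A = np.eye(n)
    b = np.ones(n)
    for i in range(n):
        if web.is_producer[i]:
            continue
        res = web.resources_of(i)
        if res.size == 0:
            raise ValueError(f"consumer {int(web.ids[i])} has no resources")
        A[i, res] -= 1.0 / res.size
    return np.linalg.solve(A, b)
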