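"""Evolutionary assembly of food webs by sequential invasion.

Webs grow from a single producer by repeated invasion attempts: each
attempt draws a random species (producer or consumer with one or two
resource links, depending on the assembly mode), introduces it at
infinitesimal biomass and relaxes the web, removing any species driven
extinct.  Three modes are supported:

* ``treelike`` - every consumer has exactly one resource, so the web
  has no undirected loops;
* ``non_omnivorous`` - a second resource is proposed with probability
  0.75 and accepted only if it sits at the same trophic level as the
  first (loops without omnivory);
* ``omnivorous`` - a second resource is added with probability 1/2 and
  always accepted, allowing links across trophic levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from evospectra.constants import INVADER_BIOMASS
from evospectra.dynamics import RelaxationResult, relax
from evospectra.web import FoodWeb, trophic_levels

__all__ = [
    "MODES",
    "AssemblyConfig",
    "Invader",
    "InvasionRecord",
    "RecordedWeb",
    "EvolutionHistory",
    "draw_invader",
    "attempt_invasion",
    "evolve",
    "success_rate",
    "metrics",
]

MODES = ("treelike", "non_omnivorous", "omnivorous")

#: Mode-specific probability that a consumer proposes a second resource.
_SECOND_RESOURCE_PROB = {"treelike": 0.0, "non_omnivorous": 0.75, "omnivorous": 0.5}


@dataclass
class AssemblyConfig:
    """Parameters of one assembly simulation.

    The defaults reproduce the standard simulation conditions: producer
    growth rate ``k = 1`` sets the time unit, decay rates are drawn from
    U(0.05, 0.5), interaction strengths from U(0.01, 1), and one third
    of all invaders are primary producers (one producer invasion for
    every two consumer invasions; the one-half variant is a flag away).
    """

    mode: str
    beta: float
    attempts: int
    seed: int = 0
    producer_fraction: float = 1.0 / 3.0
    second_resource_prob: float | None = None
    alpha_range: tuple[float, float] = (0.05, 0.5)
    eta_range: tuple[float, float] = (0.01, 1.0)
    k: float = 1.0
    level_tol: float = 1e-9
    record_every_attempt: bool = False

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if not (0.0 < self.beta <= 1.0):
            raise ValueError("beta must lie in (0, 1]")
        if self.attempts < 1:
            raise ValueError("attempts must be positive")
        if not (0.0 <= self.producer_fraction <= 1.0):
            raise ValueError("producer_fraction must lie in [0, 1]")
        if self.second_resource_prob is None:
            self.second_resource_prob = _SECOND_RESOURCE_PROB[self.mode]
        if not (0.0 <= self.second_resource_prob <= 1.0):
            raise ValueError("second_resource_prob must lie in [0, 1]")
        lo, hi = self.alpha_range
        if not (0.0 < lo < hi):
            raise ValueError("alpha_range must be positive and ordered")
        lo, hi = self.eta_range
        if not (0.0 < lo < hi):
            raise ValueError("eta_range must be positive and ordered")
        if self.k <= 0:
            raise ValueError("k must be positive")


@dataclass
class Invader:
    """A candidate species: intrinsic parameters plus resource links."""

    alpha: float
    is_producer: bool
    resources: list[int] = field(default_factory=list)  # resident species ids
    etas: list[float] = field(default_factory=list)


@dataclass
class InvasionRecord:
    """Outcome of one invasion attempt."""

    attempt_index: int
    invader_is_producer: bool
    success: bool
    extinct_count: int  # resident extinctions (the failed invader not counted)
    richness_after: int
    web_changed: bool
    non_convergent: bool
    spectrum: np.ndarray | None = None


@dataclass
class RecordedWeb:
    """Feasible post-relaxation web retained for spectral statistics."""

    attempt_index: int
    richness: int
    treelike: bool
    eigenvalues: np.ndarray


@dataclass
class EvolutionHistory:
    """Complete bookkeeping of one assembly run."""

    config: AssemblyConfig
    records: list[InvasionRecord]
    recorded_webs: list[RecordedWeb]
    residence: dict[int, tuple[int, int | None]]  # id -> (arrival, departure)
    min_producer_alpha_trace: np.ndarray
    final_web: FoodWeb


def draw_invader(config: AssemblyConfig, web: FoodWeb, rng: np.random.Generator) -> Invader:
    """Draw a random invader for the current web.

    With probability ``producer_fraction`` the invader is a primary
    producer (it consumes only the nutrient source).  Otherwise it is a
    consumer whose first resource is chosen uniformly among all resident
    species; in loop-allowing modes a second distinct resident may be
    added according to the mode's rule.  Each link strength is drawn
    independently from U(0.01, 1).
    """
    if web.n == 0:
        raise ValueError("cannot draw an invader for an empty web")
    if rng.random() < config.producer_fraction:
        return Invader(alpha=rng.uniform(*config.alpha_range), is_producer=True)
    alpha = rng.uniform(*config.alpha_range)
    first = int(rng.integers(web.n))
    resources = [int(web.ids[first])]
    etas = [rng.uniform(*config.eta_range)]
    if config.second_resource_prob > 0.0 and web.n >= 2:
        if rng.random() < config.second_resource_prob:
            other = int(rng.integers(web.n - 1))
            if other >= first:
                other += 1
            accept = True
            if config.mode == "non_omnivorous":
                levels = trophic_levels(web)
                accept = abs(levels[first] - levels[other]) < config.level_tol
            if accept:
                resources.append(int(web.ids[other]))
                etas.append(rng.uniform(*config.eta_range))
    return Invader(alpha=alpha, is_producer=False, resources=resources, etas=etas)


def _extend_web(web: FoodWeb, invader: Invader, invader_id: int) -> FoodWeb:
    """Web with the invader appended at infinitesimal biomass."""
    n = web.n
    eta = np.zeros((n + 1, n + 1))
    eta[:n, :n] = web.eta
    if not invader.is_producer:
        index = {int(sid): i for i, sid in enumerate(web.ids)}
        for rid, e in zip(invader.resources, invader.etas):
            eta[n, index[rid]] = e
    return FoodWeb(
        np.append(web.ids, invader_id),
        np.append(web.alpha, invader.alpha),
        np.append(web.is_producer, invader.is_producer),
        eta,
        np.append(web.biomass, INVADER_BIOMASS),
        web.beta,
        web.k,
    )


def attempt_invasion(
    web: FoodWeb,
    invader: Invader,
    invader_id: int,
    attempt_index: int = 0,
) -> tuple[FoodWeb, InvasionRecord, RelaxationResult]:
    """Introduce the invader and relax the web to its next feasible state.

    The invasion succeeds when the invader survives relaxation.
    ``extinct_count`` counts resident extinctions only; an invader that
    itself dies out leaves the web unchanged.
    """
    extended = _extend_web(web, invader, invader_id)
    result = relax(extended)
    success = bool(np.isin(invader_id, result.final_web.ids))
    resident_extinct = [i for i in result.extinct_ids if i != invader_id]
    record = InvasionRecord(
        attempt_index=attempt_index,
        invader_is_producer=invader.is_producer,
        success=success,
        extinct_count=len(resident_extinct),
        richness_after=result.final_web.n,
        web_changed=success or bool(resident_extinct),
        non_convergent=result.non_convergent,
        spectrum=result.eigenvalues if result.feasible else None,
    )
    return result.final_web, record, result


def evolve(config: AssemblyConfig, progress=None) -> EvolutionHistory:
    """Run a full assembly simulation.

    Starts from the basic nutrient source plus one randomly
    parameterised producer, then applies ``config.attempts`` sequential
    invasion attempts.  Feasible post-relaxation webs are recorded
    (with their community-matrix spectra) whenever their composition
    differs from the previously recorded web, or after every attempt if
    ``record_every_attempt`` is set.

    ``progress``, when given, is called as ``progress(attempt, richness)``
    every 1000 attempts.
    """
    rng = np.random.default_rng(config.seed)

    web = FoodWeb(
        ids=[0],
        alpha=[rng.uniform(*config.alpha_range)],
        is_producer=[True],
        eta=np.zeros((1, 1)),
        biomass=[INVADER_BIOMASS],
        beta=config.beta,
        k=config.k,
    )
    seed_relax = relax(web)
    web = seed_relax.final_web

    records: list[InvasionRecord] = []
    recorded: list[RecordedWeb] = []
    residence: dict[int, tuple[int, int | None]] = {0: (0, None)}
    min_alpha_trace = np.empty(config.attempts)

    if seed_relax.feasible and seed_relax.eigenvalues is not None:
        recorded.append(
            RecordedWeb(0, web.n, web.is_treelike(), seed_relax.eigenvalues)
        )
    last_recorded_ids = frozenset(int(i) for i in web.ids)
    next_id = 1

    for attempt in range(1, config.attempts + 1):
        invader = draw_invader(config, web, rng)
        invader_id = next_id
        next_id += 1
        web, record, result = attempt_invasion(web, invader, invader_id, attempt)
        records.append(record)

        if record.success:
            residence[invader_id] = (attempt, None)
        for sid in result.extinct_ids:
            if sid != invader_id:
                arrival, _ = residence[sid]
                residence[sid] = (arrival, attempt)

        producers = web.is_producer
        min_alpha_trace[attempt - 1] = (
            web.alpha[producers].min() if producers.any() else np.nan
        )

        if result.feasible and result.eigenvalues is not None:
            current_ids = frozenset(int(i) for i in web.ids)
            if config.record_every_attempt or current_ids != last_recorded_ids:
                recorded.append(
                    RecordedWeb(attempt, web.n, web.is_treelike(), result.eigenvalues)
                )
                last_recorded_ids = current_ids

        if progress is not None and attempt % 1000 == 0:
            progress(attempt, web.n)

    return EvolutionHistory(
        config=config,
        records=records,
        recorded_webs=recorded,
        residence=residence,
        min_producer_alpha_trace=min_alpha_trace,
        final_web=web,
    )


def success_rate(history: EvolutionHistory) -> float:
    """Fraction of invasion attempts in which the invader survived."""
    if not history.records:
        raise ValueError("empty history")
    return float(np.mean([r.success for r in history.records]))


def metrics(history: EvolutionHistory) -> dict:
    """Summary statistics of an assembly run.

    Returns a dict with:

    * ``richness_histogram`` - normalised frequency of the
      post-relaxation species richness over every attempt;
    * ``residence_times`` / ``residence_censored`` - completed and
      right-censored residence intervals, in invasion attempts;
    * ``residence_time_cdf`` - ``(times, cdf)`` over completed intervals;
    * ``extinction_size_distribution`` - resident extinctions per event
      relative to the pre-extinction richness;
    * ``treelike_fraction`` - fraction of recorded feasible webs with
      no multi-resource consumer.
    """
    if not history.records:
        raise ValueError("empty history")
    richness = np.array([r.richness_after for r in history.records])
    values, counts = np.unique(richness, return_counts=True)
    hist = {int(v): float(c) / richness.size for v, c in zip(values, counts)}

    completed = []
    censored = []
    end = history.records[-1].attempt_index
    for arrival, departure in history.residence.values():
        if departure is None:
            censored.append(end - arrival)
        else:
            completed.append(departure - arrival)
    completed_arr = np.sort(np.array(completed, dtype=float))
    if completed_arr.size:
        cdf = np.arange(1, completed_arr.size + 1) / completed_arr.size
    else:
        cdf = np.empty(0)

    sizes = []
    for rec in history.records:
        pre = rec.richness_after - (1 if rec.success else 0) + rec.extinct_count
        if rec.extinct_count > 0:
            sizes.append(rec.extinct_count / pre)

    n_recorded = len(history.recorded_webs)
    treelike_fraction = (
        sum(1 for w in history.recorded_webs if w.treelike) / n_recorded
        if n_recorded
        else float("nan")
    )
    return {
        "richness_histogram": hist,
        "residence_times": completed_arr,
        "residence_censored": np.array(sorted(censored), dtype=float),
        "residence_time_cdf": (completed_arr, cdf),
        "extinction_size_distribution": np.array(sizes),
        "treelike_fraction": treelike_fraction,
    }
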