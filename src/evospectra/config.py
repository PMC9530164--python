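"""Run configuration: flat key-value files, validation, defaults.

Configuration documents are flat TOML (``key = value`` pairs, no
tables).  Command-line flags override file values.  Unknown keys and
out-of-range values are hard errors so typos never pass silently.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from evospectra.assembly import MODES, AssemblyConfig
from evospectra.constants import (
    ATOL,
    EXTINCTION_THRESHOLD,
    FEASIBILITY_THRESHOLD,
    RTOL,
    check_threshold_ordering,
)
from evospectra.random_baseline import RandomEnsembleSpec

__all__ = ["RunConfig", "load_config", "KNOWN_KEYS"]

#: Every key a configuration document may set, with its default.
_DEFAULTS: dict = {
    "mode": None,  # treelike | non_omnivorous | omnivorous
    "beta": None,
    "attempts": None,
    "seed": 0,
    "producer_fraction": 1.0 / 3.0,
    "second_resource_prob": None,  # mode default when omitted
    "alpha_min": 0.05,
    "alpha_max": 0.5,
    "eta_min": 0.01,
    "eta_max": 1.0,
    "k": 1.0,
    "record_every_attempt": False,
    "extinction_threshold": EXTINCTION_THRESHOLD,
    "feasibility_threshold": FEASIBILITY_THRESHOLD,
    "rtol": RTOL,
    "atol": ATOL,
    "output_dir": "run_output",
    "log_level": "INFO",
    # random-matrix ensemble (optional; active when random_n is set)
    "random_n": None,
    "random_samples": 10_000,
    "random_diagonal": -1.0,
}

KNOWN_KEYS = frozenset(_DEFAULTS)

_LOG_LEVELS = ("DEBUG", "INFO", "WARNING", "ERROR")


@dataclass
class RunConfig:
    """Fully resolved and validated configuration of one run."""

    assembly: AssemblyConfig | None
    random: RandomEnsembleSpec | None
    output_dir: Path
    record_every_attempt: bool = False
    integrator_tolerances: tuple[float, float] = (RTOL, ATOL)
    extinction_threshold: float = EXTINCTION_THRESHOLD
    feasibility_threshold: float = FEASIBILITY_THRESHOLD
    log_level: str = "INFO"
    seed: int = 0
    resolved: dict = field(default_factory=dict)  # exact echo of every tunable


def load_config(path: str | Path | None = None, **flags) -> RunConfig:
    """Build a validated :class:`RunConfig` from a file and/or flags.

    ``path`` points at a flat TOML document; keyword flags override file
    values.  A ``ValueError`` naming the offending key is raised for
    unknown keys or out-of-range values.
    """
    values = dict(_DEFAULTS)
    sources: dict = {}
    if path is not None:
        text = Path(path).read_text()
        sources.update(tomllib.loads(text))
    sources.update({k: v for k, v in flags.items() if v is not None})

    unknown = set(sources) - KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    values.update(sources)

    if values["log_level"] not in _LOG_LEVELS:
        raise ValueError(f"log_level must be one of {_LOG_LEVELS}")
    check_threshold_ordering(
        values["extinction_threshold"], values["feasibility_threshold"], values["atol"]
    )

    assembly = None
    if values["mode"] is not None:
        if values["mode"] not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {values['mode']!r}")
        for key in ("beta", "attempts"):
            if values[key] is None:
                raise ValueError(f"configuration key {key!r} is required with mode")
        try:
            assembly = AssemblyConfig(
                mode=values["mode"],
                beta=float(values["beta"]),
                attempts=int(values["attempts"]),
                seed=int(values["seed"]),
                producer_fraction=float(values["producer_fraction"]),
                second_resource_prob=(
                    None
                    if values["second_resource_prob"] is None
                    else float(values["second_resource_prob"])
                ),
                alpha_range=(float(values["alpha_min"]), float(values["alpha_max"])),
                eta_range=(float(values["eta_min"]), float(values["eta_max"])),
                k=float(values["k"]),
                record_every_attempt=bool(values["record_every_attempt"]),
            )
        except ValueError as exc:
            raise ValueError(f"invalid assembly configuration: {exc}") from exc

    random_spec = None
    if values["random_n"] is not None:
        try:
            random_spec = RandomEnsembleSpec(
                size=int(values["random_n"]),
                diagonal=float(values["random_diagonal"]),
                samples=int(values["random_samples"]),
                seed=int(values["seed"]),
            )
        except ValueError as exc:
            raise ValueError(f"invalid random-ensemble configuration: {exc}") from exc

    if assembly is None and random_spec is None:
        raise ValueError("configuration selects neither an assembly run ('mode') "
                         "nor a random ensemble ('random_n')")

    resolved = dict(values)
    if assembly is not None:
        resolved["second_resource_prob"] = assembly.second_resource_prob
    return RunConfig(
        assembly=assembly,
        random=random_spec,
        output_dir=Path(values["output_dir"]),
        record_every_attempt=bool(values["record_every_attempt"]),
        integrator_tolerances=(float(values["rtol"]), float(values["atol"])),
        extinction_threshold=float(values["extinction_threshold"]),
        feasibility_threshold=float(values["feasibility_threshold"]),
        log_level=str(values["log_level"]),
        seed=int(values["seed"]),
        resolved=resolved,
    )
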