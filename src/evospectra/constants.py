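"""Numerical thresholds shared across the simulation protocol.

All times are in units of the inverse producer growth rate (k = 1), so
numeric time values can be read directly as multiples of a producer
generation.  The three biomass thresholds are strictly ordered:
extinction (1e-12) > feasibility (1e-14) > integrator absolute
tolerance; `check_threshold_ordering` enforces this when a
configuration overrides them.
"""

#: A species is declared extinct when its biomass falls to or below this.
EXTINCTION_THRESHOLD = 1e-12

#: A steady state is feasible when every population exceeds this.
FEASIBILITY_THRESHOLD = 1e-14

#: An eigenvalue counts as unstable when its real part exceeds this.
STABILITY_TOL = 1e-10

#: Relative deviation from the analytic steady state that counts as converged.
CONV_TOL = 1e-6

#: Softened convergence criterion applied after T_SOFTEN time units.
SOFT_CONV_TOL = 1e-2

#: Time at which the convergence criterion is softened.
T_SOFTEN = 1e4

#: Time at which integration is abandoned and the web declared non-convergent.
T_MAX = 1e5

#: Initial biomass of every newly introduced species.
INVADER_BIOMASS = 1e-10

#: Relative / absolute error tolerances of the adaptive integrator.
RTOL = 1e-9
ATOL = 1e-14

#: Condition-number bound beyond which the linear steady-state system is
#: treated as having no unique solution.
COND_LIMIT = 1e12

#: Extinction-restart cycles allowed within a single relaxation before the
#: web is flagged non-convergent.
MAX_CYCLES = 50

#: |Im lambda| below which an eigenvalue is treated as purely real.
PURELY_REAL_TOL = 1e-9


def check_threshold_ordering(
    extinction: float = EXTINCTION_THRESHOLD,
    feasibility: float = FEASIBILITY_THRESHOLD,
    atol: float = ATOL,
) -> None:
    """Raise ``ValueError`` unless extinction > feasibility >= integrator floor."""
    if not (extinction > feasibility >= atol):
        raise ValueError(
            "threshold ordering violated: require extinction threshold "
            f"({extinction}) > feasibility threshold ({feasibility}) > "
            f"integrator absolute tolerance ({atol})"
        )
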