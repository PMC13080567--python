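"""Budget impact of adopting the AI risk assay for a tested population.

Budget impact uses undiscounted annual cost differences (AIKD minus
standard of care) from the same cohort model, scaled by the number of
patients tested.  Two uptake patterns are supported: a single tested
cohort, and the same number of new patients tested each year with each
cohort's cost stream truncated at the fixed calendar window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import InputSet
from .pipeline import arm_results

#: Reference annual payer budget (USD) for the share calculation.
DEFAULT_ANNUAL_BUDGET = 70e9


@dataclass
class BIAResult:
    """Annual and cumulative undiscounted budget impact, and budget share."""

    mode: str                 # "one_time" | "recurring"
    n_tested: float           # patients tested (per year if recurring)
    annual: np.ndarray        # USD per calendar year
    cumulative: float         # USD over the window
    budget_share: float       # cumulative / (annual budget x years)


def _per_patient_deltas(inputs: InputSet) -> np.ndarray:
    """Undiscounted per-patient annual cost difference, test cost in year 1."""
    aikd, soc = arm_results(inputs)
    delta = aikd.cycle_cost - soc.cycle_cost
    delta = delta.copy()
    delta[0] += aikd.test_cost - soc.test_cost
    return delta


def bia_one_time(inputs: InputSet, n_tested: float,
                 annual_budget: float = DEFAULT_ANNUAL_BUDGET) -> BIAResult:
    """Budget impact of testing one cohort of ``n_tested`` patients once."""
    if n_tested < 0:
        raise ValueError("n_tested must be non-negative")
    delta = _per_patient_deltas(inputs)
    annual = delta * n_tested
    years = len(annual)
    cumulative = float(annual.sum())
    return BIAResult(
        mode="one_time", n_tested=n_tested, annual=annual,
        cumulative=cumulative,
        budget_share=cumulative / (annual_budget * years),
    )


def bia_recurring(inputs: InputSet, n_per_year: float, years: int | None = None,
                  annual_budget: float = DEFAULT_ANNUAL_BUDGET) -> BIAResult:
    """Budget impact of testing ``n_per_year`` new patients every year.

    The cohort entering in year ``j`` contributes its per-patient cost-delta
    stream from its own year 1 onward, truncated at the end of the
    ``years``-long calendar window (default: the model horizon).
    """
    if n_per_year < 0:
        raise ValueError("n_per_year must be non-negative")
    delta = _per_patient_deltas(inputs)
    if years is None:
        years = len(delta)
    if years < 1:
        raise ValueError("years must be >= 1")
    annual = np.zeros(years)
    for y in range(1, years + 1):
        for j in range(1, y + 1):       # cohort entering year j
            k = y - j                   # its own stream year (0-based)
            if k < len(delta):
                annual[y - 1] += n_per_year * delta[k]
    cumulative = float(annual.sum())
    return BIAResult(
        mode="recurring", n_tested=n_per_year, annual=annual,
        cumulative=cumulative,
        budget_share=cumulative / (annual_budget * years),
    )
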