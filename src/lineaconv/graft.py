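"""Event-rate statistics for hair-follicle reconstitution assays.

A grafting condition is summarised by pooled counts: hair-follicle events
observed, total donor epithelial cells grafted and number of grafts.  Rates
are events per grafted cell (the assays normalise by cell totals); the
treatment/control rate ratio optionally carries an exact 95% confidence
interval from the conditional-binomial method for two Poisson rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .synthetic import GraftCountRecord

__all__ = ["RateRatioResult", "compute_rate_ratio", "replacement_efficiency"]


@dataclass(frozen=True)
class RateRatioResult:
    rate_treatment: float
    rate_control: float
    ratio: float
    rate_treatment_per_graft: float
    rate_control_per_graft: float
    ci_low: float | None = None
    ci_high: float | None = None


def compute_rate_ratio(
    treatment: GraftCountRecord,
    control: GraftCountRecord,
    with_ci: bool = False,
    conf_level: float = 0.95,
) -> RateRatioResult:
    """Ratio of per-cell event rates between two grafting conditions.

    With ``with_ci``, the interval conditions on the total event count:
    treatment events are binomial with success probability determined by
    the two cell totals, and a Clopper-Pearson interval on that probability
    maps back to the rate ratio.  A zero-event control gives a flagged
    infinite ratio with a lower bound only.
    """
    rt = treatment.events / treatment.cells_grafted
    rc = control.events / control.cells_grafted
    ratio = math.inf if control.events == 0 else rt / rc

    ci_low = ci_high = None
    if with_ci or control.events == 0:
        x, n = treatment.events, treatment.events + control.events
        if n == 0:
            ci_low, ci_high = 0.0, math.inf
        else:
            a = 1.0 - conf_level
            p_lo = (
                0.0 if x == 0 else stats.beta.ppf(a / 2, x, n - x + 1)
            )
            p_hi = 1.0 if x == n else stats.beta.ppf(1 - a / 2, x + 1, n - x)
            scale = control.cells_grafted / treatment.cells_grafted
            ci_low = scale * p_lo / (1 - p_lo) if p_lo < 1 else math.inf
            ci_high = math.inf if p_hi == 1 else scale * p_hi / (1 - p_hi)
    return RateRatioResult(
        rate_treatment=rt,
        rate_control=rc,
        ratio=ratio,
        rate_treatment_per_graft=treatment.events / treatment.n_grafts,
        rate_control_per_graft=control.events / control.n_grafts,
        ci_low=ci_low,
        ci_high=ci_high,
    )


def replacement_efficiency(original_hf_count: int, replaced_hf_count: int) -> float:
    """Percentage of original hair follicles replaced by donor-derived ones."""
    if original_hf_count <= 0:
        raise ValueError("original_hf_count must be positive")
    if not 0 <= replaced_hf_count <= original_hf_count:
        raise ValueError("replaced count must lie in [0, original]")
    return 100.0 * replaced_hf_count / original_hf_count
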