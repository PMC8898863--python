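"""Incremental cost-effectiveness ratios, volume sweeps and thresholds.

Combines the cost amortisation and QALY accrual models into cost per
QALY at a stated volume/horizon/discount setting, sweeps annual case
volume for curve export, and runs the published sensitivity and
threshold comparisons.  A non-positive QALY gain raises
:class:`UndefinedIcerError` — never infinity or a sentinel number.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from ._round import round_pounds
from .costs import incremental_cost
from .parameters import ParameterBundle, ValidationError
from .qaly import lifetime_policy, qalys_gained, ten_year_policy

__all__ = [
    "UndefinedIcerError",
    "IcerResult",
    "VolumeSweep",
    "cost_per_qaly",
    "run_base_case",
    "volume_sweep",
    "sensitivity_uplift",
    "threshold_checks",
    "break_even_volume",
    "BASE_CASE_KEYS",
]

#: Comparison thresholds from the published cost-effectiveness literature:
#: willingness-to-pay upper bound, and the per-patient price thresholds at
#: which a 50% revision-rate reduction / a 5% quality-of-life improvement
#: keep the robotic arm cost-effective.
REVISION_REDUCTION_PRICE_THRESHOLD = 1_347.0
QOL_IMPROVEMENT_PRICE_THRESHOLD = 10_578.0


class UndefinedIcerError(ValidationError):
    """Signals a non-positive QALY gain (dominance / no benefit)."""


@dataclass(frozen=True)
class IcerResult:
    incremental_cost: float
    qalys_gained: float
    cost_per_qaly: float
    volume: int
    horizon_label: str  # "ten_year" | "lifetime"
    discounted: bool

    @property
    def cost_per_qaly_pounds(self) -> int:
        """Whole-pound (half-up) rendering of the ratio."""
        return round_pounds(self.cost_per_qaly)


@dataclass(frozen=True)
class VolumeSweep:
    rows: tuple[IcerResult, ...]
    grid: tuple[int, ...]


def cost_per_qaly(cost: float, qalys: float) -> float:
    """Exact quotient ``cost / qalys``; rounding happens only at render time.

    Raises
    ------
    UndefinedIcerError
        If ``qalys <= 0`` — the ratio is undefined, signalling no
        benefit rather than returning a sentinel.
    """
    if qalys <= 0:
        raise UndefinedIcerError(
            f"cost per QALY undefined for QALY gain {qalys!r} (must be > 0)"
        )
    return cost / qalys


BASE_CASE_KEYS = (
    ("ten_year", False),
    ("ten_year", True),
    ("lifetime", False),
    ("lifetime", True),
)


def _policy_for(params: ParameterBundle, horizon_label: str, discounted: bool):
    if horizon_label == "ten_year":
        return ten_year_policy(params, discounted)
    if horizon_label == "lifetime":
        return lifetime_policy(params, discounted)
    raise ValidationError(
        f"unknown horizon label {horizon_label!r}; expected 'ten_year' or 'lifetime'"
    )


def _single_icer(
    params: ParameterBundle,
    volume: int,
    horizon_label: str,
    discounted: bool,
    uplift: float | None = None,
) -> IcerResult:
    uplift = params.effect.adjusted_uplift if uplift is None else uplift
    cost = incremental_cost(params.costs, volume)
    qres = qalys_gained(uplift, _policy_for(params, horizon_label, discounted))
    return IcerResult(
        incremental_cost=cost.total_per_case,
        qalys_gained=qres.qalys_gained,
        cost_per_qaly=cost_per_qaly(cost.total_per_case, qres.qalys_gained),
        volume=volume,
        horizon_label=horizon_label,
        discounted=discounted,
    )


def run_base_case(
    params: ParameterBundle, volume: int = 100, uplift: float | None = None
) -> dict[tuple[str, bool], IcerResult]:
    """The four base-case ICERs: {10-year, lifetime} x {undiscounted, discounted}.

    Uses the calibrated default accrual conventions.  ``uplift``
    overrides the configured adjusted uplift (e.g. when estimated from a
    cohort).
    """
    return {
        (horizon, disc): _single_icer(params, volume, horizon, disc, uplift)
        for horizon, disc in BASE_CASE_KEYS
    }


def volume_sweep(
    params: ParameterBundle,
    grid: Iterable[int],
    horizon_label: str = "ten_year",
    discounted: bool = False,
    uplift: float | None = None,
) -> VolumeSweep:
    """One ICER per grid volume, for curve export/replotting."""
    grid = tuple(int(v) for v in grid)
    if not grid:
        raise ValidationError("volume grid must be non-empty")
    rows = tuple(
        _single_icer(params, v, horizon_label, discounted, uplift) for v in grid
    )
    return VolumeSweep(rows=rows, grid=grid)


def sensitivity_uplift(
    params: ParameterBundle, alternative_uplift: float, volume: int = 100
) -> IcerResult:
    """Lifetime undiscounted ICER with the uplift replaced wholesale."""
    if alternative_uplift <= 0:
        raise UndefinedIcerError(
            f"alternative uplift must be > 0, got {alternative_uplift!r}"
        )
    return _single_icer(params, volume, "lifetime", False, alternative_uplift)


def break_even_volume(
    params: ParameterBundle,
    threshold: float,
    horizon_label: str = "ten_year",
    discounted: bool = False,
) -> int:
    """Smallest annual volume with cost per QALY <= ``threshold``.

    Closed form from the strictly decreasing sweep:
    rental / volume + per_case <= threshold * qalys.
    """
    uplift = params.effect.adjusted_uplift
    qres = qalys_gained(uplift, _policy_for(params, horizon_label, discounted))
    per_case = params.costs.consumables_per_case + params.costs.ct_scan_per_case
    headroom = threshold * qres.qalys_gained - per_case
    if headroom <= 0:
        raise ValidationError(
            f"threshold {threshold} unreachable: per-case costs alone exceed "
            "the allowed spend at any volume"
        )
    import math

    volume = max(1, math.ceil(params.costs.robot_annual_rental / headroom))
    # guard against float edge: step down while still under threshold
    while volume > 1 and _single_icer(
        params, volume - 1, horizon_label, discounted
    ).cost_per_qaly <= threshold:
        volume -= 1
    return volume


def threshold_checks(
    params: ParameterBundle,
    volume: int = 100,
    published_mtha_cost_per_qaly: Mapping[str, float] | None = None,
) -> dict:
    """Threshold and sensitivity comparisons for the report.

    Returns a dict with: the per-patient incremental cost compared with
    the published price thresholds; each base-case cost per QALY
    compared with the willingness-to-pay bound; the uplift as a rounded
    percentage of the manual-arm mean improvement; and, if supplied,
    additive combinations with published manual-THA cost-per-QALY values
    (keys ``undiscounted`` / ``discounted``).  All comparisons use
    unrounded values; rounding applies to rendered figures only.
    """
    cost = incremental_cost(params.costs, volume)
    base = run_base_case(params, volume)
    wtp = params.effect.wtp_threshold

    relative_improvement_pct = round_pounds(
        100.0 * params.effect.adjusted_uplift / params.effect.mtha_mean_change
    )

    checks: dict = {
        "volume": volume,
        "incremental_cost": cost.total_per_case,
        "incremental_cost_below_qol_threshold": bool(
            cost.total_per_case < QOL_IMPROVEMENT_PRICE_THRESHOLD
        ),
        "incremental_cost_below_revision_threshold": bool(
            cost.total_per_case < REVISION_REDUCTION_PRICE_THRESHOLD
        ),
        "qol_threshold": QOL_IMPROVEMENT_PRICE_THRESHOLD,
        "revision_threshold": REVISION_REDUCTION_PRICE_THRESHOLD,
        "wtp_threshold": wtp,
        "relative_improvement_pct": relative_improvement_pct,
        "cost_per_qaly_below_wtp": {
            f"{h}_{'discounted' if d else 'undiscounted'}": bool(
                r.cost_per_qaly < wtp
            )
            for (h, d), r in base.items()
        },
    }

    if published_mtha_cost_per_qaly is not None:
        combined = {}
        for key, published in published_mtha_cost_per_qaly.items():
            discounted = key == "discounted"
            ours = base[("lifetime", discounted)].cost_per_qaly
            combined[key] = {
                "published_mtha": published,
                "combined": ours + published,
                "combined_pounds": round_pounds(ours + published),
            }
        checks["combined_with_published_mtha"] = combined
    return checks
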