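"""Incremental per-patient costs of robotic vs manual THA.

The robot rental is a fixed annual cost shared across the unit's annual
case volume; consumables and the preoperative CT are per-case.  Expected
revision cost is computed for reporting but cancels from the incremental
comparison under the equal-revision-rates assumption.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .parameters import CostSchedule, ValidationError

__all__ = ["IncrementalCost", "incremental_cost", "expected_revision_cost"]


@dataclass(frozen=True)
class IncrementalCost:
    """Per-patient incremental cost breakdown at a given annual volume."""

    robot_per_case: float
    consumables: float
    ct_scan: float
    total_per_case: float
    annual_volume: int


def incremental_cost(schedule: CostSchedule, annual_volume: int) -> IncrementalCost:
    """Incremental per-patient cost at ``annual_volume`` cases/year.

    robot_per_case = robot_annual_rental / annual_volume; the total adds
    per-case consumables and CT.  Values are kept unrounded; whole-pound
    rendering happens at report time.
    """
    if not isinstance(annual_volume, int) or annual_volume < 1:
        raise ValidationError(
            f"annual_volume must be an integer >= 1, got {annual_volume!r}"
        )
    robot = schedule.robot_annual_rental / annual_volume
    total = robot + schedule.consumables_per_case + schedule.ct_scan_per_case
    return IncrementalCost(
        robot_per_case=robot,
        consumables=schedule.consumables_per_case,
        ct_scan=schedule.ct_scan_per_case,
        total_per_case=total,
        annual_volume=annual_volume,
    )


def expected_revision_cost(
    ten_year_revision: float,
    septic_fraction: float,
    aseptic_cost: float,
    septic_cost: float,
) -> float:
    """Expected 10-year revision cost per primary procedure, GBP.

    ``rate * (septic_fraction * septic_cost + (1 - septic_fraction) * aseptic_cost)``.

    Identical for both arms under the equal-revision-rates assumption,
    so it cancels from the incremental cost; it is reported for context
    and available to sensitivity analyses with arm-specific rates.
    """
    for name, value in (
        ("ten_year_revision", ten_year_revision),
        ("septic_fraction", septic_fraction),
    ):
        if not math.isfinite(value) or not (0.0 <= value <= 1.0):
            raise ValidationError(f"{name} must lie in [0, 1], got {value!r}")
    for name, value in (("aseptic_cost", aseptic_cost), ("septic_cost", septic_cost)):
        if not math.isfinite(value) or value < 0:
            raise ValidationError(f"{name} must be finite and >= 0, got {value!r}")
    blended = septic_fraction * septic_cost + (1.0 - septic_fraction) * aseptic_cost
    return ten_year_revision * blended
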