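"""End-to-end analysis report.

Runs parameters -> (optional cohort estimation) -> QALY accrual ->
costs -> ICERs -> volume sweep -> sensitivity and threshold checks, and
renders the result both as a machine-readable dict (deterministic for a
given config and seed: no timestamps) and as a human-readable block in
the published table's layout.
"""

from __future__ import annotations

import dataclasses
from importlib import metadata
from pathlib import Path
from typing import Any, Mapping

from ._round import round_half_up, round_pounds
from .cohort import load_cohort
from .cohort_stats import fit_adjusted_uplift
from .costs import expected_revision_cost, incremental_cost
from .icer import run_base_case, sensitivity_uplift, threshold_checks, volume_sweep
from .parameters import ParameterBundle, load_parameters
from .qaly import lifetime_policy, qalys_gained, ten_year_policy

__all__ = ["run_report", "render_report", "DEFAULT_VOLUME_GRID"]

DEFAULT_VOLUME_GRID = tuple(range(10, 251, 10))

#: Published manual-THA lifetime cost-per-QALY estimates used for the
#: additive comparison in the discussion-style threshold block.
PUBLISHED_MTHA_COST_PER_QALY = {"undiscounted": 1_372.0, "discounted": 3_763.0}
LITERATURE_UPLIFT = 0.017


def _policy_dict(policy) -> dict[str, Any]:
    d = dataclasses.asdict(policy)
    d["survival_mode"] = policy.survival_mode.value
    d["discount_mode"] = policy.discount_mode.value
    return d


def _icer_dict(result) -> dict[str, Any]:
    return {
        "incremental_cost": result.incremental_cost,
        "qalys_gained": result.qalys_gained,
        "cost_per_qaly": result.cost_per_qaly,
        "cost_per_qaly_pounds": result.cost_per_qaly_pounds,
        "volume": result.volume,
        "horizon": result.horizon_label,
        "discounted": result.discounted,
    }


def run_report(
    config: Mapping[str, Any] | str | Path | None = None,
    cohort_file: str | Path | None = None,
    volume: int = 100,
    seed: int | None = None,
    volume_grid: tuple[int, ...] = DEFAULT_VOLUME_GRID,
) -> dict[str, Any]:
    """Execute the full pipeline and return a machine-readable report.

    If ``cohort_file`` is given, the utility uplift is estimated from it
    by the adjusted regression; otherwise the configured constant is
    used.  The returned dict is JSON-serialisable and byte-stable for a
    given config and seed.
    """
    params = load_parameters(config)

    if cohort_file is not None:
        effect = fit_adjusted_uplift(load_cohort(cohort_file))
        uplift = effect.estimate
        uplift_source = {
            "source": "estimated_from_cohort",
            "estimate": effect.estimate,
            "ci_low": effect.ci_low,
            "ci_high": effect.ci_high,
            "p_value": effect.p_value,
            "n_used": effect.n_used,
        }
    else:
        uplift = params.effect.adjusted_uplift
        uplift_source = {"source": "configured", "estimate": uplift}

    cost = incremental_cost(params.costs, volume)
    base = run_base_case(params, volume, uplift=uplift)
    sweep = volume_sweep(params, volume_grid, "ten_year", False, uplift=uplift)
    sweep_disc = volume_sweep(params, volume_grid, "ten_year", True, uplift=uplift)
    checks = threshold_checks(
        params, volume, published_mtha_cost_per_qaly=PUBLISHED_MTHA_COST_PER_QALY
    )
    sensitivity = {
        "literature_uplift": LITERATURE_UPLIFT,
        "cost_per_qaly_pounds": sensitivity_uplift(
            params, LITERATURE_UPLIFT, volume
        ).cost_per_qaly_pounds,
    }
    revision = expected_revision_cost(
        params.epidemiology.ten_year_revision,
        params.costs.septic_fraction,
        params.costs.revision_cost_aseptic,
        params.costs.revision_cost_septic,
    )

    try:
        version = metadata.version("hipcea")
    except metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"

    return {
        "parameters": params.to_dict(),
        "uplift": uplift_source,
        "incremental_cost": {
            "robot_per_case": cost.robot_per_case,
            "consumables": cost.consumables,
            "ct_scan": cost.ct_scan,
            "total_per_case": cost.total_per_case,
            "volume": cost.annual_volume,
        },
        "expected_ten_year_revision_cost": revision,
        "base_case": {
            f"{h}_{'discounted' if d else 'undiscounted'}": _icer_dict(res)
            for (h, d), res in base.items()
        },
        "policies": {
            "ten_year_undiscounted": _policy_dict(ten_year_policy(params, False)),
            "ten_year_discounted": _policy_dict(ten_year_policy(params, True)),
            "lifetime_undiscounted": _policy_dict(lifetime_policy(params, False)),
            "lifetime_discounted": _policy_dict(lifetime_policy(params, True)),
        },
        "sweep": {
            "grid": list(sweep.grid),
            "ten_year_undiscounted": [_icer_dict(r) for r in sweep.rows],
            "ten_year_discounted": [_icer_dict(r) for r in sweep_disc.rows],
        },
        "sensitivity": sensitivity,
        "threshold_checks": checks,
        "metadata": {"seed": seed, "package_version": version},
    }


def render_report(report: Mapping[str, Any]) -> str:
    """Human-readable block mirroring the published summary table."""
    p = report["parameters"]
    cost = report["incremental_cost"]
    base = report["base_case"]

    def pounds(x: float) -> str:
        return f"£{round_pounds(x):,}"

    lines = [
        "Health economic analysis",
        "",
        "Utility",
        f"  rTHA uplift                         {report['uplift']['estimate']:.3f}"
        f"  ({report['uplift']['source']})",
        "",
        "Mortality",
        f"  10-year mortality rate              {100 * p['ten_year_mortality']:.0f}%",
        f"  Remaining life expectancy           {p['life_expectancy_years']:.0f} years",
        "",
        "Financial costs",
        f"  Cost of mTHA (NHS tariff)           {pounds(p['mtha_tariff'])}",
        "  Additional costs of rTHA",
        f"    Robot (based on {cost['volume']} per year)    {pounds(cost['robot_per_case'])}",
        f"    Consumables                       {pounds(cost['consumables'])}",
        f"    CT scan                           {pounds(cost['ct_scan'])}",
        f"    Total per patient                 {pounds(cost['total_per_case'])}",
        "",
        "Rate and cost of revision",
        f"  Annual revision rate                {100 * p['annual_revision']:.3f}%",
        f"  Aseptic ({100 * (1 - p['septic_fraction']):.0f}% cases)                 "
        f"{pounds(p['revision_cost_aseptic'])}",
        f"  Septic ({100 * p['septic_fraction']:.0f}% cases)                  "
        f"{pounds(p['revision_cost_septic'])}",
        "",
        "QALYs gained",
        "  10-year gain",
        f"    Undiscounted                      "
        f"{round_half_up(base['ten_year_undiscounted']['qalys_gained'], 4):.4f}",
        f"    Discounted (5%)                   "
        f"{round_half_up(base['ten_year_discounted']['qalys_gained'], 4):.4f}",
        "  Lifetime gain",
        f"    Undiscounted                      "
        f"{round_half_up(base['lifetime_undiscounted']['qalys_gained'], 4):.4f}",
        f"    Discounted (5%)                   "
        f"{round_half_up(base['lifetime_discounted']['qalys_gained'], 4):.4f}",
        "",
        "Cost per QALY",
        "  10-year horizon",
        f"    Undiscounted                      "
        f"{pounds(base['ten_year_undiscounted']['cost_per_qaly'])}",
        f"    Discounted                        "
        f"{pounds(base['ten_year_discounted']['cost_per_qaly'])}",
        "  Lifetime horizon",
        f"    Undiscounted                      "
        f"{pounds(base['lifetime_undiscounted']['cost_per_qaly'])}",
        f"    Discounted                        "
        f"{pounds(base['lifetime_discounted']['cost_per_qaly'])}",
    ]
    return "\n".join(lines)
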