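"""Synthetic patient-level cohort generator.

The study's raw data are not public, so this module emulates the two
arms' published structure: group differences in sex mix, age and
preoperative scores; a ceiling-effect dependence of EQ-5D change on the
preoperative scores; and a true covariate-adjusted group effect on
EQ-5D change.  Covariates are drawn independently within group from
range-truncated normal distributions (no published covariance structure
to match), and the change-model intercept is solved so the manual-arm
mean change hits its target given the covariate distributions.

Generated postoperative utilities are clipped to the instrument range;
the resulting small bias in means is accepted and measured by the test
suite, not corrected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .parameters import ValidationError

__all__ = [
    "SCORE_RANGES",
    "EQ5D_FLOOR",
    "EQ5D_CEILING",
    "PatientRecord",
    "GroupSpec",
    "CohortSpec",
    "solve_intercept",
    "generate_cohort",
    "cohort_summary",
    "records_to_frame",
    "frame_to_records",
    "write_cohort",
    "load_cohort",
]

EQ5D_FLOOR = -0.56
EQ5D_CEILING = 1.0

#: Instrument ranges used for truncation and record validation.
SCORE_RANGES: dict[str, tuple[float, float]] = {
    "age": (18.0, 100.0),
    "preop_ohs": (0.0, 48.0),
    "preop_fjs": (0.0, 100.0),
    "preop_eq5d": (EQ5D_FLOOR, EQ5D_CEILING),
    "preop_eqvas": (0.0, 100.0),
    "postop_eq5d": (EQ5D_FLOOR, EQ5D_CEILING),
}

_COVARIATES = ("age", "preop_ohs", "preop_fjs", "preop_eq5d", "preop_eqvas")


@dataclass(frozen=True)
class PatientRecord:
    """One patient's group label, demographics and pre/post outcomes."""

    patient_id: str
    group: str  # "mTHA" | "rTHA"
    sex: str  # "male" | "female"
    age: float
    preop_ohs: float
    preop_fjs: float
    preop_eq5d: float
    preop_eqvas: float
    postop_eq5d: float
    eq5d_change: float

    def __post_init__(self) -> None:
        if self.group not in ("mTHA", "rTHA"):
            raise ValidationError(f"group must be mTHA or rTHA, got {self.group!r}")
        if self.sex not in ("male", "female"):
            raise ValidationError(f"sex must be male or female, got {self.sex!r}")
        for name, (lo, hi) in SCORE_RANGES.items():
            value = getattr(self, name)
            if not (lo <= value <= hi):
                raise ValidationError(
                    f"{name}={value!r} outside instrument range [{lo}, {hi}]"
                )
        if not math.isclose(
            self.eq5d_change, self.postop_eq5d - self.preop_eq5d, abs_tol=1e-9
        ):
            raise ValidationError(
                "eq5d_change must equal postop_eq5d - preop_eq5d "
                f"({self.postop_eq5d - self.preop_eq5d}), got {self.eq5d_change}"
            )


@dataclass(frozen=True)
class GroupSpec:
    """Marginal targets for one arm: size, sex mix, covariate (mean, sd)."""

    n: int
    male_fraction: float
    age: tuple[float, float]
    preop_ohs: tuple[float, float]
    preop_fjs: tuple[float, float]
    preop_eq5d: tuple[float, float]
    preop_eqvas: tuple[float, float]

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError(f"group size must be >= 2, got {self.n}")
        if not (0.0 <= self.male_fraction <= 1.0):
            raise ValidationError(
                f"male_fraction must lie in [0, 1], got {self.male_fraction}"
            )
        for name in _COVARIATES:
            mean, sd = getattr(self, name)
            lo, hi = SCORE_RANGES[name if name != "age" else "age"]
            if not (lo <= mean <= hi):
                raise ValidationError(
                    f"{name} mean {mean} outside feasible range [{lo}, {hi}]"
                )
            if sd < 0:
                raise ValidationError(f"{name} sd must be >= 0, got {sd}")


# Published arm-level marginals.  The manual arm's preoperative EQ-5D SD is
# printed as 0.312 in one table and 0.320 in the outcome-specific table; the
# latter is used.
_DEFAULT_MTHA = GroupSpec(
    n=512,
    male_fraction=0.459,
    age=(67.5, 12.1),
    preop_ohs=(20.9, 8.7),
    preop_fjs=(12.3, 15.5),
    preop_eq5d=(0.384, 0.320),
    preop_eqvas=(68.3, 22.1),
)
_DEFAULT_RTHA = GroupSpec(
    n=48,
    male_fraction=0.667,
    age=(58.9, 7.9),
    preop_ohs=(19.6, 14.3),
    preop_fjs=(12.1, 11.3),
    preop_eq5d=(0.630, 0.196),
    preop_eqvas=(77.5, 13.9),
)

#: Change-model slopes from the published adjusted regression; covariates
#: with a printed coefficient of 0.000 default to zero.
_DEFAULT_COEFFICIENTS: dict[str, float] = {
    "female": 0.0,
    "age": 0.0,
    "preop_ohs": 0.005,
    "preop_fjs": 0.0,
    "preop_eq5d": -0.829,
    "preop_eqvas": 0.002,
}


@dataclass(frozen=True)
class CohortSpec:
    """Generative model for a two-arm cohort.

    ``eq5d_change = intercept + coefficients . covariates
    + group_effect * [robotic] + N(0, residual_sd)``, with the intercept
    solved so the manual arm's expected change equals
    ``mtha_change_target``.

    The default ``residual_sd`` is deliberately smaller than the
    published marginal change SD: postoperative utilities are clipped at
    the instrument ceiling, and a wide residual would push the
    high-scoring robotic arm into the ceiling often enough to bias
    adjusted-effect recovery (see package notes on truncation bias).
    """

    mtha: GroupSpec = _DEFAULT_MTHA
    rtha: GroupSpec = _DEFAULT_RTHA
    group_effect: float = 0.091
    coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_COEFFICIENTS)
    )
    residual_sd: float = 0.08
    mtha_change_target: float = 0.370

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ValidationError(f"residual_sd must be >= 0, got {self.residual_sd}")
        unknown = set(self.coefficients) - set(_DEFAULT_COEFFICIENTS)
        if unknown:
            raise ValidationError(f"unknown change-model coefficients: {sorted(unknown)}")
        if not math.isfinite(self.group_effect):
            raise ValidationError("group_effect must be finite")

    def with_effect(self, group_effect: float) -> "CohortSpec":
        return replace(self, group_effect=group_effect)


def _truncnorm(mean: float, sd: float, lo: float, hi: float):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm(a, b, loc=mean, scale=sd)


def _truncated_mean(mean: float, sd: float, lo: float, hi: float) -> float:
    if sd == 0:
        return mean
    return float(_truncnorm(mean, sd, lo, hi).mean())


def solve_intercept(spec: CohortSpec) -> float:
    """Intercept making the manual arm's expected change hit its target.

    Uses the analytic means of the truncated covariate distributions, so
    the solve is deterministic and independent of the seed.
    """
    expected = {
        name: _truncated_mean(*getattr(spec.mtha, name), *SCORE_RANGES[name])
        for name in _COVARIATES
    }
    expected["female"] = 1.0 - spec.mtha.male_fraction
    drift = sum(spec.coefficients.get(k, 0.0) * v for k, v in expected.items())
    return spec.mtha_change_target - drift


def generate_cohort(spec: CohortSpec, seed: int) -> list[PatientRecord]:
    """Draw a full two-arm cohort; deterministic under a fixed seed."""
    rng = np.random.default_rng(seed)
    intercept = solve_intercept(spec)
    records: list[PatientRecord] = []
    for group_label, group in (("mTHA", spec.mtha), ("rTHA", spec.rtha)):
        covariates = {}
        for name in _COVARIATES:
            mean, sd = getattr(group, name)
            if sd == 0:
                covariates[name] = np.full(group.n, mean)
            else:
                dist = _truncnorm(mean, sd, *SCORE_RANGES[name])
                covariates[name] = dist.rvs(size=group.n, random_state=rng)
        female = (rng.random(group.n) >= group.male_fraction).astype(float)
        change = (
            intercept
            + spec.coefficients.get("female", 0.0) * female
            + sum(
                spec.coefficients.get(name, 0.0) * covariates[name]
                for name in _COVARIATES
            )
            + (spec.group_effect if group_label == "rTHA" else 0.0)
        )
        if spec.residual_sd > 0:
            change = change + rng.normal(0.0, spec.residual_sd, size=group.n)
        postop = np.clip(
            covariates["preop_eq5d"] + change, EQ5D_FLOOR, EQ5D_CEILING
        )
        for i in range(group.n):
            preop = float(covariates["preop_eq5d"][i])
            post = float(postop[i])
            records.append(
                PatientRecord(
                    patient_id=f"{group_label}-{i + 1:04d}",
                    group=group_label,
                    sex="female" if female[i] else "male",
                    age=float(covariates["age"][i]),
                    preop_ohs=float(covariates["preop_ohs"][i]),
                    preop_fjs=float(covariates["preop_fjs"][i]),
                    preop_eq5d=preop,
                    preop_eqvas=float(covariates["preop_eqvas"][i]),
                    postop_eq5d=post,
                    eq5d_change=post - preop,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Tabular round-trip


def records_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    frame = pd.DataFrame([vars(r) for r in records])
    if frame.empty:
        raise ValidationError("no records supplied")
    return frame


def frame_to_records(frame: pd.DataFrame) -> list[PatientRecord]:
    required = list(PatientRecord.__dataclass_fields__)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValidationError(f"cohort table missing columns: {missing}")
    return [
        PatientRecord(**{k: row[k] for k in required})
        for row in frame.to_dict("records")
    ]


def write_cohort(records: Iterable[PatientRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def load_cohort(path: str | Path) -> list[PatientRecord]:
    return frame_to_records(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# Summary tables


def _mean_sd(values: pd.Series) -> tuple[float, float]:
    return float(values.mean()), float(values.std(ddof=1))


def _diff_ci(a: pd.Series, b: pd.Series) -> tuple[float, float, float]:
    """Mean difference b - a with pooled-variance 95% CI."""
    na, nb = len(a), len(b)
    diff = float(b.mean() - a.mean())
    sp2 = (
        (na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)
    ) / (na + nb - 2)
    se = math.sqrt(sp2 * (1 / na + 1 / nb))
    tcrit = stats.t.ppf(0.975, na + nb - 2)
    return diff, diff - tcrit * se, diff + tcrit * se


def cohort_summary(records: Sequence[PatientRecord]) -> dict:
    """Per-group mean (SD) table, within-group change and between-group
    differences with 95% CIs, mirroring the published demographic and
    outcome tables."""
    frame = records_to_frame(records)
    out: dict = {"groups": {}, "differences": {}}
    by_group = {g: sub for g, sub in frame.groupby("group")}
    for g in ("mTHA", "rTHA"):
        if g not in by_group or len(by_group[g]) < 2:
            raise ValidationError(f"need >= 2 records in group {g}")
    for g, sub in by_group.items():
        stats_block = {
            name: _mean_sd(sub[name])
            for name in (
                "age",
                "preop_ohs",
                "preop_fjs",
                "preop_eq5d",
                "preop_eqvas",
                "postop_eq5d",
                "eq5d_change",
            )
        }
        stats_block["n"] = len(sub)
        stats_block["male_n"] = int((sub["sex"] == "male").sum())
        stats_block["female_n"] = int((sub["sex"] == "female").sum())
        out["groups"][g] = stats_block
    m, r = by_group["mTHA"], by_group["rTHA"]
    for name in ("age", "preop_ohs", "preop_fjs", "preop_eq5d", "preop_eqvas",
                 "postop_eq5d", "eq5d_change"):
        diff, lo, hi = _diff_ci(m[name], r[name])
        out["differences"][name] = {"diff": diff, "ci_low": lo, "ci_high": hi}
    return out
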