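"""Economic and epidemiologic model parameters.

Every numeric constant used by the downstream cost, QALY and ICER modules
lives here in validated, serialisable dataclasses.  A flat key-value
configuration document (YAML/JSON-compatible mapping) can override any
field; omitted fields fall back to the published base-case defaults.

The bundle is the single source of truth: no other module hard-codes a
cost, rate or horizon.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import yaml

SCHEMA_VERSION = 1

__all__ = [
    "CostSchedule",
    "EpidemiologyParameters",
    "DiscountPolicy",
    "EffectParameters",
    "ParameterBundle",
    "ParameterError",
    "ConfigError",
    "ValidationError",
    "load_parameters",
    "weighted_revision_rate",
    "SCHEMA_VERSION",
]


class ParameterError(ValueError):
    """Base class for configuration and validation failures."""


class ConfigError(ParameterError):
    """Malformed or unrecognised configuration input."""


class ValidationError(ParameterError):
    """A parameter value violates its invariant."""


def _check_nonnegative(name: str, value: float) -> None:
    if not math.isfinite(value) or value < 0:
        raise ValidationError(f"{name} must be finite and >= 0, got {value!r}")


def _check_proportion(name: str, value: float) -> None:
    if not math.isfinite(value) or not (0.0 <= value <= 1.0):
        raise ValidationError(f"{name} must lie in [0, 1], got {value!r}")


def _check_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValidationError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class CostSchedule:
    """Unit costs in GBP.

    Money is stored unrounded; whole-pound (half-up) rendering happens
    only at report time.

    Attributes
    ----------
    robot_annual_rental : float
        Annual rental for the robotic system (12 monthly payments),
        GBP per year.
    consumables_per_case : float
        Robotic consumables per operated case, GBP.
    ct_scan_per_case : float
        Preoperative CT scan per robotic case, GBP.
    mtha_tariff : float
        National tariff for a manual THA, GBP.  Stored for reference;
        the incremental analysis does not use it.
    revision_cost_aseptic, revision_cost_septic : float
        Cost of an aseptic / septic revision procedure, GBP.
    septic_fraction : float
        Fraction of revisions that are septic, in [0, 1].
    """

    robot_annual_rental: float = 115_200.0  # 12 x 9,600/month
    consumables_per_case: float = 278.0
    ct_scan_per_case: float = 86.0
    mtha_tariff: float = 6_207.0
    revision_cost_aseptic: float = 11_897.0
    revision_cost_septic: float = 21_937.0
    septic_fraction: float = 0.13

    def __post_init__(self) -> None:
        for name in (
            "robot_annual_rental",
            "consumables_per_case",
            "ct_scan_per_case",
            "mtha_tariff",
            "revision_cost_aseptic",
            "revision_cost_septic",
        ):
            _check_nonnegative(name, getattr(self, name))
        _check_proportion("septic_fraction", self.septic_fraction)


@dataclass(frozen=True)
class EpidemiologyParameters:
    """Mortality, revision and life-expectancy assumptions.

    Both annual and 10-year forms are stored; consistency between them
    (annual mortality x 10 = decadal mortality; annual revision =
    decadal revision / 10) is enforced at construction, as is the
    life-expectancy average across sexes.
    """

    ten_year_mortality: float = 0.25
    annual_mortality: float = 0.025
    annual_revision: float = 0.00389
    ten_year_revision: float = 0.0389
    male_fraction: float = 0.40
    male_10yr_revision: float = 0.0428
    female_10yr_revision: float = 0.0363
    life_expectancy_years: float = 17.0
    male_life_expectancy: float = 16.0
    female_life_expectancy: float = 18.0
    reference_age: float = 69.0

    def __post_init__(self) -> None:
        for name in (
            "ten_year_mortality",
            "annual_mortality",
            "annual_revision",
            "ten_year_revision",
            "male_fraction",
            "male_10yr_revision",
            "female_10yr_revision",
        ):
            _check_proportion(name, getattr(self, name))
        for name in (
            "life_expectancy_years",
            "male_life_expectancy",
            "female_life_expectancy",
            "reference_age",
        ):
            _check_nonnegative(name, getattr(self, name))
        if not math.isclose(
            self.annual_mortality * 10, self.ten_year_mortality, abs_tol=1e-9
        ):
            raise ValidationError(
                "annual_mortality x 10 must equal ten_year_mortality "
                f"({self.annual_mortality * 10} != {self.ten_year_mortality})"
            )
        if not math.isclose(
            self.annual_revision * 10, self.ten_year_revision, abs_tol=1e-9
        ):
            raise ValidationError(
                "annual_revision x 10 must equal ten_year_revision "
                f"({self.annual_revision * 10} != {self.ten_year_revision})"
            )
        expected_le = 0.5 * (self.male_life_expectancy + self.female_life_expectancy)
        if not math.isclose(self.life_expectancy_years, expected_le, abs_tol=1e-9):
            raise ValidationError(
                "life_expectancy_years must be the mean of the sex-specific "
                f"values ({expected_le}), got {self.life_expectancy_years}"
            )


@dataclass(frozen=True)
class DiscountPolicy:
    """Annual discount rate applied to future health gain."""

    annual_rate: float = 0.05
    enabled: bool = True

    def __post_init__(self) -> None:
        if not math.isfinite(self.annual_rate) or not (0.0 <= self.annual_rate < 1.0):
            raise ValidationError(
                f"annual_rate must lie in [0, 1), got {self.annual_rate!r}"
            )


@dataclass(frozen=True)
class EffectParameters:
    """Treatment-effect and decision-threshold constants.

    ``adjusted_uplift`` is the covariate-adjusted extra annual EQ-5D
    improvement attributed to the robotic arm; ``mtha_mean_change`` the
    mean within-group EQ-5D improvement after manual THA.
    """

    adjusted_uplift: float = 0.091
    mtha_mean_change: float = 0.370
    eq5d_mcid: float = 0.08
    eq5d_sd: float = 0.30
    wtp_threshold: float = 20_000.0

    def __post_init__(self) -> None:
        _check_finite("adjusted_uplift", self.adjusted_uplift)
        _check_finite("mtha_mean_change", self.mtha_mean_change)
        _check_nonnegative("eq5d_mcid", self.eq5d_mcid)
        _check_nonnegative("eq5d_sd", self.eq5d_sd)
        if not math.isfinite(self.wtp_threshold) or self.wtp_threshold <= 0:
            raise ValidationError(
                f"wtp_threshold must be > 0, got {self.wtp_threshold!r}"
            )


_SECTIONS = {
    "costs": CostSchedule,
    "epidemiology": EpidemiologyParameters,
    "discount": DiscountPolicy,
    "effect": EffectParameters,
}


@dataclass(frozen=True)
class ParameterBundle:
    """The full resolved parameter set consumed by every other module."""

    costs: CostSchedule = field(default_factory=CostSchedule)
    epidemiology: EpidemiologyParameters = field(default_factory=EpidemiologyParameters)
    discount: DiscountPolicy = field(default_factory=DiscountPolicy)
    effect: EffectParameters = field(default_factory=EffectParameters)

    def to_dict(self) -> dict[str, Any]:
        """Flatten to the flat key-value configuration representation."""
        out: dict[str, Any] = {"schema_version": SCHEMA_VERSION}
        for section in _SECTIONS:
            out.update(dataclasses.asdict(getattr(self, section)))
        return out

    def replace(self, **flat_overrides: Any) -> "ParameterBundle":
        """Return a new bundle with flat-key overrides applied."""
        merged = self.to_dict()
        for key, value in flat_overrides.items():
            if key not in merged:
                raise ConfigError(f"unknown parameter key: {key!r}")
            merged[key] = value
        return _bundle_from_flat(merged)


def _field_owner() -> dict[str, str]:
    owners: dict[str, str] = {}
    for section, cls in _SECTIONS.items():
        for f in fields(cls):
            owners[f.name] = section
    return owners


_FIELD_OWNER = _field_owner()


def _bundle_from_flat(flat: Mapping[str, Any]) -> ParameterBundle:
    per_section: dict[str, dict[str, Any]] = {s: {} for s in _SECTIONS}
    for key, value in flat.items():
        if key == "schema_version":
            if value != SCHEMA_VERSION:
                raise ConfigError(
                    f"unsupported schema_version {value!r}; expected {SCHEMA_VERSION}"
                )
            continue
        owner = _FIELD_OWNER.get(key)
        if owner is None:
            raise ConfigError(f"unknown parameter key: {key!r}")
        per_section[owner][key] = value
    return ParameterBundle(
        **{section: cls(**per_section[section]) for section, cls in _SECTIONS.items()}
    )


def load_parameters(
    source: Mapping[str, Any] | str | Path | None = None,
) -> ParameterBundle:
    """Load a parameter bundle from a flat config mapping or YAML file.

    Parameters
    ----------
    source
        ``None`` for pure defaults, a mapping of flat keys, or a path to
        a YAML document containing such a mapping.  Unknown keys are
        rejected; omitted keys take the base-case defaults.

    Returns
    -------
    ParameterBundle
        Fully validated bundle.

    Raises
    ------
    ConfigError
        Unreadable or malformed config, or an unknown key.
    ValidationError
        A value violating a field invariant.
    """
    if source is None:
        return ParameterBundle()
    if isinstance(source, (str, Path)):
        path = Path(source)
        try:
            raw = yaml.safe_load(path.read_text())
        except OSError as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}") from exc
        if raw is None:
            raw = {}
        if not isinstance(raw, Mapping):
            raise ConfigError(
                f"config {path} must be a flat mapping, got {type(raw).__name__}"
            )
        return _bundle_from_flat(raw)
    if isinstance(source, Mapping):
        return _bundle_from_flat(source)
    raise ConfigError(f"unsupported config source type: {type(source).__name__}")


def weighted_revision_rate(
    male_fraction: float, male_rate: float, female_rate: float
) -> float:
    """Sex-weighted revision rate.

    ``male_fraction * male_rate + (1 - male_fraction) * female_rate``.
    At the base case (40% male, 4.28% / 3.63%) this gives the 3.89%
    10-year rate used throughout.

    Raises
    ------
    ValidationError
        If any argument lies outside [0, 1].
    """
    _check_proportion("male_fraction", male_fraction)
    _check_proportion("male_rate", male_rate)
    _check_proportion("female_rate", female_rate)
    return male_fraction * male_rate + (1.0 - male_fraction) * female_rate
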