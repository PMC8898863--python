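import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hipcea.cohort import generate_cohort, records_to_frame
from hipcea.cohort_stats import (
    PowerSpec,
    fit_adjusted_uplift,
    group_comparisons,
    sample_size_two_group,
)
from hipcea.parameters import ValidationError
from tests.test_cohort import make_record


def _design_frame(rng, n=16):
    """Small synthetic frame with independent covariates and known truth."""
    frame = pd.DataFrame(
        {
            "patient_id": [f"p{i}" for i in range(n)],
            "group": ["rTHA" if i % 2 else "mTHA" for i in range(n)],
            "sex": ["female" if i % 3 == 0 else "male" for i in range(n)],
            "age": rng.uniform(50, 80, n),
            "preop_ohs": rng.uniform(5, 40, n),
            "preop_fjs": rng.uniform(0, 60, n),
            "preop_eq5d": rng.uniform(0.0, 0.7, n),
            "preop_eqvas": rng.uniform(40, 90, n),
        }
    )
    frame["eq5d_change"] = rng.normal(0.3, 0.1, n)
    frame["postop_eq5d"] = frame["preop_eq5d"] + frame["eq5d_change"]
    return frame


class TestFitAdjustedUplift:
    def test_matches_normal_equations_closed_form(self):
        rng = np.random.default_rng(42)
        frame = _design_frame(rng)
        effect = fit_adjusted_uplift(frame)

        X = np.column_stack(
            [
                np.ones(len(frame)),
                (frame["sex"] == "female").astype(float),
                frame["age"],
                frame["preop_ohs"],
                frame["preop_fjs"],
                frame["preop_eq5d"],
                frame["preop_eqvas"],
                (frame["group"] == "rTHA").astype(float),
            ]
        )
        y = frame["eq5d_change"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert effect.estimate == pytest.approx(beta[-1], rel=1e-10)

    def test_residuals_orthogonal_to_design(self, small_spec):
        records = generate_cohort(small_spec, 9)
        frame = records_to_frame(records)
        effect = fit_adjusted_uplift(records)
        X = np.column_stack(
            [
                np.ones(len(frame)),
                (frame["sex"] == "female").astype(float),
                frame["age"],
                frame["preop_ohs"],
                frame["preop_fjs"],
                frame["preop_eq5d"],
                frame["preop_eqvas"],
                (frame["group"] == "rTHA").astype(float),
            ]
        )
        coefs = [effect.covariate_coefficients[name][0] for name in
                 ("const", "female", "age", "preop_ohs", "preop_fjs",
                  "preop_eq5d", "preop_eqvas")]
        beta = np.array(coefs + [effect.estimate])
        residuals = frame["eq5d_change"].to_numpy() - X @ beta
        np.testing.assert_allclose(X.T @ residuals, 0, atol=1e-8)

    def test_permuted_group_labels_centre_on_zero(self, small_spec):
        spec = dataclasses.replace(small_spec, group_effect=0.2)
        records = generate_cohort(spec, 13)
        frame = records_to_frame(records)
        rng = np.random.default_rng(99)
        estimates = []
        for _ in range(40):
            shuffled = frame.copy()
            shuffled["group"] = rng.permutation(frame["group"].to_numpy())
            estimates.append(fit_adjusted_uplift(shuffled).estimate)
        assert abs(np.mean(estimates)) < 0.02

    def test_ci_brackets_estimate_and_n(self, small_spec):
        records = generate_cohort(small_spec, 21)
        effect = fit_adjusted_uplift(records)
        assert effect.ci_low <= effect.estimate <= effect.ci_high
        assert effect.n_used == len(records)
        assert 0.0 <= effect.p_value <= 1.0

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(3)
        frame = _design_frame(rng)
        frame["preop_fjs"] = 5.0  # constant column, collinear with intercept
        with pytest.raises(ValidationError, match="preop_fjs"):
            fit_adjusted_uplift(frame)

    def test_missing_fields_listed(self):
        rng = np.random.default_rng(4)
        frame = _design_frame(rng)
        frame.loc[3, "preop_eq5d"] = np.nan
        with pytest.raises(ValidationError, match="missing"):
            fit_adjusted_uplift(frame)

    def test_single_arm_rejected(self):
        records = [make_record(patient_id=f"p{i}") for i in range(5)]
        with pytest.raises(ValidationError):
            fit_adjusted_uplift(records)


class TestGroupComparisons:
    def test_published_sex_table_odds_ratio(self):
        # 2x2 fixture with the published counts; cross-product oracle
        records = []
        counts = {("mTHA", "male"): 235, ("mTHA", "female"): 277,
                  ("rTHA", "male"): 32, ("rTHA", "female"): 16}
        i = 0
        for (group, sex), n in counts.items():
            for _ in range(n):
                records.append(make_record(patient_id=f"p{i}", group=group, sex=sex))
                i += 1
        result = group_comparisons(records)
        expected_or = (16 * 235) / (32 * 277)
        assert result["sex"]["odds_ratio"] == pytest.approx(expected_or, rel=1e-12)
        # printed value is 0.43; the raw cross-product gives 0.424
        assert round(result["sex"]["odds_ratio"], 3) == 0.424
        assert result["sex"]["p_value"] < 0.05
        assert result["sex"]["ci_low"] < expected_or < result["sex"]["ci_high"]

    def test_identical_groups_symmetric(self):
        records = [make_record(patient_id=f"m{i}", sex=s)
                   for i, s in enumerate(["male", "female"] * 3)]
        records += [make_record(patient_id=f"r{i}", group="rTHA", sex=s)
                    for i, s in enumerate(["male", "female"] * 3)]
        result = group_comparisons(records)
        assert result["continuous"]["preop_eq5d"]["diff"] == pytest.approx(0.0)
        assert result["sex"]["odds_ratio"] == pytest.approx(1.0)

    def test_zero_cell_flags_or_undefined(self):
        records = [make_record(patient_id=f"m{i}", sex="male") for i in range(4)]
        records += [make_record(patient_id=f"r{i}", group="rTHA",
                                sex=["male", "female"][i % 2]) for i in range(4)]
        result = group_comparisons(records)
        assert result["sex"]["undefined"] is True
        assert result["sex"]["odds_ratio"] is None

    def test_perfectly_linear_covariate_gives_unit_correlation(self):
        records = []
        for i in range(6):
            preop = 0.1 + 0.1 * i
            post = 0.9 - 0.05 * i
            records.append(
                make_record(
                    patient_id=f"m{i}",
                    preop_eq5d=preop,
                    postop_eq5d=post,
                    eq5d_change=post - preop,
                )
            )
        for i in range(6):
            # same line change = 0.95 - 1.5 * preop as the manual arm
            preop = 0.15 + 0.1 * i
            change = 0.95 - 1.5 * preop
            records.append(
                make_record(
                    patient_id=f"r{i}",
                    group="rTHA",
                    preop_eq5d=preop,
                    postop_eq5d=preop + change,
                    eq5d_change=change,
                )
            )
        result = group_comparisons(records)
        assert result["correlations"]["preop_eq5d"]["r"] == pytest.approx(-1.0)

    def test_paired_change_matches_mean(self, small_spec):
        records = generate_cohort(small_spec, 31)
        frame = records_to_frame(records)
        result = group_comparisons(records)
        expected = frame[frame["group"] == "mTHA"]["eq5d_change"].mean()
        assert result["paired"]["mTHA"]["change"] == pytest.approx(expected)
        assert result["paired"]["mTHA"]["p_value"] < 0.001

    def test_pooled_vs_welch_flag(self, small_spec):
        records = generate_cohort(small_spec, 8)
        pooled = group_comparisons(records, pooled=True)
        welch = group_comparisons(records, pooled=False)
        assert (
            pooled["continuous"]["age"]["p_value"]
            != welch["continuous"]["age"]["p_value"]
        )


class TestSampleSize:
    def test_published_inputs_give_221_per_group(self):
        result = sample_size_two_group(PowerSpec())
        # z-quantile arithmetic oracle
        z = sps.norm.ppf(0.975) + sps.norm.ppf(0.80)
        exact = 2 * z**2 * (0.3 / 0.08) ** 2
        assert result.exact_per_group == pytest.approx(exact, rel=1e-12)
        # the study quotes 222 per group; the standard formula gives 221
        assert result.per_group == 221
        assert result.total == 442

    def test_delta_equal_sd(self):
        result = sample_size_two_group(PowerSpec(delta=0.3, sd=0.3))
        z = sps.norm.ppf(0.975) + sps.norm.ppf(0.80)
        assert result.per_group == math.ceil(2 * z**2 - 1e-12)
        assert result.per_group == 16

    def test_power_half_limit(self):
        result = sample_size_two_group(PowerSpec(power=0.5))
        z_alpha = sps.norm.ppf(0.975)
        expected = 2 * z_alpha**2 * (0.3 / 0.08) ** 2
        assert result.exact_per_group == pytest.approx(expected, rel=1e-12)

    def test_zero_delta_rejected(self):
        with pytest.raises(ValidationError):
            PowerSpec(delta=0.0)

    def test_monotonicity(self):
        n = lambda **kw: sample_size_two_group(PowerSpec(**kw)).exact_per_group
        assert n(delta=0.1) < n(delta=0.08)  # decreasing in delta
        assert n(sd=0.4) > n(sd=0.3)  # increasing in sd
        assert n(power=0.9) > n(power=0.8)  # increasing in power
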