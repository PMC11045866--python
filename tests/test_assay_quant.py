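"""Standard-curve quantification, CFU math, metabolomics preprocessing."""

import math

import numpy as np
import pandas as pd
import pytest

from mucoflow.assay_quant import (
    cfu_per_gram,
    enzyme_activity,
    fit_standard_curve,
    metabolomics_preprocess,
    normalize_activities,
    qpcr_copies,
    significant_metabolites,
)


class TestStandardCurve:
    def test_exact_line(self):
        pts = [(x, 2 * x + 1) for x in (0.0, 1.0, 2.0, 4.0)]
        curve = fit_standard_curve(pts)
        assert curve.slope == pytest.approx(2.0)
        assert curve.intercept == pytest.approx(1.0)
        assert curve.r_squared == pytest.approx(1.0)

    def test_constant_response_degenerate(self):
        curve = fit_standard_curve([(0, 3.0), (1, 3.0), (2, 3.0), (3, 3.0)])
        assert curve.slope == 0.0
        assert math.isnan(curve.r_squared)

    def test_refit_on_fitted_values_idempotent(self, rng):
        x = np.array([0.0, 1.0, 2.0, 4.0, 8.0])
        y = 0.7 * x + 0.2 + rng.normal(0, 0.05, size=5)
        c1 = fit_standard_curve(np.column_stack([x, y]))
        fitted = c1.slope * x + c1.intercept
        c2 = fit_standard_curve(np.column_stack([x, fitted]))
        assert c2.slope == pytest.approx(c1.slope)
        assert c2.intercept == pytest.approx(c1.intercept)

    def test_noisy_line_recovered_within_ols_se(self, rng):
        # analytic OLS sampling distribution over 500 replicates
        x = np.array([200.0, 100.0, 50.0, 25.0, 12.5, 6.25, 3.125])
        a, b, sigma = 0.005, 0.05, 0.002
        sxx = np.sum((x - x.mean()) ** 2)
        se_slope = sigma / math.sqrt(sxx)
        slopes = []
        for _ in range(500):
            y = a * x + b + rng.normal(0, sigma, size=len(x))
            slopes.append(fit_standard_curve(np.column_stack([x, y])).slope)
        assert abs(np.mean(slopes) - a) < 4 * se_slope / math.sqrt(500)
        assert np.std(slopes) == pytest.approx(se_slope, rel=0.2)

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            fit_standard_curve([(1, 0), (1, 1), (2, 2), (1, 3)])


class TestEnzymeActivity:
    def _unit_curve(self):
        return fit_standard_curve([(0, 0.0), (10, 10.0), (20, 20.0), (40, 40.0)])

    def test_hand_arithmetic(self):
        # 45 uM released in 45 min with 0.01 mg protein -> 100 uM/min/mg
        res = enzyme_activity(45.0, self._unit_curve(), time_min=45,
                              protein_mg=0.01)
        assert res.activity == pytest.approx(100.0)

    def test_zero_release(self):
        res = enzyme_activity(0.0, self._unit_curve(), protein_mg=0.01)
        assert res.activity == 0.0

    def test_duplicates_averaged_before_inversion(self):
        res = enzyme_activity([40.0, 50.0], self._unit_curve(), time_min=45,
                              protein_mg=0.01)
        assert res.activity == pytest.approx(45.0 / (45 * 0.01))
        assert res.replicate_values == (40.0, 50.0)

    def test_below_blank_floored_with_flag(self):
        curve = fit_standard_curve([(0, 1.0), (10, 11.0), (20, 21.0), (40, 41.0)])
        res = enzyme_activity(0.5, curve, protein_mg=0.01)
        assert res.activity == 0.0
        assert res.qc_flag == "below_blank"


class TestNormalizeActivities:
    def test_hand_shares(self):
        assert normalize_activities({"a": 3.0, "b": 1.0}) == pytest.approx(
            {"a": 0.75, "b": 0.25}
        )

    def test_single_enzyme(self):
        assert normalize_activities({"only": 2.5}) == {"only": 1.0}

    def test_six_enzyme_vector(self):
        acts = {f"e{i}": float(v) for i, v in enumerate([5, 10, 15, 20, 25, 25])}
        shares = normalize_activities(acts)
        assert sum(shares.values()) == pytest.approx(1.0)
        assert shares["e0"] == pytest.approx(0.05)
        assert shares["e5"] == pytest.approx(0.25)

    def test_all_zero_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert normalize_activities({"a": 0.0, "b": 0.0}) == {}


class TestQpcr:
    def _curve(self):
        # 100 % efficiency: slope -log2 ratio per cycle = -3.3219 per log10
        pts = [(k, 40.0 - 3.321928 * k) for k in (1.0, 2.0, 4.0, 6.0)]
        return fit_standard_curve(pts)

    def test_anchor_one_copy(self):
        assert qpcr_copies(40.0, self._curve()) == pytest.approx(1.0, rel=1e-6)

    def test_inversion_identity(self):
        curve = self._curve()
        for k in (2, 3, 5):
            cq = curve.intercept + curve.slope * k
            assert qpcr_copies(cq, curve) == pytest.approx(10.0**k, rel=1e-6)

    def test_rna_basis_rescaling(self):
        curve = self._curve()
        five_ng = qpcr_copies(30.0, curve, rna_input_ng=5.0)
        ten_ng = qpcr_copies(30.0, curve, rna_input_ng=10.0)
        assert five_ng == pytest.approx(2 * ten_ng)

    def test_dilution_series_round_trip(self, rng):
        # noisy 5-point standard series; planted copies re-quantified to 1 %
        true_log = np.array([2.0, 3.0, 4.0, 5.0, 6.0])
        cq = 38.0 - 3.3 * true_log + rng.normal(0, 0.01, 5)
        curve = fit_standard_curve(np.column_stack([true_log, cq]))
        for lg, c in zip(true_log, cq):
            assert qpcr_copies(c, curve) == pytest.approx(10**lg, rel=0.01)


class TestCfu:
    def test_hand_computation(self):
        value, censored = cfu_per_gram(30, 1e4, 0.1, 0.05, 1.0)
        assert value == pytest.approx(6e7)
        assert not censored

    def test_zero_colonies_censored_at_lod(self):
        value, censored = cfu_per_gram(0, 1e2, 0.1, 0.05, 1.0)
        assert censored
        assert value == pytest.approx(1 * 1e2 / 0.1 * 1.0 / 0.05)

    def test_mass_proportionality(self):
        v1, _ = cfu_per_gram(10, 1e3, 0.1, 0.05, 1.0)
        v2, _ = cfu_per_gram(10, 1e3, 0.1, 0.10, 1.0)
        assert v1 == pytest.approx(2 * v2)


class TestMetabolomicsPreprocess:
    def test_hand_table(self):
        peaks = pd.DataFrame(
            {"m1": [10.0, np.nan, 40.0], "m2": [np.nan, 5.0, np.nan]},
            index=["s1", "s2", "s3"],
        )
        weights = pd.Series([1.0, 1.0, 1.0], index=["s1", "s2", "s3"])
        out, dropped = metabolomics_preprocess(peaks, weights)
        assert dropped == []
        # m1 min positive 10 -> LOD 2; m2 min positive 5 -> LOD 1
        np.testing.assert_allclose(
            out["m1"], np.log10([10.0, 2.0, 40.0])
        )
        np.testing.assert_allclose(out["m2"], np.log10([1.0, 5.0, 1.0]))

    def test_weight_normalization_precedes_lod(self):
        peaks = pd.DataFrame({"m": [10.0, np.nan]}, index=["s1", "s2"])
        weights = pd.Series([2.0, 1.0], index=["s1", "s2"])
        out, _ = metabolomics_preprocess(peaks, weights)
        assert out.loc["s1", "m"] == pytest.approx(np.log10(5.0))
        assert out.loc["s2", "m"] == pytest.approx(np.log10(1.0))

    def test_no_missing_is_identity_up_to_transform(self):
        peaks = pd.DataFrame({"m": [1.0, 10.0, 100.0]}, index=list("abc"))
        weights = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        out, _ = metabolomics_preprocess(peaks, weights)
        np.testing.assert_allclose(out["m"], [0.0, 1.0, 2.0])

    def test_all_missing_metabolite_dropped(self):
        peaks = pd.DataFrame(
            {"gone": [np.nan, np.nan], "ok": [1.0, 2.0]}, index=["s1", "s2"]
        )
        weights = pd.Series([1.0, 1.0], index=["s1", "s2"])
        with pytest.warns(UserWarning, match="gone"):
            out, dropped = metabolomics_preprocess(peaks, weights)
        assert dropped == ["gone"]
        assert list(out.columns) == ["ok"]

    def test_commutes_with_sample_reordering(self, rng):
        peaks = pd.DataFrame(
            rng.uniform(1, 100, size=(6, 4)),
            index=[f"s{i}" for i in range(6)],
            columns=[f"m{i}" for i in range(4)],
        )
        weights = pd.Series(rng.uniform(20, 60, 6), index=peaks.index)
        a, _ = metabolomics_preprocess(peaks, weights)
        perm = peaks.index[::-1]
        b, _ = metabolomics_preprocess(peaks.loc[perm], weights)
        pd.testing.assert_frame_equal(a.loc[perm], b)


class TestSignificantMetabolites:
    def _table(self, fc, n=6):
        control = pd.DataFrame(
            {"m": np.full(n, 100.0) * (1 + 0.001 * np.arange(n))},
            index=[f"c{i}" for i in range(n)],
        )
        treated = pd.DataFrame(
            {"m": np.full(n, 100.0 * fc) * (1 + 0.001 * np.arange(n))},
            index=[f"t{i}" for i in range(n)],
        )
        table = pd.concat([control, treated])
        groups = pd.Series(["control"] * n + ["treated"] * n, index=table.index)
        return table, groups

    def test_both_rules_must_hold(self):
        table, groups = self._table(fc=1.4)
        res = significant_metabolites(table, groups)
        # complete separation gives small p, but FC 1.4 < 1.5
        assert res.loc["m", "p_value"] < 0.05
        assert not res.loc["m", "significant"]

    def test_fc_and_p_pass(self):
        table, groups = self._table(fc=1.6)
        res = significant_metabolites(table, groups)
        assert res.loc["m", "significant"]

    def test_planted_fold_changes_recovered_exactly(self):
        from mucoflow.synthetic_data import SimConfig, gen_metabolite_table

        peaks, weights, groups, truth = gen_metabolite_table(
            SimConfig(seed=0, noise_sd=0.0, n_samples_per_group=6),
            n_metabolites=30, missing_rate=0.0,
        )
        norm = peaks.div(weights, axis=0)
        res = significant_metabolites(norm, groups)
        hits = set(res.index[res["significant"]])
        assert hits == set(truth.planted_fold_changes)

    def test_small_groups_rejected(self):
        table, groups = self._table(fc=2.0, n=1)
        with pytest.raises(ValueError):
            significant_metabolites(table, groups)
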