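"""Dose-response fitting, AUC, Holm adjustment, densitometry contrasts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq
from statsmodels.stats.multitest import multipletests

from fshrdyn.assaystats import (
    DensitometryRecord,
    DoseResponse,
    FourPLFit,
    anova_pairwise,
    auc_trapezoid,
    fit_4pl,
    four_pl,
    holm_adjust,
    mi_ratio_contrast,
    simulate_assay,
    simulate_densitometry,
)

DOSES = np.logspace(-2, 2, 8)


class TestFit4PL:
    def test_noiseless_recovery_to_4_sig_figs(self):
        truth = FourPLFit(0.0, 100.0, 1.0, 1.0)
        fit = fit_4pl(simulate_assay(truth, DOSES, cv=0.0, n_replicates=1))
        assert fit.converged
        assert fit.bottom == pytest.approx(0.0, abs=1e-3)
        assert fit.top == pytest.approx(100.0, rel=1e-4)
        assert fit.ec50 == pytest.approx(1.0, rel=1e-4)
        assert fit.hill == pytest.approx(1.0, rel=1e-4)

    def test_ec50_is_half_max_dose_by_bisection(self):
        truth = FourPLFit(5.0, 95.0, 2.5, 1.7)
        fit = fit_4pl(simulate_assay(truth, DOSES, cv=0.0, n_replicates=1))
        half = (fit.bottom + fit.top) / 2
        crossing = brentq(lambda d: four_pl(d, fit.bottom, fit.top, fit.ec50,
                                            fit.hill) - half, 1e-6, 1e6)
        assert crossing == pytest.approx(fit.ec50, rel=1e-6)

    def test_recovery_within_3_se_at_low_nanomolar_truth(self):
        truth = FourPLFit(0.0, 100.0, 0.18, 1.0)
        doses = np.logspace(-3, 2, 8)
        fit = fit_4pl(simulate_assay(truth, doses, cv=0.05, n_replicates=3,
                                     seed=42))
        assert fit.converged
        assert abs(fit.ec50 - 0.18) < 3 * fit.se["ec50"]

    def test_zero_dose_handled_via_limit(self):
        doses = np.concatenate([[0.0], np.logspace(-2, 2, 7)])
        truth = FourPLFit(10.0, 90.0, 1.0, 1.0)
        data = simulate_assay(truth, doses, cv=0.0, n_replicates=1)
        assert data.responses[0, 0] == pytest.approx(10.0)
        fit = fit_4pl(data)
        assert fit.converged
        assert fit.ec50 == pytest.approx(1.0, rel=1e-3)

    def test_hopeless_data_flags_unconverged(self):
        rng = np.random.default_rng(0)
        data = DoseResponse(DOSES, rng.normal(50, 40, size=(1, 8)))
        fit = fit_4pl(data)
        # flat noise may fit *something*; the flag must simply be honest
        if not fit.converged:
            assert np.isnan(fit.ec50)

    def test_too_few_doses_rejected(self):
        with pytest.raises(ValueError, match="4 distinct"):
            fit_4pl(DoseResponse([1.0, 2.0, 4.0], np.ones((1, 3))))

    def test_parameter_recovery_over_seeds(self):
        """Median relative EC50 error < 10% and ±2 SE coverage >= 85%."""
        truth = FourPLFit(0.0, 100.0, 1.0, 1.0)
        errors, covered = [], 0
        n_seeds = 200
        for seed in range(n_seeds):
            fit = fit_4pl(simulate_assay(truth, DOSES, cv=0.05,
                                         n_replicates=3, seed=seed))
            errors.append(abs(fit.ec50 - 1.0))
            if abs(fit.ec50 - 1.0) <= 2 * fit.se["ec50"]:
                covered += 1
        assert np.median(errors) < 0.10
        assert covered / n_seeds >= 0.85


class TestAUC:
    def test_constant_curve(self):
        x = np.linspace(0, 10, 11)
        assert auc_trapezoid(x, np.ones(11)) == pytest.approx(10.0)

    def test_linear_curve(self):
        x = np.linspace(0, 1, 101)
        assert auc_trapezoid(x, x) == pytest.approx(0.5, abs=1e-6)

    def test_matches_cumsum_oracle(self):
        rng = np.random.default_rng(1)
        x = np.sort(rng.uniform(0, 5, 40))
        x += np.arange(40) * 1e-6  # ensure strict increase
        y = rng.normal(size=40)
        oracle = float(np.sum(0.5 * (y[1:] + y[:-1]) * np.diff(x)))
        assert auc_trapezoid(x, y) == pytest.approx(oracle)

    def test_linear_in_y_and_additive_in_x(self):
        rng = np.random.default_rng(2)
        x = np.linspace(0, 3, 31)
        y1, y2 = rng.normal(size=31), rng.normal(size=31)
        assert auc_trapezoid(x, 2 * y1 + y2) == pytest.approx(
            2 * auc_trapezoid(x, y1) + auc_trapezoid(x, y2)
        )
        assert auc_trapezoid(x, y1) == pytest.approx(
            auc_trapezoid(x[:16], y1[:16]) + auc_trapezoid(x[15:], y1[15:])
        )

    def test_unsorted_x_rejected(self):
        with pytest.raises(ValueError):
            auc_trapezoid([0.0, 2.0, 1.0], [1.0, 1.0, 1.0])


class TestHolm:
    def test_three_element_hand_computation(self):
        np.testing.assert_allclose(
            holm_adjust([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(holm_adjust([0.2]), [0.2])

    def test_ties_hit_monotone_cap(self):
        np.testing.assert_allclose(
            holm_adjust([0.2, 0.2, 0.2, 0.2]), [0.8, 0.8, 0.8, 0.8]
        )

    def test_four_element_hand_computation(self):
        # sorted: .005*4=.02, .02*3=.06, .04*2=.08, .5*1 -> .5
        np.testing.assert_allclose(
            holm_adjust([0.04, 0.005, 0.5, 0.02]), [0.08, 0.02, 0.5, 0.06]
        )

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=12))
    @settings(max_examples=150, derandomize=True)
    def test_matches_statsmodels_and_dominates_input(self, pvals):
        ours = holm_adjust(pvals)
        theirs = multipletests(pvals, method="holm")[1]
        np.testing.assert_allclose(ours, theirs, atol=1e-12)
        assert np.all(ours >= np.asarray(pvals) - 1e-15)
        assert np.all(ours <= 1.0)

    def test_permutation_equivariance(self):
        p = np.array([0.01, 0.2, 0.04, 0.8])
        perm = np.array([2, 0, 3, 1])
        np.testing.assert_allclose(holm_adjust(p)[perm], holm_adjust(p[perm]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.1, 1.4])


class TestMIRatio:
    def test_ratio_arithmetic(self):
        rec = DensitometryRecord("WT", "treated", mature=80.0, immature=50.0)
        assert rec.ratio == pytest.approx(1.6)

    def test_identical_groups_fold_one(self):
        records = [
            DensitometryRecord("WT", cond, m, 100.0)
            for cond in ("vehicle", "treated") for m in (90.0, 100.0, 110.0)
        ]
        out = mi_ratio_contrast(records)
        assert out["fold"] == pytest.approx(1.0)
        assert out["p"] == pytest.approx(1.0)

    def test_missing_condition_errors(self):
        records = [DensitometryRecord("WT", "treated", 80.0, 50.0)] * 3
        with pytest.raises(ValueError, match="vehicle"):
            mi_ratio_contrast(records)

    def test_fold_recovery_at_known_truth(self):
        # true 1.6-fold treatment effect, 10% CV, n=3 per arm
        est, ses = [], []
        for seed in range(100):
            records = simulate_densitometry("WT", fold=1.6, cv=0.10,
                                            n_replicates=3, seed=seed)
            out = mi_ratio_contrast(records)
            est.append(out["fold"])
        est = np.array(est)
        se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - 1.6) < 3 * se


class TestSimulateAssay:
    def test_zero_cv_reproduces_truth(self):
        truth = FourPLFit(0.0, 100.0, 1.0, 1.0)
        data = simulate_assay(truth, DOSES, cv=0.0, n_replicates=2)
        np.testing.assert_allclose(data.responses[0], truth(DOSES))
        np.testing.assert_allclose(data.responses[1], truth(DOSES))

    def test_seed_reproducibility(self):
        truth = FourPLFit(0.0, 100.0, 1.0, 1.0)
        d1 = simulate_assay(truth, DOSES, cv=0.05, seed=9)
        d2 = simulate_assay(truth, DOSES, cv=0.05, seed=9)
        np.testing.assert_array_equal(d1.responses, d2.responses)

    def test_empirical_cv_matches_nominal(self):
        truth = FourPLFit(0.0, 100.0, 1.0, 1.0)
        data = simulate_assay(truth, np.array([10.0]), cv=0.05,
                              n_replicates=10_000, seed=10)
        vals = data.responses[:, 0]
        cv = vals.std(ddof=1) / vals.mean()
        assert abs(cv - 0.05) / 0.05 < 0.05

    def test_mean_one_noise(self):
        truth = FourPLFit(0.0, 100.0, 1.0, 1.0)
        data = simulate_assay(truth, np.array([10.0]), cv=0.10,
                              n_replicates=50_000, seed=11)
        assert data.responses.mean() == pytest.approx(truth(10.0), rel=0.005)


def test_anova_pairwise_detects_shifted_group():
    rng = np.random.default_rng(12)
    groups = {
        "vehicle": rng.normal(10, 1, 9),
        "low": rng.normal(10.2, 1, 9),
        "high": rng.normal(15, 1, 9),
    }
    out = anova_pairwise(groups)
    assert out["anova_p"] < 1e-4
    pair = {frozenset((d["a"], d["b"])): d for d in out["pairwise"]}
    assert pair[frozenset(("vehicle", "high"))]["p_holm"] < 0.01
    assert pair[frozenset(("vehicle", "low"))]["p_holm"] > 0.05
    for d in out["pairwise"]:
        assert d["p_holm"] >= d["p_raw"]
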