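"""Combined interaction model, rIRR, and naive comparators."""

import numpy as np
import pytest

from heatccx import (
    ExperimentConfig,
    StrataSet,
    ci_overlap_rule,
    combine_datasets,
    fit_conditional_poisson,
    fit_rirr,
    naive_independent_difference,
    run_comparison_experiment,
)
from tests.conftest import random_strataset


def one_stratum(y, hw, key="s0"):
    return StrataSet(
        y=np.asarray(y, dtype=float),
        X=np.asarray(hw, dtype=float).reshape(-1, 1),
        stratum_idx=np.zeros(len(y), dtype=np.int64),
        columns=["hw_any"],
        keys=[(key,)],
    )


class TestCombine:
    def test_construction(self):
        ref = one_stratum([6, 6], [1, 0])
        ins = one_stratum([10, 5], [1, 0])
        c = combine_datasets(ref, ins)
        assert c.n_strata == 2
        assert c.columns == ["hw_any", "dt_x_hw_any"]
        # interaction zero on all reference rows, copy on insured rows
        assert np.allclose(c.X[:2, 1], 0.0)
        assert np.allclose(c.X[2:, 1], c.X[2:, 0])

    def test_rowwise_oracle(self):
        rng = np.random.default_rng(31)
        ref = random_strataset(rng, n_strata=6, n_cols=3)
        ins = random_strataset(rng, n_strata=4, n_cols=3)
        c = combine_datasets(ref, ins)
        rows = []
        for block, is_ins in ((ref, 0), (ins, 1)):
            for x in block.X:
                rows.append(np.concatenate([x, x * is_ins]))
        np.testing.assert_allclose(c.X, np.vstack(rows))
        np.testing.assert_allclose(c.y, np.concatenate([ref.y, ins.y]))

    def test_schema_mismatch_errors(self):
        rng = np.random.default_rng(32)
        ref = random_strataset(rng, n_strata=3, n_cols=2)
        ins = random_strataset(rng, n_strata=3, n_cols=3)
        with pytest.raises(ValueError):
            combine_datasets(ref, ins)


class TestRirr:
    def test_identical_datasets_give_unit_rirr(self):
        rng = np.random.default_rng(33)
        ref = random_strataset(rng, n_strata=10, n_cols=1, columns=["hw_any"],
                               beta=[0.2])
        res = fit_rirr(ref, ref)
        assert res.rirr == pytest.approx(1.0, abs=1e-8)

    def test_saturated_two_stratum_example(self):
        ref = one_stratum([6, 6], [1, 0], "ref")
        ins = one_stratum([10, 5], [1, 0], "ins")
        res = fit_rirr(ref, ins, with_naive=True)
        # beta4 = log2 - 0
        assert res.rirr == pytest.approx(2.0, abs=1e-8)
        assert res.irr_reference["irr"] == pytest.approx(1.0, abs=1e-8)
        assert res.irr_insured["irr"] == pytest.approx(2.0, abs=1e-8)

    def test_factorization_into_separate_fits(self):
        rng = np.random.default_rng(34)
        for _ in range(4):
            ref = random_strataset(rng, n_strata=12, n_cols=2,
                                   columns=["hw_any", "rh_pct"], beta=[0.1, 0.0])
            ins = random_strataset(rng, n_strata=9, n_cols=2,
                                   columns=["hw_any", "rh_pct"], beta=[0.3, 0.0])
            res = fit_rirr(ref, ins)
            b4 = res.fit_combined.coef("dt_x_hw_any")
            sep = res.fit_insured.coef("hw_any") - res.fit_reference.coef("hw_any")
            assert b4 == pytest.approx(sep, abs=1e-6)
            # reference block reproduced too
            assert res.fit_combined.coef("hw_any") == pytest.approx(
                res.fit_reference.coef("hw_any"), abs=1e-6
            )

    def test_label_swap_inverts_rirr(self):
        rng = np.random.default_rng(35)
        ref = random_strataset(rng, n_strata=10, n_cols=1, columns=["hw_any"], beta=[0.1])
        ins = random_strataset(rng, n_strata=10, n_cols=1, columns=["hw_any"], beta=[0.4])
        fwd = fit_rirr(ref, ins)
        rev = fit_rirr(ins, ref)
        assert rev.rirr == pytest.approx(1.0 / fwd.rirr, rel=1e-8)
        assert rev.ci[0] == pytest.approx(1.0 / fwd.ci[1], rel=1e-6)
        assert rev.ci[1] == pytest.approx(1.0 / fwd.ci[0], rel=1e-6)

    def test_both_dispersions_reported(self):
        rng = np.random.default_rng(36)
        ref = random_strataset(rng, n_strata=8, n_cols=1, columns=["hw_any"])
        ins = random_strataset(rng, n_strata=8, n_cols=1, columns=["hw_any"])
        d = fit_rirr(ref, ins).to_dict()["dispersion"]
        assert {"combined", "reference", "insured"} <= set(d)


class TestNaiveComparators:
    def _fit(self, y, hw):
        return fit_conditional_poisson(one_stratum(y, hw))

    def test_identical_fits_zero_z(self):
        rng = np.random.default_rng(37)
        ss = random_strataset(rng, n_strata=10, n_cols=1, columns=["hw_any"])
        fit = fit_conditional_poisson(ss)
        out = naive_independent_difference(fit, fit, "hw_any")
        assert out["z"] == pytest.approx(0.0, abs=1e-12)
        assert out["rirr_naive"] == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        rng = np.random.default_rng(38)
        a = fit_conditional_poisson(random_strataset(rng, 10, 1, columns=["hw_any"]))
        b = fit_conditional_poisson(random_strataset(rng, 10, 1, columns=["hw_any"]))
        a.beta, a.cov = np.array([0.0]), np.array([[0.01]])
        b.beta, b.cov = np.array([np.log(2.0)]), np.array([[0.01]])
        out = naive_independent_difference(a, b, "hw_any")
        assert out["z"] == pytest.approx(np.log(2.0) / np.sqrt(0.02), abs=1e-9)
        assert out["z"] == pytest.approx(4.901, abs=0.001)

    def test_zero_se_errors(self):
        rng = np.random.default_rng(39)
        fit = fit_conditional_poisson(random_strataset(rng, 10, 1, columns=["hw_any"]))
        degenerate = fit_conditional_poisson(random_strataset(rng, 10, 1, columns=["hw_any"]))
        degenerate.cov = np.array([[0.0]])
        with pytest.raises(ValueError):
            naive_independent_difference(fit, degenerate, "hw_any")

    def test_ci_overlap_examples(self):
        rng = np.random.default_rng(40)
        a = fit_conditional_poisson(random_strataset(rng, 10, 1, columns=["hw_any"]))
        b = fit_conditional_poisson(random_strataset(rng, 10, 1, columns=["hw_any"]))

        def set_ci(fit, lo, hi):
            # invert exp(b +/- 1.96 se) to hit the requested interval
            fit.beta = np.array([(np.log(lo) + np.log(hi)) / 2])
            se = (np.log(hi) - np.log(lo)) / (2 * 1.96)
            fit.cov = np.array([[se**2]])

        set_ci(a, 1.0, 1.2)
        set_ci(b, 1.3, 1.5)
        assert ci_overlap_rule(a, b, "hw_any") is True
        set_ci(a, 1.0, 1.3)
        set_ci(b, 1.2, 1.5)
        assert ci_overlap_rule(a, b, "hw_any") is False

    def test_ci_overlap_matches_interval_oracle(self):
        rng = np.random.default_rng(41)
        a = fit_conditional_poisson(random_strataset(rng, 10, 1, columns=["hw_any"]))
        b = fit_conditional_poisson(random_strataset(rng, 10, 1, columns=["hw_any"]))
        for _ in range(30):
            ba, bb = rng.normal(size=2) * 0.3
            sa, sb = rng.uniform(0.02, 0.3, size=2)
            a.beta, a.cov = np.array([ba]), np.array([[sa**2]])
            b.beta, b.cov = np.array([bb]), np.array([[sb**2]])
            lo_a, hi_a = ba - 1.96 * sa, ba + 1.96 * sa
            lo_b, hi_b = bb - 1.96 * sb, bb + 1.96 * sb
            disjoint = hi_a < lo_b or hi_b < lo_a
            assert ci_overlap_rule(a, b, "hw_any") == disjoint


class TestExperiment:
    def test_replicate_count_validation(self):
        with pytest.raises(ValueError):
            run_comparison_experiment(ExperimentConfig(n_replicates=1), seed=0)

    def test_deterministic_given_seed(self):
        cfg = ExperimentConfig(n_replicates=2, n_counties=4,
                               baseline_years=(2014, 2015))
        a = run_comparison_experiment(cfg, seed=5)
        b = run_comparison_experiment(cfg, seed=5)
        assert a["replicates"].equals(b["replicates"])

    def test_power_orders_methods(self):
        # the CI-overlap rule is conservative: with a real effect it should
        # never reject more often than the interaction-model Wald test
        cfg = ExperimentConfig(
            n_replicates=25, n_counties=10, true_irr_reference=1.0,
            true_irr_insured=1.5, baseline_years=(2014, 2015),
        )
        out = run_comparison_experiment(cfg, seed=6)
        s = out["summary"].set_index("method")["rejection_rate"]
        assert s["rirr_interaction"] >= s["ci_overlap"]
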