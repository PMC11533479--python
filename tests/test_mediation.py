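"""MVMR, error propagation, the mediation decomposition and screening."""

import numpy as np
import pytest

import mrmediate as mm
from mrmediate import Estimate, mediation_effect, propagate_se, screen_mediators
from mrmediate.instruments import MultiHarmonizedSet


class TestPropagateSE:
    def test_pythagorean_addition(self):
        r = propagate_se("add", (1, 0.3), (1, 0.4))
        assert (r.value, r.se) == (2, pytest.approx(0.5))

    def test_subtraction_same_se(self):
        r = propagate_se("subtract", (3, 0.3), (1, 0.4))
        assert (r.value, r.se) == (2, pytest.approx(0.5))

    def test_multiply_with_exact_scalar(self):
        r = propagate_se("multiply", (2, 0.1), (3, 0.0))
        assert (r.value, r.se) == (6, pytest.approx(0.3))

    def test_divide_zero_numerator_limit(self):
        r = propagate_se("divide", (0.0, 0.2), (4.0, 0.1))
        assert (r.value, r.se) == (0.0, pytest.approx(0.05))

    def test_divide_by_zero_raises(self):
        with pytest.raises(ZeroDivisionError):
            propagate_se("divide", (1, 0.1), (0, 0.1))

    def test_unknown_op(self):
        with pytest.raises(ValueError, match="unknown op"):
            propagate_se("power", (1, 0.1), (1, 0.1))

    @pytest.mark.parametrize("op", ["add", "subtract", "multiply", "divide"])
    def test_rules_track_monte_carlo(self, op, rng):
        """At z >= 10 for both inputs, first-order propagation matches the
        Monte-Carlo sd of the composed quantity (coarse check; the
        full-size comparison lives in the acceptance suite)."""
        a, b = Estimate(1.3, 0.1), Estimate(2.1, 0.15)
        da = rng.normal(a.value, a.se, 200_000)
        db = rng.normal(b.value, b.se, 200_000)
        mc = {"add": da + db, "subtract": da - db, "multiply": da * db, "divide": da / db}
        assert propagate_se(op, a, b).se == pytest.approx(mc[op].std(), rel=0.05)


class TestMediationEffect:
    def test_worked_example_from_published_coefficients(self):
        """Step-1 0.26 (SD/unit), step-2 log(1.14), total log(1.98) give a
        mediation effect ~3.4% and a proportion mediated ~5%."""
        r = mediation_effect((0.26, 0.018), (np.log(1.14), 0.07), (np.log(1.98), 0.07), "tg")
        assert r.indirect_pct == pytest.approx(3.46, rel=0.05)
        assert r.proportion_pct == pytest.approx(5.05, rel=0.05)
        assert r.indirect_beta == r.step1_beta * r.step2_beta  # exact product
        assert r.proportion == r.indirect_beta / r.total_beta

    def test_null_step2_gives_null_mediation(self):
        r = mediation_effect((0.3, 0.05), (0.0, 0.1), (0.5, 0.1))
        assert r.indirect_beta == 0.0
        assert r.proportion == 0.0

    def test_zero_total_is_error(self):
        with pytest.raises(ZeroDivisionError):
            mediation_effect((0.3, 0.05), (0.2, 0.1), (0.0, 0.1))

    def test_indirect_se_matches_monte_carlo(self, rng):
        s1, s2 = Estimate(0.5, 0.04), Estimate(0.3, 0.025)
        r = mediation_effect(s1, s2, (1.0, 0.05))
        prod = rng.normal(s1.value, s1.se, 500_000) * rng.normal(s2.value, s2.se, 500_000)
        assert r.indirect_se == pytest.approx(prod.std(), rel=0.05)

    def test_proportion_invariant_to_outcome_rescaling(self):
        """Rescaling the outcome (x c on the log-odds scale) rescales the
        indirect and total effects together, leaving the proportion fixed."""
        base = mediation_effect((0.26, 0.02), (0.131, 0.03), (0.683, 0.07))
        c = 3.7
        scaled = mediation_effect((0.26, 0.02), (0.131 * c, 0.03 * c), (0.683 * c, 0.07 * c))
        assert scaled.proportion == pytest.approx(base.proportion, rel=1e-12)
        assert scaled.proportion_se == pytest.approx(base.proportion_se, rel=1e-12)

    def test_delta_proportion_se_matches_bootstrap(self, rng):
        """Delta-method proportion SE vs parametric bootstrap, within 10%
        when the total-effect z >= 10."""
        s1, s2, tot = Estimate(0.26, 0.015), Estimate(0.13, 0.01), Estimate(0.68, 0.05)
        r = mediation_effect(s1, s2, tot)
        n = 400_000
        boot = (
            rng.normal(s1.value, s1.se, n)
            * rng.normal(s2.value, s2.se, n)
            / rng.normal(tot.value, tot.se, n)
        )
        assert r.proportion_se == pytest.approx(boot.std(), rel=0.10)

    def test_out_of_range_proportion_reported_not_clipped(self, caplog):
        with caplog.at_level("WARNING"):
            r = mediation_effect((2.0, 0.1), (1.0, 0.1), (0.5, 0.05))
        assert r.proportion == pytest.approx(4.0)
        assert any("outside" in m for m in caplog.messages)


class TestScreening:
    def test_published_pvalues_select_the_lipid_mediators(self):
        """Fasting glucose fails step 1 (p=0.21), hypertension fails step 2
        (p=0.946); LDL, HDL and TG pass both."""
        step1 = {"ldl": 1e-4, "hdl": 1e-4, "tg": 1e-4, "fg": 0.21, "htn": 1e-4}
        step2 = {"ldl": 0.015, "hdl": 1e-4, "tg": 1e-4, "fg": 0.911, "htn": 0.946}
        decisions = screen_mediators(step1, step2, alpha=0.05, m=5)
        included = {d.mediator_id for d in decisions if d.included}
        assert included == {"ldl", "hdl", "tg"}
        byid = {d.mediator_id: d for d in decisions}
        assert not byid["fg"].step1_pass
        assert byid["htn"].step1_pass and not byid["htn"].step2_pass
        assert "step2" in byid["htn"].exclusion_reason

    def test_alpha_near_one_includes_everything(self):
        decisions = screen_mediators(
            {"a": 0.9, "b": 0.5}, {"a": 0.99, "b": 0.7}, alpha=0.999999, m=1
        )
        assert all(d.included for d in decisions)

    def test_included_is_conjunction(self):
        (d,) = screen_mediators({"a": 1e-9}, {"a": 0.9}, alpha=0.05, m=1)
        assert d.step1_pass and not d.step2_pass and not d.included

    def test_id_mismatch_is_error(self):
        with pytest.raises(ValueError, match="differ"):
            screen_mediators({"a": 0.1}, {"b": 0.1})

    def test_bonferroni_threshold_divides_by_m(self):
        (d,) = screen_mediators({"a": 0.02}, {"a": 0.01}, alpha=0.05, m=5)
        assert not d.step1_pass  # 0.02 >= 0.05/5


def _multi(bx_cols, by, sy, ids=("x", "m")):
    n = len(by)
    return MultiHarmonizedSet(
        snp_ids=[f"rs{i}" for i in range(n)],
        exposure_ids=list(ids),
        beta_exp=np.column_stack(bx_cols),
        se_exp=np.full((n, len(bx_cols)), 0.01),
        beta_out=np.asarray(by, dtype=float),
        se_out=np.asarray(sy, dtype=float),
    )


class TestMVMR:
    def test_zero_second_exposure_reduces_to_univariable(self, rng):
        n = 20
        bx = rng.normal(0.1, 0.03, n)
        sy = np.full(n, 0.02)
        by = 0.5 * bx + rng.normal(0, 0.01, n)
        h = _multi([bx, np.zeros(n)], by, sy)
        est = mm.mvmr_ivw(h)
        uni = mm.IVWEstimator("random").fit(bx[:, None], by, y_se=sy)
        assert est.for_exposure("x").value == pytest.approx(float(uni.coef_[0]), rel=1e-10)
        assert np.isinf(est.for_exposure("m").se)
        assert est.pval_for("m") == 1.0

    def test_matches_multivariable_wls_oracle(self, rng):
        import statsmodels.api as sm

        for _ in range(20):
            n = 25
            X = rng.normal(0.1, 0.04, size=(n, 2))
            sy = rng.uniform(0.01, 0.05, n)
            by = X @ [0.4, -0.2] + rng.normal(0, sy)
            h = _multi([X[:, 0], X[:, 1]], by, sy)
            est = mm.mvmr_ivw(h, "fixed")
            fit = sm.WLS(by, X, weights=1 / sy**2).fit()
            np.testing.assert_allclose(est.betas, fit.params, atol=1e-10)
            np.testing.assert_allclose(
                est.ses, fit.bse / np.sqrt(fit.scale), atol=1e-10
            )

    def test_rank_deficiency_raises(self, rng):
        n = 15
        bx = rng.normal(0.1, 0.03, n)
        h = _multi([bx, 2 * bx], rng.normal(size=n), np.full(n, 0.02))
        with pytest.raises(ValueError, match="rank"):
            mm.mvmr_ivw(h)

    def test_too_few_instruments_raises(self, rng):
        h = _multi([[0.1, 0.2], [0.05, 0.1]], [0.1, 0.2], [0.02, 0.02])
        with pytest.raises(ValueError, match="too few"):
            mm.mvmr_ivw(h)

    def test_recovers_direct_and_mediator_effects(self, small_study):
        """MVMR separates the exposure's direct effect theta from the
        mediator's effect phi on synthetic data with known truth."""
        s = small_study
        exp_inst = mm.select_instruments(s.sumstats["exposure"], 5e-8)
        med_inst = mm.select_instruments(s.sumstats["mediator_1"], 5e-8)
        union = set(exp_inst.snp_ids) | set(med_inst.snp_ids)
        h = mm.harmonize_multi(
            {"exposure": s.sumstats["exposure"], "mediator_1": s.sumstats["mediator_1"]},
            s.sumstats["outcome"],
            snp_ids=union,
        )
        est = mm.mvmr_ivw(h)
        theta, phi = s.config.theta, s.config.phi[0]
        x = est.for_exposure("exposure")
        m = est.for_exposure("mediator_1")
        assert abs(x.value - theta) < 3 * x.se + 0.05
        assert abs(m.value - phi) < 3 * m.se + 0.05


class TestRunMediationAnalysis:
    @pytest.fixture(scope="class")
    @staticmethod
    def two_mediator_study():
        # one genuine mediator, one mediator genetically independent of the
        # exposure (alpha = 0) that still affects the outcome
        cfg = mm.SimulationConfig(
            n_snps=40,
            n_mediator_snps=20,
            n_per_cohort=(50_000, 50_000, 50_000),
            n_ld=8_000,
            alpha=(0.25, 0.0),
            phi=(0.28, 0.2),
            theta=0.63,
            delta_sd=0.12,
            seed=23,
        )
        return mm.simulate_study(cfg)

    def test_null_mediator_screened_out_true_one_recovered(self, two_mediator_study):
        s = two_mediator_study
        rep = mm.run_mediation_analysis(
            s.sumstats["exposure"],
            {k: s.sumstats[k] for k in ("mediator_1", "mediator_2")},
            s.sumstats["outcome"],
            ld=s.ld,
            config=mm.MediationConfig(run_battery=False, seed=5),
        )
        byid = {d.mediator_id: d for d in rep.screening}
        assert not byid["mediator_2"].included
        assert not byid["mediator_2"].step1_pass  # alpha=0: no step-1 signal
        assert byid["mediator_1"].included
        (res,) = rep.results
        truth = s.truth["proportion"]["mediator_1"]
        assert res.proportion == pytest.approx(truth, abs=0.08)
        assert "significant" in rep.instrument_counts
        assert rep.mediation_table().shape[0] == 1

    def test_independent_mediator_proportion_ci_covers_zero(self, two_mediator_study):
        """Forcing the null mediator through (alpha ~ 1) its mediated
        proportion is statistically indistinguishable from zero."""
        s = two_mediator_study
        rep = mm.run_mediation_analysis(
            s.sumstats["exposure"],
            {"mediator_2": s.sumstats["mediator_2"]},
            s.sumstats["outcome"],
            ld=s.ld,
            config=mm.MediationConfig(run_battery=False, alpha=0.9999, seed=5),
        )
        (res,) = rep.results
        assert res.proportion_ci[0] <= 0 <= res.proportion_ci[1]

    def test_battery_and_report_serialization(self, small_study):
        s = small_study
        rep = mm.run_mediation_analysis(
            s.sumstats["exposure"],
            {"mediator_1": s.sumstats["mediator_1"]},
            s.sumstats["outcome"],
            ld=s.ld,
            config=mm.MediationConfig(run_battery=True, n_boot=100, seed=5),
        )
        assert set(rep.battery) >= {"total", "step1_mediator_1"}
        assert [e.method for e in rep.battery["total"]][0] == "ivw_random"
        d = rep.to_dict()
        assert d["total_effect"]["odds_ratio"] == pytest.approx(np.exp(rep.total.beta))
        import json

        json.dumps(d)  # fully serializable

    def test_every_mediator_gets_a_screening_verdict(self, two_mediator_study):
        s = two_mediator_study
        rep = mm.run_mediation_analysis(
            s.sumstats["exposure"],
            {k: s.sumstats[k] for k in ("mediator_1", "mediator_2")},
            s.sumstats["outcome"],
            ld=s.ld,
            config=mm.MediationConfig(run_battery=False, seed=5),
        )
        verdicts = {d.mediator_id for d in rep.screening}
        assert verdicts == {"mediator_1", "mediator_2"}
        for d in rep.screening:
            assert d.included or d.exclusion_reason

    def test_no_direct_effect_proportion_near_one(self):
        """With theta = 0 the single mediator carries the whole effect."""
        props = []
        for seed in (101, 102):
            cfg = mm.SimulationConfig(
                n_snps=40,
                n_mediator_snps=20,
                n_per_cohort=(50_000, 50_000, 50_000),
                n_ld=8_000,
                theta=0.0,
                alpha=(0.3,),
                phi=(0.5,),
                seed=seed,
            )
            s = mm.simulate_study(cfg)
            rep = mm.run_mediation_analysis(
                s.sumstats["exposure"],
                {"mediator_1": s.sumstats["mediator_1"]},
                s.sumstats["outcome"],
                ld=s.ld,
                config=mm.MediationConfig(run_battery=False, seed=seed),
            )
            props.append(rep.results[0].proportion)
        assert np.mean(props) == pytest.approx(1.0, abs=0.2)
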