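import numpy as np
import pandas as pd
import pytest

from cogsurv import (
    GrowthParams,
    HazardParams,
    MCMCSettings,
    ModelSpec,
    chisq_test,
    compare_fits,
    fit_mlm,
    predict_trajectory,
    pseudo_r2,
)
from cogsurv.hazards import PiecewiseConstantHazard
from cogsurv.mcmc import PosteriorSummary, summarize_draws
from cogsurv.synthetic import SimConfig, simulate_cohort

SHORT = MCMCSettings(chains=2, iterations=600, burn_in=250, seed=3)


def _sim(growth, n=400, seed=1, hazard=None, census=29.0):
    keys = [("women", "Gf"), ("men", "Gf")]
    hazard = hazard or HazardParams(baseline=PiecewiseConstantHazard((), (0.03,)))
    cfg = SimConfig(
        n_individuals=n,
        domains=("Gf",),
        census_horizon=census,
        growth_truth={k: growth for k in keys},
        hazard_truth={k: hazard for k in keys},
        seed=seed,
    )
    return simulate_cohort(cfg)


class TestFitRecovery:
    def test_noiseless_quadratic_identified_exactly(self):
        growth = GrowthParams(2.0, -0.08, 0.003, var_u0=0.0, var_u1=0.0,
                              var_resid=0.0)
        cohort, panel, _ = _sim(growth, n=120, seed=5)
        summary, _ = fit_mlm(panel, cohort, ModelSpec(form="quadratic"),
                             MCMCSettings(chains=2, iterations=300, burn_in=200,
                                          seed=1))
        assert summary.mean("B0") == pytest.approx(2.0, abs=1e-3)
        assert summary.mean("B1") == pytest.approx(-0.08, abs=1e-3)
        assert summary.mean("B2") == pytest.approx(0.003, abs=1e-4)
        # variance posteriors concentrate near their lower bound
        assert summary.mean("var_resid") < 1e-3
        assert summary.mean("var_u1") < 1e-2

    def test_agrees_with_reml_oracle_under_ignorable_dropout(self, tmp_path):
        """With alpha = 0 the dropout is ignorable; posterior means should
        agree with a frequentist REML fit of the same model (lme4)."""
        import json
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        growth = GrowthParams(0.5, 0.05, -0.015, var_u0=9.0, var_u1=0.04,
                              corr_u0u1=-0.1, var_resid=1.0)
        cohort, panel, _ = _sim(growth, n=800, seed=7)
        summary, _ = fit_mlm(panel, cohort, ModelSpec(form="quadratic"),
                             MCMCSettings(chains=2, iterations=1200, burn_in=400,
                                          seed=2))
        panel.to_csv(tmp_path / "panel.csv", index=False)
        rscript = """
        suppressMessages(library(lme4)); suppressMessages(library(jsonlite))
        d <- read.csv("%s")
        m <- lmer(score ~ age_c + I(age_c^2) + (age_c | person_id), data = d,
                  REML = TRUE)
        vc <- as.data.frame(VarCorr(m))
        cat(toJSON(list(fixef = as.numeric(fixef(m)),
                        se = as.numeric(sqrt(diag(vcov(m)))),
                        var_u0 = vc$vcov[1], var_u1 = vc$vcov[2],
                        sigma2 = sigma(m)^2), digits = 10))
        """ % (tmp_path / "panel.csv")
        out = subprocess.run(["Rscript", "-e", rscript], capture_output=True,
                             text=True, check=True)
        ref = json.loads(out.stdout)
        for j, name in enumerate(("B0", "B1", "B2")):
            assert summary.mean(name) == pytest.approx(
                ref["fixef"][j], abs=3 * ref["se"][j] + 1e-3
            )
        assert summary.mean("var_resid") == pytest.approx(ref["sigma2"][0], rel=0.1)
        assert summary.mean("var_u0") == pytest.approx(ref["var_u0"][0], rel=0.15)
        assert summary.mean("var_u1") == pytest.approx(ref["var_u1"][0], rel=0.25)

    def test_scores_shrink_with_single_observation(self, recovery_fit, recovery_sim):
        cohort, panel, _ = recovery_sim
        _, scores = recovery_fit
        n_obs = panel.groupby("person_id").size()
        single = scores[scores["person_id"].isin(n_obs[n_obs == 1].index)]
        multi = scores[scores["person_id"].isin(n_obs[n_obs >= 3].index)]
        assert len(single) > 5 and len(multi) > 5
        # one observation barely updates the slope: posterior SD stays near
        # the prior (population) SD and the point score stays near zero
        prior_sd = np.sqrt(0.09)
        assert single["u1_sd"].mean() > 0.8 * prior_sd
        assert single["u1_hat"].abs().mean() < multi["u1_hat"].abs().mean()
        assert multi["u1_sd"].mean() < single["u1_sd"].mean()


class TestPseudoR2:
    def _fake_fit(self, var_resid, fingerprint="x"):
        draws = {"var_resid": np.full((2, 10), var_resid)}
        return summarize_draws(draws, {"fingerprint": fingerprint})

    def test_identity_is_zero(self):
        fit = self._fake_fit(0.8)
        assert pseudo_r2(fit, fit) == 0.0

    def test_hand_computed_ratio(self):
        assert pseudo_r2(self._fake_fit(0.5), self._fake_fit(1.0)) == 0.5

    def test_mismatched_data_rejected(self):
        with pytest.raises(ValueError):
            pseudo_r2(self._fake_fit(0.5, "a"), self._fake_fit(1.0, "b"))

    def test_high_age_signal_domain_has_higher_pseudo_r2(self):
        # fluid-like truth: steep quadratic decline, dispersed slopes;
        # crystallized-like truth: flat trajectory, little slope spread
        gf_like = GrowthParams(0.0, 0.03, -0.02, var_u0=70.0, var_u1=0.05,
                               var_resid=1.0)
        gc_like = GrowthParams(0.0, 0.02, 0.0, var_u0=80.0, var_u1=0.005,
                               var_resid=1.1)
        r2 = {}
        for name, growth in (("gf", gf_like), ("gc", gc_like)):
            cohort, panel, _ = _sim(growth, n=500, seed=11)
            full, _ = fit_mlm(panel, cohort, ModelSpec(form="quadratic"), SHORT)
            null, _ = fit_mlm(panel, cohort, ModelSpec(form="intercept_only"), SHORT)
            r2[name] = pseudo_r2(full, null)
        assert r2["gf"] > r2["gc"]


class TestTrajectory:
    def test_flat_line_when_no_change_terms(self):
        draws = {
            "B0": np.full((2, 50), 1.5),
            "B1": np.zeros((2, 50)),
            "B2": np.zeros((2, 50)),
        }
        fit = summarize_draws(draws, {"fixed_names": ["B0", "B1", "B2"],
                                      "age_range": (50.0, 87.0)})
        out = predict_trajectory(fit, [55.0, 65.0, 80.0])
        assert out["mean"].to_numpy() == pytest.approx([1.5, 1.5, 1.5])

    def test_curve_at_center_equals_intercept_mean(self, recovery_fit):
        summary, _ = recovery_fit
        out = predict_trajectory(summary, [65.0])
        assert out["mean"].iloc[0] == pytest.approx(summary.mean("B0"), abs=1e-9)

    def test_band_widens_at_sparse_extreme(self, recovery_fit):
        summary, _ = recovery_fit
        lo, hi = summary.meta["age_range"]
        out = predict_trajectory(summary, [65.0, hi - 0.1])
        width = out["ci_high"] - out["ci_low"]
        assert width.iloc[1] > width.iloc[0]

    def test_out_of_support_warns(self, recovery_fit):
        summary, _ = recovery_fit
        with pytest.warns(UserWarning):
            predict_trajectory(summary, [40.0, 65.0])


class TestModelComparison:
    @pytest.fixture(scope="class")
    def nested_fits(self):
        growth = GrowthParams(0.5, 0.08, -0.02, var_u0=30.0, var_u1=0.05,
                              var_resid=1.0)
        cohort, panel, _ = _sim(growth, n=350, seed=13)
        fits = []
        for form in ("intercept_only", "linear", "quadratic"):
            s, _ = fit_mlm(panel, cohort, ModelSpec(form=form), SHORT,
                           keep_draws=False)
            fits.append(s)
        return fits

    def test_duplicate_fit_has_identical_deviance(self, nested_fits):
        growth = GrowthParams(0.5, 0.08, -0.02, var_u0=30.0, var_u1=0.05,
                              var_resid=1.0)
        cohort, panel, _ = _sim(growth, n=350, seed=13)
        again, _ = fit_mlm(panel, cohort, ModelSpec(form="quadratic"), SHORT,
                           keep_draws=False)
        assert again.meta["deviance"] == pytest.approx(
            nested_fits[2].meta["deviance"]
        )

    def test_quadratic_truth_prefers_quadratic_model(self, nested_fits):
        table = compare_fits(nested_fits)
        bic = table.set_index("form")["bic"]
        assert bic["quadratic"] < bic["intercept_only"]

    def test_bic_formula(self, nested_fits):
        for fit in nested_fits:
            assert fit.meta["bic"] == pytest.approx(
                fit.meta["deviance"] + fit.meta["k"] * np.log(fit.meta["n_obs"])
            )

    def test_chisq_requires_nesting(self, nested_fits):
        io_fit, lin_fit, quad_fit = nested_fits
        res = chisq_test(io_fit, quad_fit)
        assert res["df"] == quad_fit.meta["k"] - io_fit.meta["k"]
        with pytest.raises(ValueError, match="nested"):
            chisq_test(quad_fit, io_fit)


class TestSpecValidation:
    def test_bad_form_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(form="cubic")

    def test_adjusted_intercept_only_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(form="intercept_only", adjusted=True)

    def test_empty_subset_rejected(self, recovery_sim):
        cohort, panel, _ = recovery_sim
        men = ModelSpec(form="quadratic", stratum="men")
        with pytest.raises(ValueError):
            fit_mlm(panel, cohort, men, SHORT)
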