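import numpy as np
import pandas as pd
import pandas.testing as pdt
import pytest

from cogsurv import ConfigError, GrowthParams, HazardParams, simulate_cohort, truncate_panel
from cogsurv.hazards import PiecewiseConstantHazard
from cogsurv.synthetic import SimConfig, covariate_linked_config, recovery_config


def _single_domain_config(**kw):
    growth = kw.pop("growth", GrowthParams(0.0, 0.0, 0.0, var_u0=1.0, var_u1=0.01,
                                           var_resid=1.0))
    hazard = kw.pop("hazard", HazardParams(
        baseline=PiecewiseConstantHazard((), (0.05,)), alpha1=0.0, alpha2=0.0))
    keys = [("women", "Gf"), ("men", "Gf")]
    return SimConfig(
        domains=("Gf",),
        growth_truth={k: growth for k in keys},
        hazard_truth={k: hazard for k in keys},
        **kw,
    )


class TestDeterminismAndMarginals:
    def test_identical_config_gives_identical_output(self):
        cfg = recovery_config(seed=5, n=200)
        out1 = simulate_cohort(cfg)
        out2 = simulate_cohort(recovery_config(seed=5, n=200))
        for a, b in zip(out1, out2):
            pdt.assert_frame_equal(a, b)

    def test_seed_changes_output(self):
        c1, _, _ = simulate_cohort(recovery_config(seed=1, n=100))
        c2, _, _ = simulate_cohort(recovery_config(seed=2, n=100))
        assert not c1["time"].equals(c2["time"])

    def test_covariate_marginals(self):
        cfg = _single_domain_config(n_individuals=4000, seed=11)
        cohort, _, _ = simulate_cohort(cfg)
        n = len(cohort)
        for col, p in (("smoker", cfg.prop_smokers),):
            se = np.sqrt(p * (1 - p) / n)
            assert abs(cohort[col].mean() - p) < 4 * se
        p = cfg.prop_women
        se = np.sqrt(p * (1 - p) / n)
        assert abs((cohort["sex"] == "women").mean() - p) < 4 * se
        # entry ages respect the truncation bounds and center
        age = cohort["start_age_c"] + 65.0
        assert age.min() >= 50.0 and age.max() <= 87.0
        assert abs(age.median() - 65.0) < 0.5
        assert cohort["srh"].between(1, 5).all()

    def test_time_and_event_invariants(self):
        cohort, panel, _ = simulate_cohort(recovery_config(seed=3, n=500))
        assert (cohort["time"] > 0).all()
        assert set(cohort["event"].unique()) <= {0, 1}
        censored = cohort[cohort["event"] == 0]
        assert censored["time"].eq(29.0).all()
        # occasions strictly increasing in age within person
        grp = panel.groupby("person_id")["age_c"]
        assert (grp.apply(lambda s: s.is_monotonic_increasing)).all()


class TestDegenerateAndClosedForm:
    def test_zero_noise_scores_lie_on_fixed_curve(self):
        growth = GrowthParams(1.0, -0.05, 0.002, var_u0=0.0, var_u1=0.0,
                              var_resid=0.0)
        cfg = _single_domain_config(n_individuals=50, seed=2, growth=growth)
        _, panel, _ = simulate_cohort(cfg)
        a = panel["age_c"].to_numpy()
        expected = 1.0 - 0.05 * a + 0.002 * a * a
        assert panel["score"].to_numpy() == pytest.approx(expected, abs=1e-12)

    def test_exponential_survival_closed_form(self):
        lam = 0.08
        cfg = _single_domain_config(
            n_individuals=8000, seed=4, census_horizon=1e6,
            hazard=HazardParams(baseline=PiecewiseConstantHazard((), (lam,))),
        )
        cohort, _, _ = simulate_cohort(cfg)
        t = cohort["time"].to_numpy()
        assert cohort["event"].all()
        assert abs(t.mean() - 1 / lam) < 4 * (1 / lam) / np.sqrt(t.size)
        for t0 in (2.0, 10.0, 25.0):
            s = np.exp(-lam * t0)
            se = np.sqrt(s * (1 - s) / t.size)
            assert abs(np.mean(t > t0) - s) < 4 * se


class TestSelectionMechanism:
    def test_death_independent_of_slope_when_alpha_zero(self):
        cfg = _single_domain_config(
            n_individuals=6000, seed=6, census_horizon=1e6,
            growth=GrowthParams(0.0, 0.0, 0.0, var_u0=70.0, var_u1=0.09,
                                var_resid=1.0),
            hazard=HazardParams(baseline=PiecewiseConstantHazard((), (0.05,))),
        )
        cohort, _, lat = simulate_cohort(cfg)
        m = cohort.merge(lat, on="person_id")
        r = np.corrcoef(m["u1"], m["time"])[0, 1]
        assert abs(r) < 3.5 / np.sqrt(len(m))

    def test_negative_alpha2_selects_against_decliners(self):
        # strong decline-mortality link: persons observed longest have
        # higher (less negative) latent slopes than the cohort average
        cfg = _single_domain_config(
            n_individuals=4000, seed=8,
            growth=GrowthParams(0.0, 0.0, 0.0, var_u0=10.0, var_u1=0.09,
                                var_resid=1.0),
            hazard=HazardParams(baseline=PiecewiseConstantHazard((), (0.08,)),
                                alpha2=-3.0),
        )
        cohort, panel, lat = simulate_cohort(cfg)
        occ = panel.groupby("person_id").size()
        retained = occ[occ >= 3].index
        m = lat.set_index("person_id")
        assert m.loc[retained, "u1"].mean() > m["u1"].mean() + 0.01

    def test_srh_dependence_knob(self):
        cfg = _single_domain_config(
            n_individuals=4000, seed=9,
            growth=GrowthParams(0.0, 0.0, 0.0, var_u0=50.0, var_u1=0.01,
                                var_resid=1.0),
        ).replace(srh_dependence=0.8)
        cohort, _, lat = simulate_cohort(cfg)
        m = cohort.merge(lat, on="person_id")
        assert np.corrcoef(m["srh"], m["u0"])[0, 1] > 0.2


class TestTruncation:
    def _toy(self):
        cohort = pd.DataFrame(
            {
                "person_id": ["a", "b"],
                "domain": "Gf",
                "sex": "women",
                "start_age_c": [0.0, 0.0],
                "smoker": 0,
                "srh": 3,
                "event": [1, 0],
                "time": [3.0, 29.0],
            }
        )
        panel = pd.DataFrame(
            {
                "person_id": ["a"] * 4 + ["b"] * 4,
                "occasion": [1, 2, 3, 4] * 2,
                "age_c": [0.0, 4.0, 8.0, 12.0] * 2,
                "domain": "Gf",
                "score": 0.0,
            }
        )
        return cohort, panel

    def test_death_truncates_schedule(self):
        cohort, panel = self._toy()
        out = truncate_panel(panel, cohort)
        assert list(out[out["person_id"] == "a"]["occasion"]) == [1]
        assert list(out[out["person_id"] == "b"]["occasion"]) == [1, 2, 3, 4]

    def test_identity_when_no_deaths(self):
        cohort, panel = self._toy()
        cohort["event"] = 0
        cohort["time"] = 29.0
        out = truncate_panel(panel, cohort)
        pdt.assert_frame_equal(out, panel)

    def test_orphan_ids_rejected(self):
        cohort, panel = self._toy()
        panel.loc[0, "person_id"] = "ghost"
        with pytest.raises(ValueError, match="ghost"):
            truncate_panel(panel, cohort)


class TestValidation:
    @pytest.mark.parametrize(
        "kw, field",
        [
            ({"prop_women": 1.2}, "prop_women"),
            ({"srh_dist": (0.5, 0.5, 0.0, 0.0, 0.1)}, "srh_dist"),
            ({"max_occasions": 0}, "max_occasions"),
            ({"census_horizon": -1.0}, "census_horizon"),
            ({"entry_age_iqr": (70.0, 60.0)}, "entry_age_iqr"),
            ({"visit_gap_years": (0.0, 2.0)}, "visit_gap_years"),
        ],
    )
    def test_config_errors_name_the_field(self, kw, field):
        with pytest.raises(ConfigError, match=field):
            recovery_config(seed=0, n=10).replace(**kw)

    def test_missing_truth_entry(self):
        cfg = recovery_config(seed=0, n=10)
        with pytest.raises(ConfigError, match="growth_truth"):
            cfg.replace(domains=("Gc",))


def test_covariate_linked_config_links_both_channels():
    cohort, panel, _ = simulate_cohort(covariate_linked_config(seed=12, n=3000))
    merged = panel.groupby("person_id")["score"].first().reset_index().merge(
        cohort, on="person_id"
    )
    # smokers score lower at baseline and die more
    smokers = merged["smoker"] == 1
    assert merged.loc[smokers, "score"].mean() < merged.loc[~smokers, "score"].mean()
    assert cohort[cohort.smoker == 1]["event"].mean() > cohort[cohort.smoker == 0]["event"].mean()
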