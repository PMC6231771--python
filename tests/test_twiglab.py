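"""Unit tests for twig-experiment trait estimation and variance decomposition."""

import numpy as np
import pandas as pd
import pytest

from phenosync import climate, twiglab
from phenosync.exceptions import (
    DegenerateInputError,
    InvalidParameterError,
    MissingDataError,
)


class TestMeanLeafoutFirstK:
    def test_mean_of_eight_earliest(self):
        dates = np.array([3, 5, 7, 9, 11, 13, 15, 17, 19, 21], dtype=float)
        mean, complete = twiglab.mean_leafout_first_k(dates, k=8)
        assert mean == 10.0 and complete

    def test_identical_replicates(self):
        mean, complete = twiglab.mean_leafout_first_k(np.full(10, 42.0))
        assert mean == 42.0 and complete

    def test_fewer_than_k_flagged(self):
        dates = np.array([5, 6, 7, 8, 9, 10, np.nan, np.nan, np.nan, np.nan])
        mean, complete = twiglab.mean_leafout_first_k(dates, k=8)
        assert mean == 7.5 and not complete

    def test_no_leafout_is_missing_data(self):
        with pytest.raises(MissingDataError):
            twiglab.mean_leafout_first_k(np.array([np.nan, np.nan]))


class TestSensitivitySlopes:
    def test_daylength_slope(self):
        slope = twiglab.daylength_sensitivity(
            np.array([300.0, 250.0, 200.0]), np.array([8.0, 12.0, 16.0])
        )
        assert slope == pytest.approx(-12.5)

    def test_flat_response_is_insensitive(self):
        assert twiglab.daylength_sensitivity(
            np.full(3, 200.0), np.array([8.0, 12.0, 16.0])
        ) == pytest.approx(0.0)

    def test_twofold_requirement_under_short_days_is_negative_slope(self):
        # needing 2x the warming at 8 h vs 16 h: slope = -DD16/8 per hour
        dd16 = 180.0
        slope = twiglab.daylength_sensitivity(
            np.array([2 * dd16, dd16]), np.array([8.0, 16.0])
        )
        assert slope == pytest.approx(-dd16 / 8.0)

    def test_chilling_slope(self):
        slope = twiglab.chilling_sensitivity(
            np.array([400.0, 300.0, 200.0]), np.array([500.0, 1000.0, 1500.0])
        )
        assert slope == pytest.approx(-0.2)

    def test_single_level_rejected(self):
        with pytest.raises(DegenerateInputError):
            twiglab.daylength_sensitivity(np.array([1.0, 2.0]), np.array([8.0, 8.0]))

    def test_slope_invariant_to_constant_dd_shift(self):
        dd = np.array([310.0, 270.0, 240.0])
        hours = np.array([8.0, 12.0, 16.0])
        assert twiglab.daylength_sensitivity(dd, hours) == pytest.approx(
            twiglab.daylength_sensitivity(dd + 57.0, hours)
        )


def make_traits(n=11, seed=0):
    rng = np.random.default_rng(seed)
    return [
        climate.IndividualTraits(
            id=f"t{i:02d}",
            forcing_req=float(rng.normal(180, 25)),
            daylength_sensitivity=float(-rng.uniform(0, 25)),
            chilling_sensitivity=float(-rng.uniform(0, 0.08)),
        )
        for i in range(n)
    ]


class TestForcingRequirementAndTraitRecovery:
    def test_fully_released_cell_value(self):
        table = pd.DataFrame(
            {
                "individual_id": ["a"] * 3,
                "collection_chill_h": [500.0, 1000.0, 1500.0],
                "daylength_h": [16.0, 16.0, 16.0],
                "dd_at_leafout": [260.0, 220.0, 180.0],
            }
        )
        assert twiglab.forcing_requirement(table) == 180.0

    def test_missing_cell_is_error(self):
        table = pd.DataFrame(
            {
                "individual_id": ["a"],
                "collection_chill_h": [500.0],
                "daylength_h": [8.0],
                "dd_at_leafout": [260.0],
            }
        )
        with pytest.raises(MissingDataError):
            twiglab.forcing_requirement(table)

    def test_planted_forcing_requirement_recovered_from_noisy_twigs(self):
        traits = [climate.IndividualTraits(id="a", forcing_req=180.0)]
        table = twiglab.simulate_twig_experiment(
            traits, np.array([500.0, 1000.0, 1500.0]), noise_sd=5.0, seed=1
        )
        assert twiglab.forcing_requirement(table) == pytest.approx(180.0, abs=10.0)

    def test_trait_recovery_loop_correlates_planted_and_estimated(self):
        """Simulate from the trait model, re-estimate, correlate > 0.9."""
        traits = make_traits()
        table = twiglab.simulate_twig_experiment(
            traits, np.array([500.0, 1000.0, 1500.0]), noise_sd=3.0, seed=2
        )
        est = twiglab.estimate_traits(table)
        planted = pd.DataFrame(
            {
                "forcing_req": [t.forcing_req for t in traits],
                "daylength_sensitivity": [t.daylength_sensitivity for t in traits],
                "chilling_sensitivity": [t.chilling_sensitivity for t in traits],
            },
            index=[t.id for t in traits],
        )
        for col in planted.columns:
            r = np.corrcoef(planted[col], est.loc[planted.index, col])[0, 1]
            assert r > 0.9, col


class TestAnovaPartition:
    def orthogonal_design(self, seed=0, n=11):
        """Traits constructed orthogonal so sequential SS is order-free."""
        rng = np.random.default_rng(seed)
        f = np.linspace(-1, 1, n)
        d = np.sign(np.arange(n) % 2 - 0.5) * np.abs(f[::-1])
        d -= d @ f / (f @ f) * f
        c = rng.normal(size=n)
        for v in (f, d):
            c -= c @ v / (v @ v) * v
        traits = pd.DataFrame(
            {
                "forcing_req": f,
                "daylength_sensitivity": d,
                "chilling_sensitivity": c,
            },
            index=[f"t{i:02d}" for i in range(n)],
        )
        traits.index.name = "individual_id"
        return traits

    def response_from(self, traits, weights, noise_sd, seed, n_levels=2):
        rng = np.random.default_rng(seed)
        rows = []
        for level in range(n_levels):
            for ind, row in traits.iterrows():
                y = (
                    weights[0] * row["forcing_req"]
                    + weights[1] * row["daylength_sensitivity"]
                    + weights[2] * row["chilling_sensitivity"]
                    + rng.normal(0, noise_sd)
                )
                rows.append(
                    {
                        "individual_id": ind,
                        "collection_chill_h": 500.0 * (level + 1),
                        "leafout_doy": y,
                    }
                )
        return pd.DataFrame(rows)

    def test_single_cue_response_attributed_to_that_cue(self):
        traits = self.orthogonal_design()
        data = self.response_from(traits, (0.0, 1.0, 0.0), noise_sd=1e-8, seed=1)
        shares = twiglab.partition_variance_anova(data, traits)
        assert (shares["pct_daylength"] > 99.9).all()
        assert (shares["pct_residual"] < 0.1).all()

    def test_planted_orthogonal_mix_recovered(self):
        traits = self.orthogonal_design()
        # weights chosen so SS contributions are 50/30/20 along orthogonal,
        # equal-norm trait vectors
        norm = np.sqrt(
            (traits**2).sum()
        )
        w = np.sqrt(np.array([50.0, 30.0, 20.0])) / norm.to_numpy()
        data = self.response_from(traits, w, noise_sd=1e-9, seed=2)
        shares = twiglab.partition_variance_anova(data, traits)
        for got, want in zip(
            ["pct_forcing", "pct_daylength", "pct_chilling"], [50.0, 30.0, 20.0]
        ):
            assert shares[got].iloc[0] == pytest.approx(want, abs=5.0)

    def test_pure_noise_leaves_residual_dominant(self):
        traits = self.orthogonal_design()
        data = self.response_from(traits, (0.0, 0.0, 0.0), noise_sd=1.0, seed=3)
        shares = twiglab.partition_variance_anova(data, traits)
        assert (shares["pct_residual"] > 50.0).all()

    def test_shares_sum_to_100(self):
        traits = self.orthogonal_design()
        data = self.response_from(traits, (0.5, 0.3, 0.2), noise_sd=1.0, seed=4)
        shares = twiglab.partition_variance_anova(data, traits)
        total = (
            shares[["pct_forcing", "pct_daylength", "pct_chilling", "pct_residual"]]
            .sum(axis=1)
        )
        np.testing.assert_allclose(total, 100.0)


class TestVarianceComponents:
    def test_planted_shares_recovered(self):
        data = twiglab.simulate_nested_twigs(seed=5)
        comps = twiglab.variance_components(data)
        shares = comps.shares
        assert shares["individual"] == pytest.approx(52.0, abs=15.0)
        assert shares["treatment"] == pytest.approx(33.0, abs=15.0)
        assert shares["residual"] == pytest.approx(15.0, abs=8.0)
        assert sum(shares.values()) == pytest.approx(100.0)

    def test_zero_individual_variance(self):
        data = twiglab.simulate_nested_twigs(var_individual=0.0, seed=6)
        shares = twiglab.variance_components(data).shares
        assert shares["individual"] < 5.0

    def test_zero_residual_variance(self):
        data = twiglab.simulate_nested_twigs(var_residual=1e-12, seed=7)
        shares = twiglab.variance_components(data).shares
        assert shares["residual"] < 0.1

    def test_negative_moment_estimates_truncated_and_flagged(self):
        # no true individual effect and tiny replication noise often yields
        # a negative moment estimate; force it with an adversarial layout
        rng = np.random.default_rng(8)
        rows = []
        for t in range(4):
            for i in range(3):
                base = 10.0 * t
                for r in range(6):
                    rows.append(
                        {
                            "collection_chill_h": float(t),
                            "individual_id": f"i{i}",
                            "leafout_doy": base + rng.normal(0, 5.0),
                        }
                    )
        comps = twiglab.variance_components(pd.DataFrame(rows))
        if comps.truncated:
            assert comps.var_individual == 0.0 or comps.var_treatment == 0.0
        assert sum(comps.shares.values()) == pytest.approx(100.0)

    def test_design_requirements_enforced(self):
        data = twiglab.simulate_nested_twigs(n_treatments=1)
        with pytest.raises(InvalidParameterError):
            twiglab.variance_components(data)

    def test_matches_reml_on_balanced_design(self):
        """Independent oracle: lme4-style REML via statsmodels MixedLM."""
        import statsmodels.formula.api as smf

        data = twiglab.simulate_nested_twigs(seed=9)
        comps = twiglab.variance_components(data)
        data = data.assign(
            cell=data["collection_chill_h"].astype(str) + ":" + data["individual_id"]
        )
        md = smf.mixedlm(
            "leafout_doy ~ 1",
            data,
            groups=data["collection_chill_h"],
            re_formula="1",
            vc_formula={"ind": "0 + C(cell)"},
        ).fit(reml=True)
        reml_trt = float(md.cov_re.iloc[0, 0])
        reml_ind = float(md.vcomp[0])
        reml_res = float(md.scale)
        # balanced design: method-of-moments and REML agree closely
        assert comps.var_individual == pytest.approx(reml_ind, rel=0.15)
        assert comps.var_residual == pytest.approx(reml_res, rel=0.1)
        assert comps.var_treatment == pytest.approx(reml_trt, rel=0.35, abs=5.0)
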