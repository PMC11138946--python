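"""Experiment grid bookkeeping, descriptive statistics and regressions."""

import numpy as np
import pandas as pd
import pytest

from epibehave.experiment import (
    ALPHA_PAIRS,
    OneInflatedBeta,
    default_design,
    descriptive_stats,
    fit_summary_models,
    population_profiles,
    run_grid,
)

from conftest import make_synthetic_severity_table

SMALL = dict(profiles=("0", "D"), alpha_pairs=((1.0, 1.0), (0.1, 1.0)),
             beta0=(1.0,), pi=(0.5,), tau=(3.0,), kappa=(0.75, 0.9),
             horizon=120.0)


class TestDesign:
    def test_grid_cardinality(self):
        d = default_design()
        assert d.cell_size == 384              # 4 beta0 x 4 pi x 4 tau x 6 kappa
        assert len(d.alpha_pairs) == 10        # 4 homogeneous + 6 heterogeneous
        assert d.n_runs == 9 * 10 * 384
        # one in-group pair across all profiles spans 9 x 384 runs,
        # one profile across all pairs spans 10 x 384 runs
        assert default_design(alpha_pairs=((0.1, 0.1),)).n_runs == 3456
        assert default_design(profiles=("0",)).n_runs == 3840

    def test_alpha_pairs_unordered_from_levels(self):
        levels = {0.1, 1.0, 2.0, 3.0}
        assert len(set(ALPHA_PAIRS)) == 10
        for a, b in ALPHA_PAIRS:
            assert a in levels and b in levels and a <= b

    def test_delta_alpha_conventions(self):
        assert default_design().delta_alpha(0.1, 2.0) == pytest.approx(-1.9)
        rev = default_design(delta_alpha_convention="p1")
        assert rev.delta_alpha(0.1, 2.0) == pytest.approx(1.9)
        with pytest.raises(ValueError):
            default_design(delta_alpha_convention="x")

    def test_mixture_assigns_reference_to_low_standard_group(self):
        lo, hi = population_profiles("0xD", 0.1, 2.0)
        assert (lo.a, lo.e, lo.alpha) == (20.0, 0.0, 0.1)
        assert (hi.a, hi.e, hi.alpha) == (20.0, 10.0, 2.0)
        homo = population_profiles("A", 1.0, 1.0)
        assert homo[0] == homo[1]


class TestRunGrid:
    @pytest.fixture(scope="class")
    def small_rows(self):
        return run_grid(default_design(**SMALL))

    def test_row_count_and_schema(self, small_rows):
        d = default_design(**SMALL)
        assert len(small_rows) == d.n_runs == 2 * 2 * 2
        assert (small_rows["error"] == "").all()
        for col in ("profile", "alpha_m1", "delta_alpha", "n_secondary",
                    "peak_height", "final_size"):
            assert col in small_rows.columns

    def test_deterministic_rerun(self, small_rows):
        again = run_grid(default_design(**SMALL))
        pd.testing.assert_frame_equal(small_rows, again)

    def test_checkpoint_resume(self, small_rows, tmp_path):
        cp = tmp_path / "partial.csv"
        # seed the checkpoint with the first half of the rows
        small_rows.iloc[:4].to_csv(cp, index=False)
        resumed = run_grid(default_design(**SMALL), checkpoint=cp)
        pd.testing.assert_frame_equal(
            resumed.reset_index(drop=True), small_rows, check_dtype=False)
        assert len(pd.read_csv(cp)) == len(small_rows)


class TestDescriptiveStats:
    def test_layout_and_single_row_group(self):
        df = pd.DataFrame({
            "profile": ["0", "0", "A"],
            "alpha_m1": [0.1, 0.1, 1.0], "alpha_p1": [0.1, 1.0, 1.0],
            "epidemic": [True, True, False], "n_secondary": [1, 3, 0],
            "peak_time": [50.0, 60.0, 10.0], "peak_height": [100.0, 300.0, 2.0],
            "time_to_curb": [40.0, 50.0, np.nan], "final_size": [0.9, 0.8, 0.1],
            "error": ["", "", ""],
        })
        t = descriptive_stats(df, by="profile")
        assert ("Peak size", "Mean") in t.columns
        assert t.loc["A", ("Peak size", "Median")] == 2.0
        assert t.loc["A", ("Peak size", "Mean")] == 2.0
        assert t.loc["A", ("Peak size", "SD")] == 0.0
        assert t.loc["0", ("Nb2. waves", "Mean")] == 2.0
        # NaN time-to-curb excluded measure-wise
        assert t.loc["0", ("Time to curb", "Mean")] == 45.0
        t2 = descriptive_stats(df, by="alpha_pair")
        assert (0.1, 0.1) in t2.index


class TestSummaryModels:
    # kept in a range where the beta mean stays away from the unit
    # boundary, so the continuous and point-mass parts remain separable
    WAVES = {"Intercept": -2.0, "kappa": 2.5, "tau": -0.05,
             "alpha_m1": -0.5, "profile": {"A": 0.6}}
    PEAK = {"Intercept": 7.0, "beta0": 0.5, "kappa": -0.5, "pi": -0.7}
    FINAL = {"Intercept": 0.5, "beta0": 0.4, "kappa": -1.0, "pi": -1.0}

    @pytest.fixture(scope="class")
    def recovery(self):
        rng = np.random.default_rng(42)
        df = make_synthetic_severity_table(5000, rng, self.WAVES, self.PEAK,
                                           self.FINAL)
        return df, fit_summary_models(df)

    @pytest.mark.parametrize("model, coefs", [
        ("waves", WAVES), ("peak", PEAK), ("final_size", FINAL),
    ])
    def test_recovers_generating_coefficients(self, recovery, model, coefs):
        _, fits = recovery
        res = getattr(fits, model)
        params = pd.Series(np.asarray(res.params),
                           index=res.model.exog_names)
        bse = pd.Series(np.asarray(res.bse), index=res.model.exog_names)
        for term, true in coefs.items():
            if term == "profile":
                for pid, c in true.items():
                    name = f"C(profile, Treatment('0'))[T.{pid}]"
                    assert abs(params[name] - c) < 2 * bse[name]
            else:
                assert abs(params[term] - true) < 2 * bse[term]

    def test_diagnostics_reported(self, recovery):
        _, fits = recovery
        assert set(fits.pseudo_r2) == {"waves", "peak", "final_size"}
        assert all(0.0 <= v <= 1.0 for v in fits.pseudo_r2.values())
        assert fits.gof["waves"][1] > 0

    def test_constant_response_gives_zero_pseudo_r2(self):
        rng = np.random.default_rng(3)
        df = make_synthetic_severity_table(
            800, rng, {"Intercept": 0.0}, {"Intercept": 5.0}, {"Intercept": 1.0})
        df["n_secondary"] = 2
        fits = fit_summary_models(df)
        assert fits.pseudo_r2["waves"] == pytest.approx(0.0, abs=1e-8)

    def test_one_inflated_beta_reduces_to_beta_regression(self):
        """Without any unit responses the fit must agree with plain beta
        regression (independent statsmodels implementation)."""
        from statsmodels.othermod.betareg import BetaModel

        rng = np.random.default_rng(11)
        n = 2000
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        mu = 1 / (1 + np.exp(-(0.4 + 0.9 * X[:, 1])))
        y = np.clip(rng.beta(mu * 8, (1 - mu) * 8), 1e-6, 1 - 1e-6)
        ours = OneInflatedBeta(y, X).fit()
        ref = BetaModel(y, X, exog_precision=np.ones((n, 1))).fit(disp=0)
        np.testing.assert_allclose(np.asarray(ours.params)[:2],
                                   np.asarray(ref.params)[:2], rtol=1e-4)
        # precision parameter agrees on the log scale
        np.testing.assert_allclose(np.asarray(ours.params)[2],
                                   np.asarray(ref.params)[2], rtol=1e-3)

    def test_response_domain_checked(self):
        with pytest.raises(ValueError):
            OneInflatedBeta(np.array([0.5, 1.2]), np.ones((2, 1)))
        with pytest.raises(ValueError):
            OneInflatedBeta(np.array([0.0, 0.5]), np.ones((2, 1)))
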