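import numpy as np
import pandas as pd
import pytest

from nestphen.decomposition import (
    FULL_TERMS,
    CentredDesign,
    centre,
    fit_centred,
    fit_difference,
    fit_full,
    fit_lmm,
    fit_trend,
)
from nestphen.phenology_core import FemaleSeason

from conftest import make_crossed_panel


def _season(fid, year, fnd, ocf=2, ecf=2, exp=0, size=90.0):
    return FemaleSeason(fid, year, fnd, ocf, ecf, exp, size)


class TestCentre:
    def test_deviations_and_means(self):
        seasons = [
            _season("A", 2000, 150), _season("A", 2002, 148), _season("A", 2004, 146),
        ]
        sst = {2000: 18.0, 2002: 18.2, 2004: 18.4}
        design = centre(seasons, sst)
        assert design.data["d_t"].tolist() == [-2.0, 0.0, 2.0]
        # single female: her grand-centred mean year is 0
        assert design.data["mean_t"].tolist() == [0.0, 0.0, 0.0]
        assert design.grand_means["t"] == pytest.approx(2002.0)

    def test_single_observation_female(self):
        seasons = [_season("A", 2000, 150), _season("B", 2004, 140)]
        design = centre(seasons, {2000: 18.0, 2004: 18.4})
        assert (design.data[[f"d_{x}" for x in ("t", "sst", "be", "ecf", "size")]]
                .to_numpy() == 0).all()

    def test_missing_sst_year_named(self):
        with pytest.raises(ValueError, match="2004"):
            centre([_season("A", 2004, 150)], {2000: 18.0})

    def test_per_female_sums_and_grand_centring(self, default_design):
        df = default_design.data
        for col in ["d_t", "d_sst", "d_be", "d_ecf", "d_size"]:
            sums = df.groupby("female_id")[col].sum()
            assert np.abs(sums.to_numpy()).max() < 1e-9
        # mean of t̄ over females (not observations) is 0
        per_female = df.groupby("female_id")["mean_t"].first()
        assert per_female.mean() == pytest.approx(0.0, abs=1e-9)

    def test_sst_is_annual_covariate(self, default_design):
        df = default_design.data
        raw_sst = df["d_sst"] + df["mean_sst"]  # centred parts re-assemble
        assert (raw_sst.groupby(df["year"]).nunique() == 1).all()


class TestModelSequence:
    def test_noiseless_trend_exact(self):
        """FND an exact linear function of year -> OLS slope is exact."""
        pairs = [
            (f"F{i}", y)
            for i in range(12)
            for y in (2000 + (i % 3), 2005, 2010 - (i % 4))
        ]
        df = pd.DataFrame(
            {
                "female_id": [f for f, _ in pairs],
                "year": [y for _, y in pairs],
                "fnd": [200 - 0.6 * (y - 2000) for _, y in pairs],
            }
        )
        mean_t = df.groupby("female_id")["year"].transform("mean")
        grand = mean_t.groupby(df["female_id"]).first().mean()
        design = CentredDesign(
            data=df.assign(d_t=df["year"] - mean_t, mean_t=mean_t - grand)
        )
        fit = fit_trend(design, random_effects=False)
        assert fit.coef("t") == pytest.approx(-0.6, abs=1e-10)

    def test_reparameterization_identity(self, default_design):
        """M3 is an exact change of basis of M2 (OLS)."""
        m2 = fit_centred(default_design, random_effects=False)
        m3 = fit_difference(default_design, random_effects=False)
        assert abs(m3.coef("t") - m2.coef("d_t")) < 1e-8
        assert abs(m3.coef("mean_t") - (m2.coef("mean_t") - m2.coef("d_t"))) < 1e-8

    def test_balanced_within_slope_oracle(self):
        """On balanced data M2's Δt slope equals the pooled within-female
        OLS slope of (FND − female mean) on (t − t̄), computed independently."""
        rng = np.random.default_rng(0)
        rows = []
        for i in range(30):
            base = 2000 + int(rng.integers(0, 10))
            u = rng.normal(0, 5)
            for dt_ in (-1, 1):  # two observations per female
                rows.append((f"F{i}", base + dt_, 160 - 0.8 * (base + dt_ - 2005) + u + rng.normal(0, 3)))
        df = pd.DataFrame(rows, columns=["female_id", "year", "fnd"])
        mean_t = df.groupby("female_id")["year"].transform("mean")
        grand = mean_t.groupby(df["female_id"]).first().mean()
        design = CentredDesign(data=df.assign(d_t=df["year"] - mean_t, mean_t=mean_t - grand))
        m2 = fit_centred(design, random_effects=False)
        within_y = df["fnd"] - df.groupby("female_id")["fnd"].transform("mean")
        within_x = df["year"] - mean_t
        oracle = float(within_x @ within_y) / float(within_x @ within_x)
        assert m2.coef("d_t") == pytest.approx(oracle, abs=1e-10)

    def test_ols_matches_normal_equations(self, default_design):
        """Full OLS fit equals an independent normal-equations solve."""
        fit = fit_full(default_design, random_effects=False)
        X = default_design.matrix(FULL_TERMS)
        y = default_design.data["fnd"].to_numpy(dtype=float)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.abs(np.asarray(fit.estimates) - beta).max() < 1e-8

    def test_constant_shift_moves_only_intercept(self, default_design):
        base = fit_full(default_design, random_effects=False)
        shifted_df = default_design.data.copy()
        shifted_df["fnd"] += 100.0
        shifted = CentredDesign(data=shifted_df, grand_means=default_design.grand_means)
        fit = fit_full(shifted, random_effects=False)
        assert fit.coef("intercept") == pytest.approx(base.coef("intercept") + 100.0)
        for term in FULL_TERMS[1:]:
            assert fit.coef(term) == pytest.approx(base.coef(term), abs=1e-8)

    def test_rank_deficiency_names_terms(self):
        seasons = [
            _season("A", 2000, 150, exp=0), _season("A", 2002, 148, exp=0),
            _season("B", 2001, 149, exp=0), _season("B", 2003, 147, exp=0),
        ]
        design = centre(seasons, {y: 18.0 + 0.1 * (y - 2000) for y in range(2000, 2004)})
        with pytest.raises(ValueError, match="collinear"):
            fit_full(design, random_effects=False)  # experience constant at 0

    def test_too_few_years_rejected(self):
        seasons = [_season("A", 2000, 150), _season("B", 2001, 149)]
        design = centre(seasons, {2000: 18.0, 2001: 18.1})
        with pytest.raises(ValueError, match="years"):
            fit_trend(design, random_effects=False)


class TestCrossedLMM:
    def test_matches_lme4_oracle(self):
        """REML fit of the frozen panel reproduces lme4::lmer values.

        Oracle: lmer(fnd ~ mean_t + d_t + (1|female_id) + (1|year), REML)
        run once on the identical dataset (seed 42 panel).
        """
        design = CentredDesign(data=make_crossed_panel(42))
        fit = fit_lmm(("intercept", "mean_t", "d_t"), design, lrt=False)
        assert fit.estimates == pytest.approx(
            [155.5847063370, -0.6864468634, -0.8304895947], abs=2e-5
        )
        assert fit.se == pytest.approx(
            [1.3532222671, 0.8229420388, 0.1986666306], abs=2e-5
        )
        assert fit.vc["individual"] == pytest.approx(60.555561, abs=2e-3)
        assert fit.vc["year"] == pytest.approx(1.304353, abs=2e-3)
        assert fit.vc["residual"] == pytest.approx(14.734489, abs=2e-3)
        assert fit.loglik == pytest.approx(-331.4379068468, abs=1e-5)

    def test_ml_loglik_matches_lme4(self):
        from nestphen.decomposition import _CrossedLMM

        df = make_crossed_panel(42)
        design = CentredDesign(data=df)
        X = design.matrix(("intercept", "mean_t", "d_t"))
        y = df["fnd"].to_numpy(float)
        f = pd.Categorical(df["female_id"]).codes.astype(int)
        yr = pd.Categorical(df["year"]).codes.astype(int)
        ml = _CrossedLMM(y, X, f, yr).fit(reml=False)["loglik"]
        assert ml == pytest.approx(-332.6140297516, abs=1e-5)

    def test_zero_variance_limit_matches_ols(self):
        """Degenerate limit: with all planted variances zero the mixed fit
        collapses onto OLS and the variance estimates vanish."""
        df = make_crossed_panel(7)
        df["fnd"] = 160 - 0.7 * (df["mean_t"] + df["d_t"])  # exact, no noise
        design = CentredDesign(data=df)
        lmm = fit_lmm(("intercept", "mean_t", "d_t"), design, lrt=False)
        ols = fit_centred(design, random_effects=False)
        assert np.abs(np.asarray(lmm.estimates) - np.asarray(ols.estimates)).max() < 1e-4
        assert lmm.vc["individual"] < 1e-6
        assert lmm.vc["year"] < 1e-6

    def test_lrt_is_twice_ml_loglik_difference(self):
        from nestphen.decomposition import _CrossedLMM

        df = make_crossed_panel(42)
        design = CentredDesign(data=df)
        fit = fit_lmm(("intercept", "mean_t", "d_t"), design, lrt=True)
        X = design.matrix(("intercept", "mean_t", "d_t"))
        y = df["fnd"].to_numpy(float)
        f = pd.Categorical(df["female_id"]).codes.astype(int)
        yr = pd.Categorical(df["year"]).codes.astype(int)
        full = _CrossedLMM(y, X, f, yr).fit(reml=False)["loglik"]
        red = _CrossedLMM(y, np.delete(X, 2, axis=1), f, yr).fit(reml=False)["loglik"]
        stat = fit.stats.set_index("term").loc["d_t", "statistic"]
        assert stat == pytest.approx(2 * (full - red), abs=1e-6)

    def test_variance_recovery_at_scale(self, default_design):
        """Planted individual sd 8 / year sd 3 recovered at full size."""
        fit = fit_centred(default_design, random_effects=True)
        assert np.sqrt(fit.vc["individual"]) == pytest.approx(8.0, rel=0.5)
        assert np.sqrt(fit.vc["year"]) == pytest.approx(3.0, rel=0.5)

    def test_needs_two_levels_per_factor(self):
        df = make_crossed_panel(42)
        df["year"] = 2000
        with pytest.raises(ValueError, match="levels"):
            fit_lmm(("intercept", "d_t"), CentredDesign(data=df))
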