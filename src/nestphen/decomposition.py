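"""Within-subject centring and the model sequence separating levels of change.

The temporal trend in individual first nest date (FND) mixes two processes:
females changing their own behaviour across their careers (within-individual
change: plasticity, ageing) and the composition of the breeding population
changing (among-individual change: recruitment, selection). Within-subject
centring separates the two: each covariate x observed for female i in year t
is replaced by the female's own mean (x̄ᵢ, grand-centred across females) and
her deviation from it (Δx = x − x̄ᵢ). The model sequence is

* M1 ``FND ~ t``                 — the raw individual-level trend;
* M2 ``FND ~ t̄ + Δt``            — within (Δt) vs among (t̄) trend;
* M3 ``FND ~ t̄ + t``             — the t̄ slope is now the within−among
  difference (an exact reparameterization of M2);
* full ``FND ~ Δt + t̄ + Δx + x̄`` for each predictor x in {SST, breeding
  experience, estimated clutch frequency, size} — effect slopes at both
  levels, holding the others fixed.

Each model can be fitted by OLS (used by the attribution slope products, so
that contributions sum exactly) or as a linear mixed model with crossed
random intercepts for year and female (used for inference). The mixed fits
use a profiled REML criterion specialised to two crossed random-intercept
factors; likelihood-ratio tests per fixed term refit by ML.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from nestphen.phenology_core import FemaleSeason, seasons_to_frame

PREDICTORS = ("sst", "be", "ecf", "size")

#: fixed-term column order of the full model
FULL_TERMS = (
    "intercept",
    "d_t",
    "mean_t",
    "d_sst",
    "mean_sst",
    "d_be",
    "mean_be",
    "d_ecf",
    "mean_ecf",
    "d_size",
    "mean_size",
)


@dataclass(frozen=True)
class CentredDesign:
    """Per-observation centred design for the decomposition models.

    ``data`` has one row per female-season with columns: female_id, year,
    fnd, d_t, mean_t, and d_<x> / mean_<x> for each predictor. ``mean_*``
    columns are grand-centred so that their mean over *females* (each female
    counted once) is zero; per-female Δ columns sum to zero exactly.
    """

    data: pd.DataFrame
    grand_means: dict[str, float] = field(default_factory=dict)

    @property
    def n_obs(self) -> int:
        return len(self.data)

    @property
    def n_females(self) -> int:
        return self.data["female_id"].nunique()

    def matrix(self, terms: tuple[str, ...]) -> np.ndarray:
        cols = []
        for t in terms:
            if t == "intercept":
                cols.append(np.ones(len(self.data)))
            else:
                cols.append(self.data[t].to_numpy(dtype=float))
        return np.column_stack(cols)


@dataclass(frozen=True)
class ModelFit:
    """One regression fit: coefficients, tests and variance components."""

    terms: tuple[str, ...]
    estimates: np.ndarray
    se: np.ndarray
    loglik: float
    method: str  # "ols" | "reml"
    n_obs: int
    stats: pd.DataFrame  # per-term statistic and p-value
    vc: dict[str, float] = field(default_factory=dict)  # year/individual/residual

    def coef(self, term: str) -> float:
        return float(self.estimates[self.terms.index(term)])

    def coef_se(self, term: str) -> float:
        return float(self.se[self.terms.index(term)])

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.vc.values()):
            raise ValueError("variance components must be non-negative")


def centre(
    seasons: list[FemaleSeason] | pd.DataFrame,
    sst_by_year: pd.DataFrame | dict[int, float],
) -> CentredDesign:
    """Build the centred design from female-season metrics and annual SST.

    ``sst_by_year`` maps year -> window-mean SST (°C); every season year must
    be present. The year covariate stays in calendar units, so slopes read as
    days per year. Single-observation females get Δ = 0 for every covariate.
    """
    df = seasons if isinstance(seasons, pd.DataFrame) else seasons_to_frame(seasons)
    if isinstance(sst_by_year, pd.DataFrame):
        cols = list(sst_by_year.columns)
        sst_map = dict(
            zip(sst_by_year[cols[0]].astype(int), sst_by_year[cols[1]].astype(float))
        )
    else:
        sst_map = {int(k): float(v) for k, v in sst_by_year.items()}
    missing = sorted(set(df["year"].astype(int)) - set(sst_map))
    if missing:
        raise ValueError(f"no SST value for year(s): {missing}")

    out = pd.DataFrame(
        {
            "female_id": df["female_id"].astype(str),
            "year": df["year"].astype(int),
            "fnd": df["first_nest_doy"].astype(float),
        }
    )
    raw = {
        "t": out["year"].astype(float),
        "sst": out["year"].map(sst_map).astype(float),
        "be": df["experience"].astype(float).to_numpy(),
        "ecf": df["estimated_cf"].astype(float).to_numpy(),
        "size": df["mean_size_cm"].astype(float).to_numpy(),
    }
    if np.isnan(raw["size"]).any():
        raise ValueError("mean_size_cm is missing for some seasons; cannot centre")

    grand_means: dict[str, float] = {}
    for name, values in raw.items():
        v = pd.Series(np.asarray(values, dtype=float), index=out.index)
        female_mean = v.groupby(out["female_id"]).transform("mean")
        grand = float(female_mean.groupby(out["female_id"]).first().mean())
        grand_means[name] = grand
        out[f"d_{name}"] = v - female_mean
        out[f"mean_{name}"] = female_mean - grand
    return CentredDesign(data=out, grand_means=grand_means)


# ---------------------------------------------------------------------------
# OLS fits


def _ols_fit(design: CentredDesign, terms: tuple[str, ...]) -> ModelFit:
    X = design.matrix(terms)
    _check_rank(X, terms)
    y = design.data["fnd"].to_numpy(dtype=float)
    res = sm.OLS(y, X).fit()
    table = pd.DataFrame(
        {"term": terms, "statistic": res.tvalues, "p_value": res.pvalues, "df": res.df_resid}
    )
    return ModelFit(
        terms=terms,
        estimates=np.asarray(res.params),
        se=np.asarray(res.bse),
        loglik=float(res.llf),
        method="ols",
        n_obs=len(y),
        stats=table,
    )


def _check_rank(X: np.ndarray, terms: tuple[str, ...]) -> None:
    """Reject rank-deficient designs, naming the collinear columns."""
    r = np.linalg.qr(X, mode="r")
    diag = np.abs(np.diag(r))
    bad = diag < 1e-8 * max(diag.max(), 1.0)
    if bad.any():
        names = [terms[i] for i in np.flatnonzero(bad)]
        raise ValueError(f"design is rank deficient; collinear terms: {names}")


def fit_trend(design: CentredDesign, random_effects: bool = True) -> ModelFit:
    """M1: FND ~ year. The slope is the raw individual-level trend (d/yr)."""
    if design.data["year"].nunique() < 3:
        raise ValueError("need at least 3 distinct years to fit a trend")
    terms = ("intercept", "t")
    design = _with_raw_t(design)
    return fit_lmm(terms, design) if random_effects else _ols_fit(design, terms)


def fit_centred(design: CentredDesign, random_effects: bool = True) -> ModelFit:
    """M2: FND ~ t̄ + Δt — within- (Δt) and among-individual (t̄) trends."""
    terms = ("intercept", "mean_t", "d_t")
    return fit_lmm(terms, design) if random_effects else _ols_fit(design, terms)


def fit_difference(design: CentredDesign, random_effects: bool = True) -> ModelFit:
    """M3: FND ~ t̄ + t — the t̄ slope is (among − within), t is within.

    Exact reparameterization of M2: t = t̄ + Δt, so the t coefficient equals
    M2's Δt coefficient and the t̄ coefficient equals M2's (t̄ − Δt).
    """
    terms = ("intercept", "mean_t", "t")
    design = _with_raw_t(design)
    return fit_lmm(terms, design) if random_effects else _ols_fit(design, terms)


def fit_full(design: CentredDesign, random_effects: bool = True) -> ModelFit:
    """Full model: FND ~ Δt + t̄ + Δx + x̄ for all four predictors.

    With ``random_effects=False`` this is the attribution model whose slopes
    enter the contribution products; with ``True`` it is the inference model.
    """
    terms = FULL_TERMS
    return fit_lmm(terms, design) if random_effects else _ols_fit(design, terms)


def _with_raw_t(design: CentredDesign) -> CentredDesign:
    """Expose raw year under the column name 't' (centred on the grand mean).

    M1/M3 use the year covariate directly; it is shifted by the same grand
    mean used for t̄ so that t = t̄ + Δt holds column-wise exactly.
    """
    if "t" in design.data.columns:
        return design
    df = design.data.copy()
    df["t"] = df["mean_t"] + df["d_t"]
    return CentredDesign(data=df, grand_means=design.grand_means)


# ---------------------------------------------------------------------------
# Crossed random-intercepts REML


class _CrossedLMM:
    """Profiled (RE)ML for y = Xβ + Z_f u + Z_y v + ε with u, v, ε iid normal.

    Parameterized by the variance ratios γ = (σ_f², σ_y²)/σ²; β and σ² are
    profiled out analytically, and all per-evaluation algebra runs on q×q
    matrices (q = #females + #years) via the Woodbury identity, never on n×n.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, f_codes: np.ndarray, y_codes: np.ndarray):
        self.n, self.p = X.shape
        self.qf = int(f_codes.max()) + 1
        self.qy = int(y_codes.max()) + 1
        # Z'Z in block form: [[diag(cf), N], [N', diag(cy)]] with N the
        # female x year incidence counts — the female block stays diagonal,
        # so every solve Schur-complements onto the (small) year block.
        self.cf = np.bincount(f_codes, minlength=self.qf).astype(float)
        self.cy = np.bincount(y_codes, minlength=self.qy).astype(float)
        self.N = np.zeros((self.qf, self.qy))
        np.add.at(self.N, (f_codes, y_codes), 1.0)
        W = np.column_stack([X, y])
        self.ZfW = np.zeros((self.qf, self.p + 1))
        np.add.at(self.ZfW, f_codes, W)
        self.ZyW = np.zeros((self.qy, self.p + 1))
        np.add.at(self.ZyW, y_codes, W)
        self.WtW = W.T @ W

    def _profile(self, gamma: np.ndarray) -> dict:
        """β̂, rss, log|V0| and log|XᵀV0⁻¹X| at fixed variance ratios.

        Uses the Woodbury identity U'V0⁻¹W = U'W − (Z'U)'(D⁻¹+Z'Z)⁻¹(Z'W) and
        |V0| = |D⁻¹+Z'Z|·|D|, with the (D⁻¹+Z'Z) solve done blockwise.
        """
        gf, gy = float(gamma[0]), float(gamma[1])
        # quadratic-form corrections accumulated into W'V0^-1 W
        WtVW = self.WtW.copy()
        logdet_v0 = 0.0
        if gf > 0 and gy > 0:
            af = 1.0 / gf + self.cf  # diagonal of the female block
            S = np.diag(1.0 / gy + self.cy) - (self.N / af[:, None]).T @ self.N
            Ls = np.linalg.cholesky(S)
            bf, by = self.ZfW, self.ZyW
            u = by - self.N.T @ (bf / af[:, None])
            xy = np.linalg.solve(Ls.T, np.linalg.solve(Ls, u))
            xf = (bf - self.N @ xy) / af[:, None]
            WtVW -= bf.T @ xf + by.T @ xy
            logdet_v0 = (
                float(np.log(af).sum()) + 2.0 * float(np.log(np.diag(Ls)).sum())
                + self.qf * np.log(gf) + self.qy * np.log(gy)
            )
        elif gf > 0:
            af = 1.0 / gf + self.cf
            WtVW -= self.ZfW.T @ (self.ZfW / af[:, None])
            logdet_v0 = float(np.log(af).sum()) + self.qf * np.log(gf)
        elif gy > 0:
            ay = 1.0 / gy + self.cy
            WtVW -= self.ZyW.T @ (self.ZyW / ay[:, None])
            logdet_v0 = float(np.log(ay).sum()) + self.qy * np.log(gy)
        XtVX = WtVW[: self.p, : self.p]
        XtVy = WtVW[: self.p, self.p]
        ytVy = float(WtVW[self.p, self.p])
        Lx = np.linalg.cholesky(XtVX)
        beta = np.linalg.solve(Lx.T, np.linalg.solve(Lx, XtVy))
        rss = max(ytVy - float(XtVy @ beta), 1e-12)
        logdet_xvx = 2.0 * float(np.log(np.diag(Lx)).sum())
        return {
            "beta": beta,
            "rss": rss,
            "logdet_v0": logdet_v0,
            "logdet_xvx": logdet_xvx,
            "XtVX": XtVX,
        }

    def neg2_reml(self, gamma: np.ndarray) -> float:
        pr = self._profile(gamma)
        ndf = self.n - self.p
        s2 = pr["rss"] / ndf
        return (
            ndf * np.log(s2)
            + pr["logdet_v0"]
            + pr["logdet_xvx"]
            + ndf * (1.0 + np.log(2 * np.pi))
        )

    def neg2_ml(self, gamma: np.ndarray) -> float:
        pr = self._profile(gamma)
        s2 = pr["rss"] / self.n
        return self.n * np.log(s2) + pr["logdet_v0"] + self.n * (1.0 + np.log(2 * np.pi))

    def fit(self, reml: bool = True, maxiter: int = 500, tol: float = 1e-8) -> dict:
        """Minimize the profiled −2·log-lik over the two variance ratios.

        Nelder–Mead on the log-ratio scale (the surface is smooth and
        2-dimensional; derivative-free search avoids numeric-gradient noise
        near the γ = 0 boundary), with the boundary itself — either or both
        ratios exactly zero — scored as explicit candidates.
        """
        obj = self.neg2_reml if reml else self.neg2_ml
        nm_opts = {"xatol": 1e-8, "fatol": 1e-9, "maxiter": 4 * maxiter,
                   "maxfev": 8 * maxiter}
        candidates: list[tuple[float, np.ndarray, bool]] = []
        for start in ([np.log(0.5), np.log(0.05)], [np.log(2.0), np.log(0.5)]):
            res = optimize.minimize(
                lambda th: obj(np.exp(th)), start, method="Nelder-Mead",
                options=nm_opts,
            )
            candidates.append((float(res.fun), np.exp(res.x), bool(res.success)))
        for free in (0, 1):  # one component pinned at zero

            def obj1(th, free=free):
                g = np.zeros(2)
                g[free] = np.exp(th[0])
                return obj(g)

            res = optimize.minimize(obj1, [0.0], method="Nelder-Mead", options=nm_opts)
            g = np.zeros(2)
            g[free] = float(np.exp(res.x[0]))
            candidates.append((float(res.fun), g, bool(res.success)))
        candidates.append((float(obj(np.zeros(2))), np.zeros(2), True))

        candidates = [c for c in candidates if np.isfinite(c[0])]
        if not candidates:
            raise RuntimeError("mixed-model optimization failed: no finite objective")
        fun, gamma, converged = min(candidates, key=lambda c: c[0])
        # a successful run at the optimum, or two independent searches
        # agreeing there, both certify convergence
        at_opt = [c for c in candidates if c[0] <= fun + max(1e-6, 1e-9 * abs(fun))]
        converged = converged or any(s for _, _, s in at_opt) or len(at_opt) >= 2
        message = "" if converged else "optimizer iteration limit reached"
        pr = self._profile(gamma)
        ndf = self.n - self.p if reml else self.n
        s2 = pr["rss"] / ndf
        cov = s2 * np.linalg.inv(pr["XtVX"])
        return {
            "gamma": gamma,
            "beta": pr["beta"],
            "se": np.sqrt(np.diag(cov)),
            "sigma2": s2,
            "sigma2_f": gamma[0] * s2,
            "sigma2_y": gamma[1] * s2,
            "loglik": -0.5 * fun,
            "converged": converged,
            "message": message,
        }


def fit_lmm(
    terms: tuple[str, ...],
    design: CentredDesign,
    reml: bool = True,
    lrt: bool = True,
) -> ModelFit:
    """Linear mixed model with crossed year and female random intercepts.

    REML point estimates and standard errors; per-term likelihood-ratio
    chi-square tests (df = 1) from ML refits with and without each term.
    """
    df = design.data
    for col, label in (("female_id", "female"), ("year", "year")):
        if df[col].nunique() < 2:
            raise ValueError(f"random factor {label!r} needs >= 2 levels")
    X = design.matrix(terms)
    _check_rank(X, terms)
    y = df["fnd"].to_numpy(dtype=float)
    f_codes = pd.Categorical(df["female_id"]).codes.astype(int)
    y_codes = pd.Categorical(df["year"]).codes.astype(int)

    model = _CrossedLMM(y, X, f_codes, y_codes)
    res = model.fit(reml=reml)
    if not res["converged"]:
        raise RuntimeError(f"REML did not converge: {res['message']}")

    rows = []
    if lrt:
        full_ml = _CrossedLMM(y, X, f_codes, y_codes).fit(reml=False)["loglik"]
        for j, term in enumerate(terms):
            if term == "intercept":
                rows.append((term, np.nan, np.nan))
                continue
            Xr = np.delete(X, j, axis=1)
            red_ml = _CrossedLMM(y, Xr, f_codes, y_codes).fit(reml=False)["loglik"]
            chi2 = max(2.0 * (full_ml - red_ml), 0.0)
            rows.append((term, chi2, float(stats.chi2.sf(chi2, df=1))))
    else:
        rows = [(t, np.nan, np.nan) for t in terms]
    table = pd.DataFrame(rows, columns=["term", "statistic", "p_value"])
    table["df"] = 1

    return ModelFit(
        terms=terms,
        estimates=res["beta"],
        se=res["se"],
        loglik=res["loglik"],
        method="reml" if reml else "ml",
        n_obs=len(y),
        stats=table,
        vc={
            "individual": float(res["sigma2_f"]),
            "year": float(res["sigma2_y"]),
            "residual": float(res["sigma2"]),
        },
    )


def fit_to_dict(fit: ModelFit) -> dict:
    """JSON-serializable view of a ModelFit."""
    return {
        "terms": list(fit.terms),
        "estimates": [float(v) for v in fit.estimates],
        "se": [float(v) for v in fit.se],
        "loglik": float(fit.loglik),
        "method": fit.method,
        "n_obs": int(fit.n_obs),
        "stats": fit.stats.replace({np.nan: None}).to_dict(orient="records"),
        "vc": {k: float(v) for k, v in fit.vc.items()},
    }
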