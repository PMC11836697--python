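"""Slope-product attribution of the trend in first nest date.

Each predictor x (SST, breeding experience, estimated clutch frequency,
size) contributes to the temporal trend in first nest date in proportion to
(how fast x itself changes over time) × (how strongly x shifts first nest
date). Both factors are estimated at the within-individual level (Δx on Δt;
FND on Δx) and the among-individual level (x̄ on t̄; FND on x̄); their product
is the change in FND per year attributable to x at that level, and the
contributions plus an unexplained remainder sum to the total trend from the
predictor-free model (FND ~ t̄ + Δt).

Trend regressions run one row per observation (female-season), matching the
reported degrees of freedom of the study design this mirrors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from nestphen.decomposition import PREDICTORS, CentredDesign, ModelFit

LEVELS = ("within", "among")


@dataclass(frozen=True)
class ContributionTable:
    """Per-predictor slope pairs, products, totals and remainders.

    ``slopes`` maps (level, predictor) -> (trend_slope, trend_se,
    effect_slope, effect_se); ses are NaN when slopes were supplied
    externally rather than fitted. ``totals`` maps level -> total trend in
    first nest date (d/yr) from the predictor-free model. ``direct_residual``
    carries the full model's own Δt / t̄ coefficient, an alternative estimate
    of the unexplained trend.
    """

    slopes: dict[tuple[str, str], tuple[float, float, float, float]]
    totals: dict[str, float]
    direct_residual: dict[str, float] = field(default_factory=dict)

    def contribution(self, level: str, predictor: str) -> float:
        trend, _, effect, _ = self.slopes[(level, predictor)]
        return trend * effect

    def contributions(self, level: str) -> dict[str, float]:
        return {x: self.contribution(level, x) for x in PREDICTORS}

    def residual(self, level: str) -> float:
        """Unexplained trend: total minus the sum of contributions."""
        return self.totals[level] - sum(self.contributions(level).values())

    def percentage(self, level: str, predictor: str) -> float:
        """Share of the total trend (%, from unrounded products)."""
        return 100.0 * self.contribution(level, predictor) / self.totals[level]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for level in LEVELS:
            for x in PREDICTORS:
                trend, trend_se, effect, effect_se = self.slopes[(level, x)]
                rows.append(
                    {
                        "level": level,
                        "predictor": x,
                        "trend_slope": trend,
                        "trend_se": trend_se,
                        "effect_slope": effect,
                        "effect_se": effect_se,
                        "contribution": trend * effect,
                        "pct_of_total": self.percentage(level, x),
                        "level_total": self.totals[level],
                        "level_residual": self.residual(level),
                    }
                )
        return pd.DataFrame(rows)


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.ptp(x) == 0:
        raise ValueError("predictor has zero variance; cannot fit trend")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return float(res.params[1]), float(res.bse[1])


def predictor_trends(
    design: CentredDesign,
) -> dict[tuple[str, str], tuple[float, float]]:
    """Temporal trend of each predictor at both levels.

    Simple OLS regressions over all observations: Δx on Δt (within) and
    grand-centred x̄ on t̄ (among). Returns (level, predictor) -> (slope, se).
    """
    df = design.data
    d_t = df["d_t"].to_numpy(dtype=float)
    mean_t = df["mean_t"].to_numpy(dtype=float)
    out: dict[tuple[str, str], tuple[float, float]] = {}
    for x in PREDICTORS:
        out[("within", x)] = _ols_slope(d_t, df[f"d_{x}"].to_numpy(dtype=float))
        out[("among", x)] = _ols_slope(mean_t, df[f"mean_{x}"].to_numpy(dtype=float))
    return out


def contribution(trend_slope: float, effect_slope: float) -> float:
    """Change in first nest date (d/yr) attributable to one predictor.

    The product of the predictor's own temporal trend (units/yr) and its
    effect on first nest date (d/unit).
    """
    if not (np.isfinite(trend_slope) and np.isfinite(effect_slope)):
        raise ValueError("slope inputs must be finite")
    return trend_slope * effect_slope


def build_table(
    design: CentredDesign,
    base_fit: ModelFit,
    full_fit: ModelFit,
) -> ContributionTable:
    """Assemble the contribution table from fitted models.

    ``base_fit`` is the predictor-free centred model (FND ~ t̄ + Δt) giving
    the level totals; ``full_fit`` is the all-predictor OLS model giving the
    effect slopes. Both must have been fitted on ``design``.
    """
    for fit, needed in ((base_fit, ("d_t", "mean_t")), (full_fit, ("d_sst", "mean_size"))):
        if fit.n_obs != design.n_obs or any(t not in fit.terms for t in needed):
            raise ValueError("fits do not match the supplied design")
    trends = predictor_trends(design)
    slopes = {}
    for level, prefix in (("within", "d"), ("among", "mean")):
        for x in PREDICTORS:
            trend, trend_se = trends[(level, x)]
            term = f"{prefix}_{x}"
            slopes[(level, x)] = (trend, trend_se, full_fit.coef(term), full_fit.coef_se(term))
    totals = {"within": base_fit.coef("d_t"), "among": base_fit.coef("mean_t")}
    direct = {"within": full_fit.coef("d_t"), "among": full_fit.coef("mean_t")}
    return ContributionTable(slopes=slopes, totals=totals, direct_residual=direct)


def table_from_slopes(
    slopes: dict[tuple[str, str], tuple[float, float]],
    totals: dict[str, float],
) -> ContributionTable:
    """Build a table from externally supplied (trend, effect) slope pairs.

    ``slopes`` maps (level, predictor) -> (trend_slope, effect_slope); used
    for worked examples reproducing published decompositions without any
    fitting. Standard errors are recorded as NaN.
    """
    full = {
        key: (trend, float("nan"), effect, float("nan"))
        for key, (trend, effect) in slopes.items()
    }
    return ContributionTable(slopes=full, totals=dict(totals))


def read_slopes_csv(path) -> ContributionTable:
    """Read a slope-pair CSV (columns level,predictor,trend_slope,effect_slope,
    level_total; the total may be given on any row of its level)."""
    df = pd.read_csv(path)
    slopes = {
        (str(r.level), str(r.predictor)): (float(r.trend_slope), float(r.effect_slope))
        for r in df.itertuples(index=False)
    }
    totals = {}
    for level, grp in df.groupby("level"):
        vals = grp["level_total"].dropna().unique()
        if len(vals) != 1:
            raise ValueError(f"level {level!r} needs exactly one level_total value")
        totals[str(level)] = float(vals[0])
    return table_from_slopes(slopes, totals)


_LABELS = {
    "sst": "sea surface temperature",
    "be": "breeding experience",
    "ecf": "estimated clutch frequency",
    "size": "size",
}


def render_decomposition(table: ContributionTable, pie_path=None) -> str:
    """Human-readable decomposition report; optionally draws pie charts.

    Percentage shares are computed from unrounded products and rounded only
    here, at display time.
    """
    lines = []
    for level in LEVELS:
        total = table.totals[level]
        lines.append(f"{level}-individual change in first nest date: {total:+.2f} d/yr")
        for x in PREDICTORS:
            trend, _, effect, _ = table.slopes[(level, x)]
            c = table.contribution(level, x)
            lines.append(
                f"  {_LABELS[x]:<28s} trend {trend:+.4g}/yr x effect {effect:+.4g} d"
                f" = {c:+.2f} d/yr ({table.percentage(level, x):.0f}%)"
            )
        res = table.residual(level)
        lines.append(
            f"  {'unexplained':<28s} {res:+.2f} d/yr ({100 * res / total:.0f}%)"
        )
        if level in table.direct_residual:
            lines.append(
                f"  (full-model direct {level} year coefficient:"
                f" {table.direct_residual[level]:+.2f} d/yr)"
            )
    report = "\n".join(lines)
    if pie_path is not None:
        _draw_pies(table, pie_path)
    return report


def _draw_pies(table: ContributionTable, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4.5))
    for ax, level in zip(axes, LEVELS):
        parts = {**{_LABELS[x]: table.contribution(level, x) for x in PREDICTORS},
                 "unexplained": table.residual(level)}
        sizes = np.abs(list(parts.values()))
        if sizes.sum() == 0:
            sizes = np.ones(len(parts))
        ax.pie(sizes, labels=list(parts), autopct="%.0f%%", startangle=90)
        ax.set_title(f"{level}-individual ({table.totals[level]:+.2f} d/yr)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
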