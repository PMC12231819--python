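"""Group-comparison decision tree: assumption checks, test selection,
post-hocs, and significance/trend labelling.

Routing mirrors common practice for small-cohort biomarker studies:

* Shapiro-Wilk on model residuals (alpha = 0.05) gates normality; failure
  routes to Kruskal-Wallis with Dunn post-hocs (Holm-adjusted).
* Levene's test (median-centred, alpha = 0.05) gates homoscedasticity;
  failure with normality intact routes to Welch's ANOVA with Games-Howell
  post-hocs.
* Otherwise a one-way ANOVA (or two-way with sex as a fixed factor, when
  sex labels are supplied) with Tukey-HSD post-hocs.

Labels: p <= 0.05 is "significant"; 0.05 < p <= 0.09 is a "trend";
anything larger is "ns".
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["StatResult", "choose_and_run", "posthoc", "label_p",
           "dunn_posthoc", "chi_square_counts"]

ALPHA_SIG = 0.05
TREND_HI = 0.09


def label_p(p: float) -> str:
    if p <= ALPHA_SIG:
        return "significant"
    if p <= TREND_HI:
        return "trend"
    return "ns"


@dataclass
class StatResult:
    outcome: str
    design: str            # oneway | twoway_sex | kruskal
    statistic: float
    df: tuple
    p: float
    label: str
    welch: bool = False    # Welch correction applied on the parametric path
    shapiro_p: float = np.nan
    levene_p: float = np.nan
    posthoc: list = field(default_factory=list)  # (pair, p_adj, method)

    def to_row(self) -> dict:
        return {
            "outcome": self.outcome, "design": self.design,
            "welch": self.welch, "statistic": self.statistic,
            "df": "/".join(f"{d:.4g}" for d in self.df), "p": self.p,
            "label": self.label, "shapiro_p": self.shapiro_p,
            "levene_p": self.levene_p,
        }


def _group_arrays(values, groups):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    names = sorted(pd.unique(groups), key=str)
    arrs = [values[groups == g] for g in names]
    if len(names) < 2:
        raise ValueError("need at least two groups")
    if min(len(a) for a in arrs) < 3:
        raise ValueError("need at least three subjects per group")
    return values, groups, names, arrs


def choose_and_run(values, groups, sex=None, outcome: str = "",
                   gate_alpha: float = 0.05, run_posthoc: bool = True) -> StatResult:
    """Run the assumption-gated omnibus test for one outcome.

    Residuals are taken about the cell means (group, or group x sex when a
    sex factor is supplied).  The chosen path, gate p-values and post-hoc
    results are all recorded on the returned :class:`StatResult`.
    """
    values, groups, names, arrs = _group_arrays(values, groups)

    if sex is not None:
        sex = np.asarray(sex)
        cells = pd.Series(values).groupby([pd.Series(groups), pd.Series(sex)])
        resid = values - cells.transform("mean").to_numpy()
    else:
        resid = values - pd.Series(values).groupby(pd.Series(groups)).transform(
            "mean").to_numpy()

    shapiro_p = float(sps.shapiro(resid).pvalue)
    levene_p = float(sps.levene(*arrs, center="median").pvalue)
    normal = shapiro_p >= gate_alpha
    homosked = levene_p >= gate_alpha

    if not normal:
        stat, p = sps.kruskal(*arrs)
        res = StatResult(outcome, "kruskal", float(stat), (len(names) - 1,),
                         float(p), label_p(p), shapiro_p=shapiro_p,
                         levene_p=levene_p)
    elif not homosked:
        import pingouin as pg

        aov = pg.welch_anova(
            data=pd.DataFrame({"y": values, "g": groups}), dv="y", between="g")
        stat = float(aov["F"].iloc[0])
        p = float(aov["p_unc"].iloc[0])
        df = (float(aov["ddof1"].iloc[0]), float(aov["ddof2"].iloc[0]))
        res = StatResult(outcome, "oneway", stat, df, p, label_p(p),
                         welch=True, shapiro_p=shapiro_p, levene_p=levene_p)
    elif sex is not None:
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        df_in = pd.DataFrame({"y": values, "g": groups, "s": sex})
        model = ols("y ~ C(g) * C(s)", data=df_in).fit()
        table = sm.stats.anova_lm(model, typ=2)
        stat = float(table.loc["C(g)", "F"])
        p = float(table.loc["C(g)", "PR(>F)"])
        df = (float(table.loc["C(g)", "df"]), float(table.loc["Residual", "df"]))
        res = StatResult(outcome, "twoway_sex", stat, df, p, label_p(p),
                         shapiro_p=shapiro_p, levene_p=levene_p)
    else:
        stat, p = sps.f_oneway(*arrs)
        df = (len(names) - 1, len(values) - len(names))
        res = StatResult(outcome, "oneway", float(stat), df, float(p),
                         label_p(p), shapiro_p=shapiro_p, levene_p=levene_p)

    if run_posthoc:
        res.posthoc = posthoc(values, groups, res.design, welch=res.welch)
    return res


def posthoc(values, groups, design: str, welch: bool = False) -> list:
    """Pairwise post-hocs matched to the omnibus design.

    Tukey HSD after plain (one- or two-way) ANOVA; Games-Howell after
    Welch's ANOVA; Dunn with Holm adjustment after Kruskal-Wallis.
    Returns ``[(("g1", "g2"), p_adj, method), ...]``.
    """
    values, groups, names, arrs = _group_arrays(values, groups)
    if design == "kruskal":
        return dunn_posthoc(values, groups)
    if design in ("oneway", "twoway_sex"):
        if welch:
            import pingouin as pg

            gh = pg.pairwise_gameshowell(
                data=pd.DataFrame({"y": values, "g": groups}), dv="y", between="g")
            return [((str(r["A"]), str(r["B"])), float(r["pval"]), "games-howell")
                    for _, r in gh.iterrows()]
        res = sps.tukey_hsd(*arrs)
        return [((names[a], names[b]), float(res.pvalue[a, b]), "tukey")
                for a, b in itertools.combinations(range(len(names)), 2)]
    raise ValueError(f"unknown design {design!r}")


def dunn_posthoc(values, groups) -> list:
    """Dunn's rank-based z-tests with Holm step-down adjustment.

    Uses the tie-corrected variance ``(N(N+1)/12 - sum(t^3 - t)/(12(N-1)))``
    of mean-rank differences.
    """
    from statsmodels.stats.multitest import multipletests

    values, groups, names, _ = _group_arrays(values, groups)
    ranks = sps.rankdata(values)
    n_tot = len(values)
    _, counts = np.unique(values, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (12.0 * (n_tot - 1))
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term
    mean_rank = {g: ranks[groups == g].mean() for g in names}
    n_g = {g: int((groups == g).sum()) for g in names}
    pairs = list(itertools.combinations(names, 2))
    p_raw = []
    for a, b in pairs:
        se = np.sqrt(var_base * (1.0 / n_g[a] + 1.0 / n_g[b]))
        z = (mean_rank[a] - mean_rank[b]) / se
        p_raw.append(2.0 * sps.norm.sf(abs(z)))
    p_adj = multipletests(p_raw, method="holm")[1]
    return [((a, b), float(p), "dunn-holm") for (a, b), p in zip(pairs, p_adj)]


def chi_square_counts(contingency: np.ndarray) -> tuple[float, float]:
    """Chi-square test of independence for a counts table (nominal data)."""
    stat, p, _, _ = sps.chi2_contingency(np.asarray(contingency))
    return float(stat), float(p)


def stats_table(outcomes: pd.DataFrame, value_col: str = "logit",
                sex: dict[str, str] | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run :func:`choose_and_run` for every (scope, band/measure) outcome.

    ``outcomes`` is a tidy table with columns ``subject_id``, ``group``,
    ``scope`` and either ``band`` (band power) or none (single measure),
    plus the value column.  Returns (omnibus table, long post-hoc table).
    """
    keys = ["scope"] + (["band"] if "band" in outcomes.columns else [])
    main_rows, ph_rows = [], []
    for key, sub in outcomes.groupby(keys, sort=False):
        key = key if isinstance(key, tuple) else (key,)
        name = ":".join(str(k) for k in key)
        vals = sub[value_col].to_numpy()
        grp = sub["group"].to_numpy()
        sx = (np.array([sex[s] for s in sub["subject_id"]])
              if sex is not None else None)
        res = choose_and_run(vals, grp, sex=sx, outcome=name)
        main_rows.append(res.to_row())
        for (a, b), p_adj, method in res.posthoc:
            ph_rows.append({"outcome": name, "group_a": a, "group_b": b,
                            "p_adj": p_adj, "method": method})
    return pd.DataFrame(main_rows), pd.DataFrame(ph_rows)
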