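"""Joint methylation-expression analyses.

Per gene we form log2 fold changes (male over female, offset-stabilised) in
mean expression (FC_Expr) and gene-body methylation (FC_Meth), restricted to
genes both expressed and methylated in at least one sex, then test: the
rank correlation of the two fold changes; whether the FC_Expr ~ FC_Meth
slope differs between X and autosomes (OLS interaction F-test); enrichment
odds ratios of bias classes on the X; paired within-gene methylation shifts
between the sexes; and whether the X and autosomal gene-body methylation
distributions differ at all (k-sample Anderson-Darling).
"""

from __future__ import annotations

import warnings
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calling import bh_adjust
from .model import AnalysisConfig, ValidationError


def joint_table(gene_meth: pd.DataFrame, expr: pd.DataFrame,
                assignments: pd.DataFrame,
                config: Optional[AnalysisConfig] = None) -> pd.DataFrame:
    """One row per gene qualifying for the joint analysis.

    ``gene_meth``: per-gene percent levels with columns level_F / level_M
    (index gene_id).  ``expr``: classified DE output with mean_F / mean_M
    FPKM and bias_class.  A gene qualifies when methylated above the floor
    (default 1%) in >= 1 sex and expressed above the floor (default 1 FPKM)
    in >= 1 sex.
    """
    config = config or AnalysisConfig()
    df = gene_meth.join(expr[["mean_F", "mean_M", "bias_class", "q"]]
                        .rename(columns={"bias_class": "de_class",
                                         "q": "de_q"}), how="inner")
    meth_ok = (df["level_F"] > config.methylated_gene_floor) | \
        (df["level_M"] > config.methylated_gene_floor)
    expr_ok = (df["mean_F"] > config.expressed_gene_floor) | \
        (df["mean_M"] > config.expressed_gene_floor)
    df = df[meth_ok & expr_ok].copy()
    eps = config.fc_offset
    df["FC_Expr"] = np.log2((df["mean_M"] + eps) / (df["mean_F"] + eps))
    df["FC_Meth"] = np.log2((df["level_M"] + eps) / (df["level_F"] + eps))
    if "linkage" not in df.columns:
        amap = assignments.set_index("scaffold")["linkage"]
        if "scaffold" in df.columns:
            df["linkage"] = df["scaffold"].map(amap).fillna("unassigned")
        else:
            df["linkage"] = "unassigned"
    return df


def attach_linkage(df: pd.DataFrame, gene_scaffold: pd.Series,
                   assignments: pd.DataFrame) -> pd.DataFrame:
    """Add a linkage column by mapping genes to scaffolds to X/A calls."""
    amap = assignments.set_index("scaffold")["linkage"]
    out = df.copy()
    out["linkage"] = gene_scaffold.reindex(out.index).map(amap) \
        .fillna("unassigned")
    return out


def fc_correlation(df: pd.DataFrame,
                   linkage: Optional[str] = None) -> dict:
    """Spearman correlation between FC_Meth and FC_Expr (midranks).

    ``linkage`` restricts to X or A genes.  Constant input is flagged
    undefined rather than raising.
    """
    sub = df if linkage is None else df[df["linkage"] == linkage]
    x = sub["FC_Meth"].to_numpy(dtype=float)
    y = sub["FC_Expr"].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValidationError("need >= 3 genes for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"rho": np.nan, "p": np.nan, "n": len(x), "undefined": True}
    rho, p = stats.spearmanr(x, y)
    return {"rho": float(rho), "p": float(p), "n": len(x),
            "undefined": False}


def interaction_glm(df: pd.DataFrame) -> dict:
    """OLS of FC_Expr ~ FC_Meth x linkage; F-test of the interaction.

    The interaction term asks whether the X and autosomal regression slopes
    run parallel; F has (1, n - 4) degrees of freedom.
    """
    import statsmodels.formula.api as smf
    sub = df[df["linkage"].isin(["X", "A"])].copy()
    if sub["linkage"].nunique() < 2:
        raise ValidationError("need both X and A genes for the interaction")
    model = smf.ols("FC_Expr ~ FC_Meth * C(linkage)", data=sub).fit()
    name = [c for c in model.params.index if ":" in c][0]
    t = model.tvalues[name]
    F = float(t ** 2)
    p = float(model.pvalues[name])
    slopes = {}
    base = model.params["FC_Meth"]
    inter = model.params[name]
    levels = sorted(sub["linkage"].unique())       # A then X
    slopes[levels[0]] = float(base)
    slopes[levels[1]] = float(base + inter)
    return {"F": F, "df": (1, int(model.df_resid)), "p": p,
            "slopes": slopes, "n": int(model.nobs)}


def enrichment_contrasts(df: pd.DataFrame,
                         classes_col: str = "de_class") -> pd.DataFrame:
    """Observed/expected (odds ratio) of each bias class on the X.

    Per class: the 2x2 table (class vs not) x (X vs A), cross-product odds
    ratio, chi-square with 1 df (no continuity correction), BH across
    classes.  Zero-margin classes are flagged undefined.
    """
    sub = df[df["linkage"].isin(["X", "A"])]
    rows = []
    for cls in sorted(sub[classes_col].dropna().unique()):
        is_cls = sub[classes_col] == cls
        on_x = sub["linkage"] == "X"
        a = int((is_cls & on_x).sum())
        b = int((is_cls & ~on_x).sum())
        c = int((~is_cls & on_x).sum())
        d = int((~is_cls & ~on_x).sum())
        tab = np.array([[a, b], [c, d]])
        if tab.sum(axis=0).min() == 0 or tab.sum(axis=1).min() == 0:
            rows.append((cls, a, b, c, d, np.nan, np.nan, np.nan, True))
            continue
        orr = (a * d) / (b * c) if b * c > 0 else np.inf
        chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
        rows.append((cls, a, b, c, d, orr, float(chi2), float(p), False))
    out = pd.DataFrame(rows, columns=["class", "x_in", "a_in", "x_out",
                                      "a_out", "odds_ratio", "chi2", "p",
                                      "undefined"])
    ok = ~out["undefined"]
    q = np.full(len(out), np.nan)
    q[ok.to_numpy()] = bh_adjust(out.loc[ok, "p"].to_numpy())
    out["q"] = q
    return out


def dm_de_overlap_test(df: pd.DataFrame, dm_col: str = "dm_class",
                       de_col: str = "de_class") -> dict:
    """Chi-square (1 df, no correction) of DM status crossed with DE status."""
    is_dm = df[dm_col].isin(["MBm", "FABm"])
    is_de = df[de_col].isin(["MB", "MB+", "FAB", "FAB+"])
    tab = pd.crosstab(is_dm, is_de).reindex(index=[False, True],
                                            columns=[False, True],
                                            fill_value=0).to_numpy()
    if tab.sum(axis=0).min() == 0 or tab.sum(axis=1).min() == 0:
        return {"chi2": np.nan, "p": np.nan, "table": tab,
                "undefined": True}
    chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
    return {"chi2": float(chi2), "p": float(p), "table": tab,
            "undefined": False}


def paired_shift_test(level_F: np.ndarray, level_M: np.ndarray,
                      alternative: str = "two-sided") -> dict:
    """Wilcoxon signed-rank test of paired per-gene methylation levels.

    Zero differences are dropped; midranks; normal approximation with
    continuity correction above 25 nonzero pairs, exact enumeration below.
    Also reports the direction counts (genes higher in males vs females).
    """
    x = np.asarray(level_F, dtype=float)
    y = np.asarray(level_M, dtype=float)
    d = y - x
    nz = d[d != 0]
    res = {"n_pairs": len(d), "n_nonzero": len(nz),
           "n_up_in_male": int((d > 0).sum()),
           "n_down_in_male": int((d < 0).sum()),
           "median_shift": float(np.median(d)) if len(d) else np.nan}
    if len(nz) == 0:
        res.update(statistic=np.nan, p=np.nan, undefined=True)
        return res
    method = "exact" if len(nz) <= 25 else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        w = stats.wilcoxon(nz, alternative=alternative, method=method,
                           correction=(method == "approx"))
    res.update(statistic=float(w.statistic), p=float(w.pvalue),
               undefined=False)
    return res


def distribution_contrast(values_x: np.ndarray,
                          values_a: np.ndarray) -> dict:
    """k-sample Anderson-Darling comparison of two level distributions
    (midrank version, interpolated p)."""
    x = np.asarray(values_x, dtype=float)
    a = np.asarray(values_a, dtype=float)
    if len(x) < 5 or len(a) < 5:
        raise ValidationError("need >= 5 values per group")
    if np.ptp(np.concatenate([x, a])) == 0:
        return {"statistic": np.nan, "p": np.nan, "undefined": True}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = stats.anderson_ksamp([x, a], midrank=True)
    return {"statistic": float(r.statistic),
            "p": float(r.significance_level), "undefined": False}
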