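"""Differential methylation between morphs.

The per-unit test is a binomial logistic regression of methylated-read
proportion on group: each replicate contributes one binomial observation
``m_r`` of ``n_r``, and the group effect is assessed by a likelihood-ratio
chi-square with 1 df against the intercept-only model.  Because the group
factor saturates the group means, the MLE under the alternative is the
pooled per-group proportion and the LRT statistic reduces to the G-statistic
of the pooled 2x2 table — this closed form is what we compute (vectorised
over units); tests cross-check it against an iteratively fitted GLM.

Threshold calibration follows a sex-balanced permutation scheme: all
nonredundant pseudo-groupings of the replicates, either sex-pure ("by_sex")
or with each pseudo-group holding one sample of each sex ("mixed"), are run
through the same DM pipeline and their DM counts compared by rank-sum.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .calling import bh_adjust, metagene_profile, MetageneProfile
from .model import AnalysisConfig, GeneModel, SiteCounts, ValidationError

MBM, FABM, UB = "MBm", "FABm", "UB"


# ---------------------------------------------------------------------------
# coverage filters
# ---------------------------------------------------------------------------

def filter_dm_units(coverage: pd.DataFrame, min_reads: int,
                    top_quantile_drop: float) -> np.ndarray:
    """Mask of retained units given a unit x sample coverage frame.

    Drops units with any-sample coverage below ``min_reads`` or above that
    sample's (1 - top_quantile_drop) coverage quantile.
    """
    cov = coverage.to_numpy(dtype=float)
    keep = (cov >= min_reads).all(axis=1)
    hi = np.quantile(cov, 1.0 - top_quantile_drop, axis=0)
    keep &= (cov <= hi).all(axis=1)
    return keep


def filter_dm_sites(sites: SiteCounts, config: AnalysisConfig) -> np.ndarray:
    cov = pd.DataFrame({s: sites.coverage(s) for s in sites.samples})
    return filter_dm_units(cov, config.min_site_coverage,
                           config.site_coverage_top_quantile_drop)


# ---------------------------------------------------------------------------
# the logistic likelihood-ratio test
# ---------------------------------------------------------------------------

def logistic_lrt(m_F: np.ndarray, u_F: np.ndarray,
                 m_M: np.ndarray, u_M: np.ndarray
                 ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised binomial-logistic LRT of a group effect.

    Inputs are pooled per-group methylated / unmethylated read counts (the
    sufficient statistics).  Returns ``(lrt, p, diff)`` with ``diff`` the
    male-minus-female pooled level in percent points.  Units with zero
    coverage in either group get NaN.
    """
    m_F, u_F, m_M, u_M = (np.asarray(a, dtype=float)
                          for a in (m_F, u_F, m_M, u_M))
    n_F, n_M = m_F + u_F, m_M + u_M
    n = n_F + n_M
    m = m_F + m_M
    u = u_F + u_M
    with np.errstate(divide="ignore", invalid="ignore"):
        ll_alt = (_entropy_term(m_F, n_F) + _entropy_term(u_F, n_F) +
                  _entropy_term(m_M, n_M) + _entropy_term(u_M, n_M))
        ll_null = _entropy_term(m, n) + _entropy_term(u, n)
    lrt = 2.0 * (ll_alt - ll_null)
    lrt = np.maximum(lrt, 0.0)
    p = stats.chi2.sf(lrt, df=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        diff = (m_M / n_M - m_F / n_F) * 100.0
    bad = (n_F == 0) | (n_M == 0)
    lrt = np.where(bad, np.nan, lrt)
    p = np.where(bad, np.nan, p)
    diff = np.where(bad, np.nan, diff)
    return lrt, p, diff


def _entropy_term(k, n):
    """k * log(k / n) with the 0 log 0 = 0 convention."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = k * (np.log(k) - np.log(n))
    return np.where(k > 0, out, 0.0)


def dm_logistic_test(sites: SiteCounts, groups: Dict[str, Sequence[str]],
                     unit_ids: Optional[Sequence] = None) -> pd.DataFrame:
    """Per-site logistic LRT between two sample groups.

    ``groups`` maps the two group names (female first) to sample id lists.
    """
    (gF, sF), (gM, sM) = groups.items()
    m_F = sum(sites.m(s) for s in sF)
    u_F = sum(sites.u(s) for s in sF)
    m_M = sum(sites.m(s) for s in sM)
    u_M = sum(sites.u(s) for s in sM)
    lrt, p, diff = logistic_lrt(m_F, u_F, m_M, u_M)
    n_F, n_M = m_F + u_F, m_M + u_M
    with np.errstate(divide="ignore", invalid="ignore"):
        lev_F = np.where(n_F > 0, m_F / np.maximum(n_F, 1) * 100.0, np.nan)
        lev_M = np.where(n_M > 0, m_M / np.maximum(n_M, 1) * 100.0, np.nan)
    out = pd.DataFrame({"level_F": lev_F, "level_M": lev_M, "diff": diff,
                        "lrt": lrt, "p": p})
    if unit_ids is not None:
        out.insert(0, "unit_id", list(unit_ids))
    else:
        out.insert(0, "unit_id", [f"{r.scaffold}:{r.pos}:{r.strand}"
                                  for r in sites.df.itertuples()])
    return out


def dm_gene_test(gene_counts: pd.DataFrame,
                 groups: Dict[str, Sequence[str]]) -> pd.DataFrame:
    """Gene-level logistic LRT from a frame with per-sample m_<s>/u_<s>
    columns indexed by gene."""
    (gF, sF), (gM, sM) = groups.items()
    m_F = sum(gene_counts["m_" + s].to_numpy() for s in sF)
    u_F = sum(gene_counts["u_" + s].to_numpy() for s in sF)
    m_M = sum(gene_counts["m_" + s].to_numpy() for s in sM)
    u_M = sum(gene_counts["u_" + s].to_numpy() for s in sM)
    lrt, p, diff = logistic_lrt(m_F, u_F, m_M, u_M)
    n_F, n_M = m_F + u_F, m_M + u_M
    return pd.DataFrame({"unit_id": gene_counts.index,
                         "level_F": m_F / np.maximum(n_F, 1) * 100.0,
                         "level_M": m_M / np.maximum(n_M, 1) * 100.0,
                         "diff": diff, "lrt": lrt, "p": p})


def classify_dm(records: pd.DataFrame, min_diff: float,
                fdr: float) -> pd.DataFrame:
    """BH-adjust across units and label MBm / FABm / UB.

    A unit is biased when q < fdr and |diff| >= min_diff (percent points);
    the sign of diff (male minus female) fixes the direction.
    """
    out = records.copy()
    ok = out["p"].notna()
    q = np.full(len(out), np.nan)
    q[ok.to_numpy()] = bh_adjust(out.loc[ok, "p"].to_numpy())
    out["q"] = q
    sig = (out["q"] < fdr) & (out["diff"].abs() >= min_diff)
    out["bias_class"] = np.where(
        sig & (out["diff"] > 0), MBM,
        np.where(sig & (out["diff"] < 0), FABM, UB))
    return out


def dm_class_counts(records: pd.DataFrame) -> Dict[str, int]:
    c = records["bias_class"].value_counts()
    return {k: int(c.get(k, 0)) for k in (MBM, FABM, UB)}


# ---------------------------------------------------------------------------
# sex-balanced pair-null calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairGrouping:
    """One pseudo-comparison: two disjoint pseudo-groups of samples."""

    grouping_id: str
    kind: str                       # by_sex | mixed
    group_a: Tuple[str, ...]
    group_b: Tuple[str, ...]


def enumerate_pair_groupings(female_ids: Sequence[str],
                             male_ids: Sequence[str]) -> List[PairGrouping]:
    """All nonredundant 2v2 pseudo-groupings of the bisulphite replicates.

    * by_sex: every pair of females against every pair of males
      (C(nF,2) x C(nM,2); 9 for 3+3).
    * mixed: each pseudo-group holds one female and one male, females and
      males distinct across the two pseudo-groups, group-label swaps
      collapsed (C(nF,2) x C(nM,2) x 2; 18 for 3+3).
    """
    F, M = list(female_ids), list(male_ids)
    if len(F) < 2 or len(M) < 2:
        raise ValidationError("need >= 2 replicates per sex")
    out: List[PairGrouping] = []
    for i, fa in enumerate(combinations(F, 2)):
        for j, mb in enumerate(combinations(M, 2)):
            out.append(PairGrouping(f"by_sex_{i}_{j}", "by_sex",
                                    tuple(fa), tuple(mb)))
    k = 0
    for f1, f2 in combinations(F, 2):
        for m_pair in combinations(M, 2):
            for ma, mb in (m_pair, m_pair[::-1]):
                out.append(PairGrouping(f"mixed_{k}", "mixed",
                                        (f1, ma), (f2, mb)))
                k += 1
    return out


def calibrate_dm_threshold(sites: SiteCounts,
                           groupings: Sequence[PairGrouping],
                           thresholds: Sequence[float],
                           config: Optional[AnalysisConfig] = None,
                           min_coverage: Optional[int] = None) -> pd.DataFrame:
    """DM-unit counts per pseudo-grouping at each |diff| threshold.

    Each grouping is run through the same filter -> LRT -> BH pipeline as a
    real comparison; a unit counts when q < fdr and |diff| >= threshold.
    Returns a long frame (grouping_id, kind, threshold, n_dm).
    """
    config = config or AnalysisConfig()
    minc = config.min_site_coverage if min_coverage is None else min_coverage
    rows = []
    for g in groupings:
        involved = list(g.group_a) + list(g.group_b)
        cov = pd.DataFrame({s: sites.coverage(s) for s in involved})
        keep = filter_dm_units(cov, minc,
                               config.site_coverage_top_quantile_drop)
        sub = sites.subset(keep)
        m_a = sum(sub.m(s) for s in g.group_a)
        u_a = sum(sub.u(s) for s in g.group_a)
        m_b = sum(sub.m(s) for s in g.group_b)
        u_b = sum(sub.u(s) for s in g.group_b)
        _, p, diff = logistic_lrt(m_a, u_a, m_b, u_b)
        ok = ~np.isnan(p)
        q = np.full(len(p), np.nan)
        q[ok] = bh_adjust(p[ok])
        for t in thresholds:
            n_dm = int(((q < config.fdr) & (np.abs(diff) >= t)).sum())
            rows.append((g.grouping_id, g.kind, float(t), n_dm))
    return pd.DataFrame(rows, columns=["grouping_id", "kind", "threshold",
                                       "n_dm"])


def rank_sum_by_sex_vs_mixed(calib: pd.DataFrame,
                             threshold: float) -> dict:
    """Mann-Whitney comparison of by-sex vs mixed DM counts at a threshold.

    W is the U statistic with the by-sex counts as the first sample (the
    number of (by_sex, mixed) pairs where the by-sex count exceeds the mixed
    one, ties counting half); p is the two-sided normal approximation with
    continuity correction.  Complete separation of 9 vs 18 groupings gives
    W = 162.
    """
    sub = calib[calib["threshold"] == float(threshold)]
    a = sub.loc[sub["kind"] == "by_sex", "n_dm"].to_numpy()
    b = sub.loc[sub["kind"] == "mixed", "n_dm"].to_numpy()
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return {"W": float(res.statistic), "p": float(res.pvalue),
            "n_by_sex": len(a), "n_mixed": len(b),
            "complete_separation": float(res.statistic) == len(a) * len(b)}


# ---------------------------------------------------------------------------
# methylation PCA
# ---------------------------------------------------------------------------

def methylation_pca(levels: pd.DataFrame) -> dict:
    """PCA of a sample x site methylation-level matrix.

    Column-centred (per site), unscaled singular-value decomposition — the
    same convention as R's prcomp with default arguments.  Returns per-sample
    scores and the variance fraction of each component.
    """
    if levels.shape[0] < 2:
        raise ValidationError("PCA needs >= 2 samples")
    X = levels.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValidationError("PCA input contains missing levels")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-|loading| coordinate positive
    for k in range(len(S)):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    scores = U * S
    var = S ** 2
    frac = var / var.sum() if var.sum() > 0 else var
    return {"scores": pd.DataFrame(scores, index=levels.index,
                                   columns=[f"PC{i + 1}"
                                            for i in range(len(S))]),
            "variance_fraction": frac}


def site_level_matrix(sites: SiteCounts,
                      site_keys: pd.DataFrame) -> pd.DataFrame:
    """Sample x site level matrix (m/(m+u)) restricted to the given site key
    rows; sites with zero coverage in any sample are dropped."""
    key = sites.df.merge(site_keys.assign(_keep=True),
                         on=["scaffold", "pos", "strand"], how="left")
    mask = key["_keep"].notna().to_numpy()
    sub = sites.subset(mask)
    cols = {}
    ok = np.ones(len(sub), dtype=bool)
    for s in sub.samples:
        ok &= sub.coverage(s) > 0
    sub = sub.subset(ok)
    for s in sub.samples:
        cols[s] = sub.m(s) / sub.coverage(s)
    mat = pd.DataFrame(cols).T
    mat.columns = [f"{r.scaffold}:{r.pos}:{r.strand}"
                   for r in sub.df.itertuples()]
    return mat


# ---------------------------------------------------------------------------
# DM-site / gene overlap
# ---------------------------------------------------------------------------

def dm_site_gene_overlap(dm_sites: pd.DataFrame, genes: Sequence[GeneModel],
                         flank: int = 1000,
                         n_body_bins: int = 60) -> dict:
    """Count DM sites per gene span +/- flank and profile them along bodies.

    A site inside several genes' flanked spans counts for each.  Returns
    per-gene counts, the fraction of DM sites that are genic (within any
    flanked span), and a metagene profile of the DM sites.
    """
    pos0 = dm_sites["pos"].to_numpy() - 1
    scafs = dm_sites["scaffold"].to_numpy()
    counts: Dict[str, int] = {}
    hit = np.zeros(len(dm_sites), dtype=bool)
    for g in genes:
        sel = (scafs == g.scaffold) & (pos0 >= g.start0 - flank) & \
            (pos0 < g.end0 + flank)
        n = int(sel.sum())
        if n:
            counts[g.gene_id] = n
            hit |= sel
    profile = metagene_profile(dm_sites, genes,
                               methylated_mask=np.ones(len(dm_sites),
                                                       dtype=bool),
                               n_body_bins=n_body_bins, flank_bp=flank)
    frac = float(hit.mean()) if len(dm_sites) else np.nan
    return {"per_gene_counts": counts, "genic_fraction": frac,
            "profile": profile}
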