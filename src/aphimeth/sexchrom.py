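"""X-chromosome assignment from male:female sequencing depth.

In an X0 system males carry a single X, so X-linked scaffolds show half the
male read depth of autosomal scaffolds.  Per scaffold we take the median
depth in each morph, normalise the male median by the genome-wide
mean-depth ratio (female mean / male mean), and assign: ratio < 1 -> X,
ratio > 1 -> autosome, anything else (ratio exactly 1, zero female median,
scaffolds below the length floor) stays unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import AnalysisConfig, GeneModel, ValidationError

X, A, UNASSIGNED = "X", "A", "unassigned"


@dataclass
class DepthSummary:
    """Per-scaffold median depth plus the genome-wide mean for one morph."""

    medians: pd.Series           # indexed by scaffold
    genome_mean: float
    n_positions: pd.Series


def scaffold_depth_summary(depth: pd.DataFrame,
                           include_zero_depth: bool = True) -> DepthSummary:
    """Summarise a (scaffold, pos, depth) table.

    ``include_zero_depth=False`` drops zero-depth positions before the
    median (exposed because pipelines differ on this point; default keeps
    all assembled positions).
    """
    if depth.empty:
        raise ValidationError("empty depth table")
    d = depth if include_zero_depth else depth[depth["depth"] > 0]
    med = d.groupby("scaffold")["depth"].median()
    n = d.groupby("scaffold")["depth"].size()
    return DepthSummary(medians=med, genome_mean=float(d["depth"].mean()),
                        n_positions=n)


def assign_linkage(summary_F: DepthSummary, summary_M: DepthSummary,
                   scaffold_lengths: pd.Series,
                   config: Optional[AnalysisConfig] = None,
                   n_hist_bins: int = 40) -> pd.DataFrame:
    """Normalised male:female coverage ratio and X/A call per scaffold.

    norm_ratio = male_median x (mean_F / mean_M) / female_median.  Scaffolds
    shorter than ``min_scaffold_length`` stay unassigned.  The returned
    frame's attrs carry a histogram of the ratio and a valley-depth
    bimodality check (warning flag only).
    """
    config = config or AnalysisConfig()
    if summary_M.genome_mean <= 0:
        raise ValidationError("male genome-wide mean depth is zero")
    norm = summary_F.genome_mean / summary_M.genome_mean
    scafs = scaffold_lengths.index
    med_F = summary_F.medians.reindex(scafs)
    med_M = summary_M.medians.reindex(scafs)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = med_M * norm / med_F
    linkage = np.full(len(scafs), UNASSIGNED, dtype=object)
    ok = (scaffold_lengths.to_numpy() >= config.min_scaffold_length) & \
        np.isfinite(ratio.to_numpy()) & (med_F.to_numpy() > 0)
    r = ratio.to_numpy()
    linkage[ok & (r < 1.0)] = X
    linkage[ok & (r > 1.0)] = A
    out = pd.DataFrame({"scaffold": scafs, "length": scaffold_lengths.values,
                        "median_depth_F": med_F.values,
                        "median_depth_M": med_M.values,
                        "norm_ratio": r, "linkage": linkage})
    out.attrs["mean_depth_F"] = summary_F.genome_mean
    out.attrs["mean_depth_M"] = summary_M.genome_mean
    finite = r[np.isfinite(r)]
    if len(finite):
        hist, edges = np.histogram(finite, bins=n_hist_bins)
        out.attrs["ratio_histogram"] = (hist, edges)
        out.attrs["bimodal"] = _valley_check(hist)
        if not out.attrs["bimodal"]:
            import warnings
            warnings.warn("male:female coverage-ratio distribution does not "
                          "look bimodal; X assignment may be unreliable")
    return out


def _valley_check(hist: np.ndarray) -> bool:
    """True when the histogram has two peaks separated by a valley at most
    half the smaller peak's height (a crude dip heuristic)."""
    if len(hist) < 3:
        return False
    imax = int(np.argmax(hist))
    # search a second peak on the far side of the global one
    best = (0, -1)
    for i in range(len(hist)):
        if abs(i - imax) < 2:
            continue
        lo, hi = sorted((i, imax))
        valley = hist[lo + 1:hi].min() if hi - lo > 1 else hist[lo]
        if hist[i] > best[0] and valley <= 0.5 * min(hist[i], hist[imax]):
            best = (hist[i], i)
    return best[1] >= 0


def validate_with_markers(assignments: pd.DataFrame,
                          markers: pd.DataFrame) -> pd.DataFrame:
    """Concordance of coverage-based calls with marker-known linkage.

    ``markers`` columns: marker, scaffold, known_linkage (X|A).  Markers on
    scaffolds missing from the assignment table are reported unresolved.
    """
    amap = assignments.set_index("scaffold")["linkage"]
    rows = []
    for r in markers.itertuples():
        pred = amap.get(r.scaffold, None)
        if pred is None or pred == UNASSIGNED:
            rows.append((r.marker, r.scaffold, r.known_linkage,
                         pred or "absent", None))
        else:
            rows.append((r.marker, r.scaffold, r.known_linkage, pred,
                         pred == r.known_linkage))
    out = pd.DataFrame(rows, columns=["marker", "scaffold", "known_linkage",
                                      "predicted", "concordant"])
    resolved = out["concordant"].notna()
    out.attrs["n_resolved"] = int(resolved.sum())
    out.attrs["concordance"] = (float(out.loc[resolved, "concordant"].mean())
                                if resolved.any() else np.nan)
    return out


def chromosome_composition_stats(assignments: pd.DataFrame,
                                 genes: Sequence[GeneModel]) -> dict:
    """X vs autosome structural contrasts.

    Reports per-linkage gene counts and assembled Mb; a two-proportion
    chi-square on CDS base counts (CDS depletion); a rank-sum test on
    per-gene CDS lengths; and an exact binomial test of the X gene count
    against the assembled-length expectation.
    """
    amap = assignments.set_index("scaffold")["linkage"]
    lmap = assignments.set_index("scaffold")["length"]
    per = {X: {"genes": 0, "cds_bases": 0, "cds_lengths": []},
           A: {"genes": 0, "cds_bases": 0, "cds_lengths": []},
           UNASSIGNED: {"genes": 0, "cds_bases": 0, "cds_lengths": []}}
    for g in genes:
        link = amap.get(g.scaffold, UNASSIGNED)
        per[link]["genes"] += 1
        per[link]["cds_bases"] += g.cds_length
        per[link]["cds_lengths"].append(g.cds_length)
    bases = {k: int(lmap[amap == k].sum()) for k in (X, A)}
    out = {"n_genes": {k: per[k]["genes"] for k in (X, A, UNASSIGNED)},
           "assembled_mb": {k: bases[k] / 1e6 for k in (X, A)},
           "cds_fraction": {k: (per[k]["cds_bases"] / bases[k]
                                if bases[k] else np.nan) for k in (X, A)}}
    out["x_assembly_share"] = bases[X] / max(bases[X] + bases[A], 1)
    # CDS depletion: 2x2 of (CDS, non-CDS) bases by linkage
    tab = np.array([[per[X]["cds_bases"], bases[X] - per[X]["cds_bases"]],
                    [per[A]["cds_bases"], bases[A] - per[A]["cds_bases"]]])
    if tab.min() >= 0 and tab.sum(axis=1).min() > 0:
        chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
        out["cds_depletion"] = {"chi2": float(chi2), "p": float(p)}
    lx, la = per[X]["cds_lengths"], per[A]["cds_lengths"]
    if lx and la:
        r = stats.mannwhitneyu(lx, la, alternative="two-sided")
        out["cds_length_test"] = {"U": float(r.statistic),
                                  "p": float(r.pvalue)}
    n_assigned = per[X]["genes"] + per[A]["genes"]
    if n_assigned:
        bt = stats.binomtest(per[X]["genes"], n_assigned,
                             out["x_assembly_share"])
        out["x_gene_count_test"] = {"p": float(bt.pvalue)}
    return out
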