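"""Methylation calling and summarisation.

The central statistic is a per-site, per-sample one-sided binomial test of
``m`` methylated reads out of ``n = m + u`` against the bisulphite
conversion-failure rate lambda estimated from an unmethylated control genome:
``p = P(X >= m | n, lambda)``.  Benjamini-Hochberg adjustment is applied
within each sample across sites; a site is called methylated at q < fdr.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import (AnalysisConfig, ConversionError, GeneModel, SiteCounts,
                    ValidationError, CONTEXTS)


# ---------------------------------------------------------------------------
# context-level summaries
# ---------------------------------------------------------------------------

def context_methylation_summary(sites: SiteCounts,
                                pooled: bool = False) -> pd.DataFrame:
    """Per-context methylated-read proportion, per sample or pooled.

    Returns a frame indexed by context (CpG, CHG, CHH) with one column per
    sample (or a single ``pooled`` column).  The proportion is the
    read-weighted level sum(m) / sum(m + u); contexts with zero coverage get
    NaN.
    """
    rows = {}
    ctx = sites.df["context"].to_numpy()
    for c in CONTEXTS:
        mask = ctx == c
        if pooled:
            m = sum(int(sites.m(s)[mask].sum()) for s in sites.samples)
            t = sum(int(sites.coverage(s)[mask].sum()) for s in sites.samples)
            rows[c] = {"pooled": m / t if t else np.nan}
        else:
            rows[c] = {}
            for s in sites.samples:
                m = int(sites.m(s)[mask].sum())
                t = int(sites.coverage(s)[mask].sum())
                rows[c][s] = m / t if t else np.nan
    return pd.DataFrame(rows).T.rename_axis("context")


def estimate_conversion_error(control: SiteCounts) -> ConversionError:
    """Pooled false-positive methylation rate from a control genome.

    lambda = sum(m) / sum(m + u) over all contexts, samples and sites; the
    per-sample rates are reported alongside for QC.
    """
    per_sample = {}
    M = T = 0
    for s in control.samples:
        m = int(control.m(s).sum())
        t = int(control.coverage(s).sum())
        per_sample[s] = m / t if t else np.nan
        M += m
        T += t
    if T == 0:
        raise ValidationError("control genome has zero coverage")
    return ConversionError(lam=M / T, n_control_sites=len(control),
                           per_sample_lambdas=per_sample)


# ---------------------------------------------------------------------------
# the binomial site caller
# ---------------------------------------------------------------------------

def binomial_site_pvalues(m: np.ndarray, n: np.ndarray,
                          lam: float) -> np.ndarray:
    """One-sided tail P(X >= m | n, lam); the lam = 0 limit is 0 for m > 0
    and 1 otherwise."""
    m = np.asarray(m)
    n = np.asarray(n)
    if lam == 0.0:
        return np.where(m > 0, 0.0, 1.0)
    return stats.binom.sf(m - 1, n, lam)


def coverage_filter_mask(sites: SiteCounts, min_coverage: int) -> np.ndarray:
    """Sites covered by at least ``min_coverage`` reads in every sample."""
    mask = np.ones(len(sites), dtype=bool)
    for s in sites.samples:
        mask &= sites.coverage(s) >= min_coverage
    return mask


def call_methylated_sites(sites: SiteCounts, lam: float,
                          config: Optional[AnalysisConfig] = None,
                          context: str = "CpG") -> pd.DataFrame:
    """Per-sample binomial calls on sites covered in all samples.

    Returns a long frame: scaffold, pos, strand, sample, m, u, p, q, call.
    BH is applied within each sample; ``call`` is q < config.fdr.
    """
    config = config or AnalysisConfig()
    sub = sites.in_context(context) if context else sites
    sub = sub.subset(coverage_filter_mask(sub, config.min_site_coverage))
    frames = []
    for s in sub.samples:
        m = sub.m(s)
        n = sub.coverage(s)
        p = binomial_site_pvalues(m, n, lam)
        q = bh_adjust(p)
        frames.append(pd.DataFrame({
            "scaffold": sub.df["scaffold"], "pos": sub.df["pos"],
            "strand": sub.df["strand"], "sample": s, "m": m, "u": n - m,
            "p": p, "q": q, "call": q < config.fdr}))
    return pd.concat(frames, ignore_index=True)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    if len(p) == 0:
        return np.asarray(p, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def sites_methylated_in_any_sample(calls: pd.DataFrame) -> pd.DataFrame:
    """Site key rows (scaffold, pos, strand) called methylated in >= 1 sample."""
    hit = calls[calls["call"]]
    return hit[["scaffold", "pos", "strand"]].drop_duplicates()


# ---------------------------------------------------------------------------
# feature aggregation
# ---------------------------------------------------------------------------

FEATURE_CLASSES = ("exon", "intron", "utr5", "utr3", "gene", "intergenic")


def _interval_lookup(genes: Sequence[GeneModel], kind: str):
    """Per-scaffold sorted interval starts/ends with owner ids, for
    vectorised point-in-interval queries.  Intervals 0-based half-open."""
    per_scaf: Dict[str, list] = {}
    for g in genes:
        if kind == "gene":
            ivs = [(g.start0, g.end0)]
        elif kind == "intron":
            ivs = g.introns
        else:
            ivs = getattr(g, {"exon": "exons", "utr5": "utr5",
                              "utr3": "utr3", "cds": "cds"}[kind])
        for a, b in ivs:
            per_scaf.setdefault(g.scaffold, []).append((a, b, g.gene_id))
    out = {}
    for scaf, ivs in per_scaf.items():
        ivs.sort()
        out[scaf] = (np.array([i[0] for i in ivs]),
                     np.array([i[1] for i in ivs]),
                     [i[2] for i in ivs])
    return out


def assign_sites_to_intervals(site_df: pd.DataFrame,
                              genes: Sequence[GeneModel],
                              kind: str) -> np.ndarray:
    """Index of the covering interval's gene per site ('' if none).

    Intervals of one feature class are assumed non-overlapping within a
    scaffold (enforced upstream for a single annotation).
    """
    lookup = _interval_lookup(genes, kind)
    owner = np.full(len(site_df), "", dtype=object)
    pos0 = site_df["pos"].to_numpy() - 1
    scafs = site_df["scaffold"].to_numpy()
    for scaf in np.unique(scafs):
        if scaf not in lookup:
            continue
        starts, ends, gids = lookup[scaf]
        sel = scafs == scaf
        p = pos0[sel]
        idx = np.searchsorted(starts, p, side="right") - 1
        ok = (idx >= 0) & (p < ends[np.clip(idx, 0, None)])
        vals = np.full(sel.sum(), "", dtype=object)
        gid_arr = np.array(gids, dtype=object)
        vals[ok] = gid_arr[idx[ok]]
        owner[sel] = vals
    return owner


def aggregate_feature_methylation(sites: SiteCounts,
                                  genes: Sequence[GeneModel],
                                  samples: Optional[Sequence[str]] = None,
                                  classes: Iterable[str] = FEATURE_CLASSES,
                                  context: str = "CpG") -> pd.DataFrame:
    """Pool reads over features and report the pooled level per feature class.

    Per feature: level = sum(m) / sum(m + u) pooling the selected samples.
    ``intergenic`` is the complement of gene spans.  Features with zero
    pooled coverage are flagged ``undefined``.
    """
    samples = list(samples or sites.samples)
    sub = sites.in_context(context) if context else sites
    m_tot = sum(sub.m(s) for s in samples)
    t_tot = sum(sub.coverage(s) for s in samples)
    rows = []
    gene_owner = assign_sites_to_intervals(sub.df, genes, "gene")
    for cls in classes:
        if cls == "intergenic":
            mask = gene_owner == ""
            pm, pt = int(m_tot[mask].sum()), int(t_tot[mask].sum())
            rows.append(("intergenic", cls, pm, pt))
            continue
        owner = gene_owner if cls == "gene" else \
            assign_sites_to_intervals(sub.df, genes, cls)
        ser = pd.DataFrame({"owner": owner, "m": m_tot, "t": t_tot})
        grp = ser[ser["owner"] != ""].groupby("owner").sum()
        for gid, r in grp.iterrows():
            rows.append((gid, cls, int(r["m"]), int(r["t"])))
        # features never covered still appear, flagged undefined
        seen = set(grp.index)
        for g in genes:
            if g.gene_id not in seen and _has_feature(g, cls):
                rows.append((g.gene_id, cls, 0, 0))
    out = pd.DataFrame(rows, columns=["feature_id", "feature_class",
                                      "pooled_m", "pooled_t"])
    out["level"] = np.where(out["pooled_t"] > 0,
                            out["pooled_m"] / out["pooled_t"].replace(0, 1),
                            np.nan)
    out["undefined"] = out["pooled_t"] == 0
    return out


def _has_feature(g: GeneModel, cls: str) -> bool:
    return bool({"exon": g.exons, "intron": g.introns, "utr5": g.utr5,
                 "utr3": g.utr3, "gene": [1]}.get(cls))


def gene_methylation_levels(sites: SiteCounts, genes: Sequence[GeneModel],
                            groups: Dict[str, Sequence[str]],
                            context: str = "CpG") -> pd.DataFrame:
    """Per-gene pooled methylation level for each sample group.

    Returns a frame indexed by gene_id with one ``level_<group>`` (percent)
    and one ``reads_<group>`` column per group.
    """
    sub = sites.in_context(context) if context else sites
    owner = assign_sites_to_intervals(sub.df, genes, "gene")
    df = pd.DataFrame({"owner": owner})
    for name, samp in groups.items():
        df["m_" + name] = sum(sub.m(s) for s in samp)
        df["t_" + name] = sum(sub.coverage(s) for s in samp)
    grp = df[df["owner"] != ""].groupby("owner").sum()
    out = pd.DataFrame(index=grp.index)
    for name in groups:
        t = grp["t_" + name]
        out[f"level_{name}"] = grp["m_" + name] / t.replace(0, np.nan) * 100.0
        out[f"reads_{name}"] = t
    out = out.reindex([g.gene_id for g in genes])
    for name in groups:
        out[f"reads_{name}"] = out[f"reads_{name}"].fillna(0).astype(int)
    out.index.name = "gene_id"
    return out


# ---------------------------------------------------------------------------
# metagene profiles
# ---------------------------------------------------------------------------

@dataclass
class MetageneProfile:
    """Positional density of sites over scaled gene bodies plus fixed flanks.

    ``covered`` and ``methylated`` hold per-bin site counts; bins run
    upstream flank -> body (TSS to TES, strand-oriented) -> downstream flank.
    """

    n_body_bins: int
    flank_bp: int
    flank_bin_bp: int
    covered: np.ndarray
    methylated: np.ndarray
    n_genes_used: int
    n_genes_skipped: int

    @property
    def n_flank_bins(self) -> int:
        return self.flank_bp // self.flank_bin_bp

    @property
    def body_slice(self) -> slice:
        return slice(self.n_flank_bins, self.n_flank_bins + self.n_body_bins)

    def to_frame(self) -> pd.DataFrame:
        nb = len(self.covered)
        nf = self.n_flank_bins
        region = (["upstream"] * nf + ["body"] * self.n_body_bins +
                  ["downstream"] * nf)
        return pd.DataFrame({"bin": np.arange(nb), "region": region,
                             "covered": self.covered,
                             "methylated": self.methylated})


def metagene_profile(site_df: pd.DataFrame, genes: Sequence[GeneModel],
                     methylated_mask: Optional[np.ndarray] = None,
                     n_body_bins: int = 60, flank_bp: int = 1000,
                     flank_bin_bp: int = 50) -> MetageneProfile:
    """Bin sites over gene bodies (scaled) and flanks (fixed bp), TSS->TES.

    ``site_df`` needs scaffold/pos columns; ``methylated_mask`` marks the
    subset counted into the methylated profile.  Genes shorter than
    ``n_body_bins`` bases are skipped.
    """
    nf = flank_bp // flank_bin_bp
    nbins = n_body_bins + 2 * nf
    covered = np.zeros(nbins, dtype=np.int64)
    meth = np.zeros(nbins, dtype=np.int64)
    if methylated_mask is None:
        methylated_mask = np.zeros(len(site_df), dtype=bool)
    methylated_mask = np.asarray(methylated_mask, dtype=bool)
    pos0 = site_df["pos"].to_numpy() - 1
    scafs = site_df["scaffold"].to_numpy()
    order = np.argsort(pos0, kind="mergesort")
    used = skipped = 0
    by_scaf: Dict[str, np.ndarray] = {}
    for scaf in np.unique(scafs):
        sel = np.flatnonzero(scafs == scaf)
        by_scaf[scaf] = sel[np.argsort(pos0[sel], kind="mergesort")]
    for g in genes:
        if g.length < n_body_bins:
            skipped += 1
            continue
        idx = by_scaf.get(g.scaffold)
        if idx is None:
            used += 1
            continue
        p = pos0[idx]
        lo, hi = g.start0 - flank_bp, g.end0 + flank_bp
        a, b = np.searchsorted(p, [lo, hi])
        sel = idx[a:b]
        pp = p[a:b]
        binno = np.empty(len(pp), dtype=np.int64)
        up = pp < g.start0
        down = pp >= g.end0
        body = ~up & ~down
        binno[up] = (pp[up] - lo) // flank_bin_bp
        binno[body] = nf + ((pp[body] - g.start0) * n_body_bins) // g.length
        binno[down] = nf + n_body_bins + (pp[down] - g.end0) // flank_bin_bp
        if g.strand == "-":
            binno = nbins - 1 - binno
        np.add.at(covered, binno, 1)
        np.add.at(meth, binno, methylated_mask[sel].astype(np.int64))
        used += 1
    return MetageneProfile(n_body_bins=n_body_bins, flank_bp=flank_bp,
                           flank_bin_bp=flank_bin_bp, covered=covered,
                           methylated=meth, n_genes_used=used,
                           n_genes_skipped=skipped)


# ---------------------------------------------------------------------------
# expression strata by methylation level
# ---------------------------------------------------------------------------

METH_BINS = ((0.0, 1.0), (1.0, 25.0), (25.0, 50.0), (50.0, 75.0),
             (75.0, 100.0 + 1e-9))
METH_BIN_LABELS = ("[0,1)", "[1,25)", "[25,50)", "[50,75)", "[75,100]")


def methylation_bin(level_percent: np.ndarray) -> np.ndarray:
    """Assign gene methylation levels (percent) to the five study bins.

    A gene at exactly 1% falls in the first methylated bin [1,25).
    """
    lv = np.asarray(level_percent, dtype=float)
    out = np.full(lv.shape, "", dtype=object)
    for (lo, hi), lab in zip(METH_BINS, METH_BIN_LABELS):
        out[(lv >= lo) & (lv < hi)] = lab
    return out


def methylation_expression_strata(gene_level_percent: pd.Series,
                                  gene_fpkm: pd.Series,
                                  gene_cv: Optional[pd.Series] = None,
                                  min_fpkm: float = 1.0) -> dict:
    """Expression and expression-stability distributions by methylation bin.

    Genes below ``min_fpkm`` are excluded.  Reports per-bin FPKM (and CV)
    values, a Spearman trend of expression on bin index, and the
    Mann-Whitney comparison of the unmethylated bin against the first
    methylated bin.
    """
    df = pd.DataFrame({"level": gene_level_percent, "fpkm": gene_fpkm})
    if gene_cv is not None:
        df["cv"] = gene_cv
    df = df.dropna(subset=["level", "fpkm"])
    df = df[df["fpkm"] >= min_fpkm]
    df["bin"] = methylation_bin(df["level"].to_numpy())
    df = df[df["bin"] != ""]
    groups = {lab: df.loc[df["bin"] == lab, "fpkm"].to_numpy()
              for lab in METH_BIN_LABELS}
    bin_idx = df["bin"].map({lab: i for i, lab in
                             enumerate(METH_BIN_LABELS)}).to_numpy()
    res = {"per_bin_fpkm": groups, "n_per_bin":
           {k: len(v) for k, v in groups.items()}}
    if len(df) >= 3 and len(np.unique(bin_idx)) > 1:
        rho, p = stats.spearmanr(bin_idx, np.log10(df["fpkm"] + 1e-9))
        res["trend_rho"], res["trend_p"] = float(rho), float(p)
    g0, g1 = groups[METH_BIN_LABELS[0]], groups[METH_BIN_LABELS[1]]
    if len(g0) and len(g1):
        u = stats.mannwhitneyu(g1, g0, alternative="two-sided")
        res["unmeth_vs_meth_U"], res["unmeth_vs_meth_p"] = \
            float(u.statistic), float(u.pvalue)
    if gene_cv is not None:
        res["per_bin_cv"] = {lab: df.loc[df["bin"] == lab, "cv"].to_numpy()
                             for lab in METH_BIN_LABELS}
    return res
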