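"""Synthetic genomes, bisulphite counts, depth summaries and expression counts.

The generator emulates the data structure of a whole-genome bisulphite +
RNA-seq study of an X0 insect (males hemizygous for X):

* CpG-dominant methylation with bimodal per-site levels — a minority of genes
  carry methylation, their sites drawn from a high Beta; everything else is
  truly unmethylated and only reads as methylated through incomplete
  bisulphite conversion (rate ``conversion_error_lambda``, default 0.45%);
* 3'-biased placement of methylated-gene CpG sites along gene bodies;
* three bisulphite and six expression replicates per morph;
* male X coverage at half the autosomal ratio (hemizygosity);
* male autosomal hypomethylation and X hypermethylation in differentially
  methylated genes;
* a male excess among sex-biased genes, with extreme male bias enriched on X;
* methylation-expression coupling, strongest for X-linked genes.

Generation is a pure function of ``(config, seed)``; the accompanying
:class:`GroundTruth` records every latent label so recovery can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .model import (ASEXUAL_FEMALE, MALE, GeneModel, SampleMeta, SampleSheet,
                    SiteCounts, ValidationError)

MALE_DEPTH_SCALE_DEFAULT = 90.0 / 79.0   # pooled male/female mean-depth ratio


@dataclass
class SimulationConfig:
    # genome geometry
    n_autosomal_scaffolds: int = 24
    n_x_scaffolds: int = 8
    scaffold_length_range: Tuple[int, int] = (24_000, 40_000)
    genes_per_scaffold: int = 6
    gene_length_range: Tuple[int, int] = (2_000, 5_000)
    exons_per_gene: Tuple[int, int] = (2, 6)
    # methylation landscape
    cpg_density: float = 15.0            # CpG sites per kb
    chg_chh_density: float = 15.0        # non-CpG sites per kb (truly unmethylated)
    prop_methylated_genes: float = 0.35
    methylated_level_beta: Tuple[float, float] = (5.0, 1.7)
    unmethylated_level: float = 0.0
    three_prime_bias: float = 3.0        # placement density ramp toward 3'
    # observation model
    conversion_error_lambda: float = 0.0045
    coverage_mean: float = 30.0
    coverage_model: str = "poisson"      # poisson | nb
    coverage_nb_dispersion: float = 0.1
    male_x_coverage_factor: float = 0.5
    male_depth_scale: float = MALE_DEPTH_SCALE_DEFAULT
    n_bs_replicates: int = 3
    n_control_sites: int = 20_000
    depth_bin: int = 25                  # spacing of sampled depth positions
    # sex-specific methylation effects
    frac_dm_genes: float = 0.30          # of methylated genes
    male_autosome_hypo_shift: float = -0.20
    male_x_hyper_shift: float = 0.20
    # expression
    n_expr_replicates: int = 6
    frac_sex_biased_genes: float = 0.33
    male_bias_excess: float = 1.18       # MB : FAB odds among biased genes
    frac_extreme_biased: float = 0.045   # of biased genes, before X enrichment
    x_mb_enrichment: float = 4.0         # odds multiplier, extreme-male on X
    sex_bias_log2fc: float = 1.0         # moderate-bias effect (2-fold)
    extreme_log2fc: float = 3.6          # extreme-bias effect (~12-fold)
    expr_mean_log2_range: Tuple[float, float] = (3.0, 10.0)
    expr_dispersion: float = 0.05
    meth_expr_coupling: float = 2.0      # log2-mean shift per unit methylation
    cv_reduction_for_methylated: float = 0.7
    fc_coupling_autosome: float = 1.0    # log2FC-expr per unit methylation shift
    fc_coupling_x: float = 4.0
    seed: int = 0

    def __post_init__(self):
        for name in ("prop_methylated_genes", "frac_dm_genes",
                     "frac_sex_biased_genes", "frac_extreme_biased",
                     "male_x_coverage_factor", "conversion_error_lambda",
                     "unmethylated_level"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0,1], got {v}")
        if self.three_prime_bias < 1.0:
            raise ValidationError("three_prime_bias must be >= 1")
        if self.coverage_model not in ("poisson", "nb"):
            raise ValidationError("coverage_model must be poisson|nb")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown simulation keys: {sorted(unknown)}")
        d = dict(d)
        for f_ in fields(cls):
            if f_.name in d and isinstance(d[f_.name], list):
                d[f_.name] = tuple(d[f_.name])
        return cls(**d)


@dataclass
class GroundTruth:
    """Latent state behind one simulated dataset."""

    scaffolds: pd.DataFrame    # scaffold, length, linkage
    genes: pd.DataFrame        # gene_id, scaffold, linkage, methylated, is_dm,
                               # level_F, level_M, expr_class, true_log2fc, ...
    sites: pd.DataFrame        # scaffold, pos, strand, context, gene_id,
                               # level_F, level_M

    def to_json(self, path) -> None:
        payload = {k: getattr(self, k).to_dict(orient="list")
                   for k in ("scaffolds", "genes", "sites")}
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(**{k: pd.DataFrame(v) for k, v in payload.items()})


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def _gene_structure(rng, gid, scaffold, strand, start0, length, k_exons):
    """Alternate exon/intron segments; terminal exon ends become UTRs."""
    nseg = 2 * k_exons - 1
    min_seg = max(40, min(200, length // (2 * nseg)))
    w = rng.dirichlet(np.ones(nseg)) * (length - nseg * min_seg) + min_seg
    bounds = start0 + np.concatenate([[0], np.cumsum(w)]).astype(int)
    bounds[-1] = start0 + length
    exons = [(int(bounds[i]), int(bounds[i + 1]))
             for i in range(0, nseg, 2)]
    # UTRs: 100 bp at the 5' terminus, 150 bp at the 3' terminus
    first, last = exons[0], exons[-1]
    if strand == "+":
        utr5 = [(first[0], min(first[0] + 100, first[1]))]
        utr3 = [(max(last[1] - 150, last[0]), last[1])]
    else:
        utr5 = [(max(last[1] - 100, last[0]), last[1])]
        utr3 = [(first[0], min(first[0] + 150, first[1]))]
    cds = []
    lo = utr5[0][1] if strand == "+" else utr3[0][1]
    hi = utr3[0][0] if strand == "+" else utr5[0][0]
    for a, b in exons:
        aa, bb = max(a, lo), min(b, hi)
        if bb > aa:
            cds.append((aa, bb))
    return GeneModel(gene_id=gid, scaffold=scaffold, strand=strand,
                     start0=start0, end0=start0 + length, exons=exons,
                     cds=cds, utr5=utr5, utr3=utr3)


def _sample_3prime_biased(rng, n, bias):
    """Positions in [0,1) with linear density 1 at the 5' end, ``bias`` at 3'."""
    u = rng.random(n)
    if bias == 1.0:
        return u
    b = bias
    c = 1.0 + (b - 1.0) / 2.0
    return (-1.0 + np.sqrt(1.0 + 2.0 * (b - 1.0) * c * u)) / (b - 1.0)


def simulate_genome(config: SimulationConfig,
                    rng: np.random.Generator | None = None):
    """Build scaffolds, gene models, CpG/CHG/CHH site placements and the
    latent methylation state.

    Returns ``(genes, scaffold_table, truth)``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    lo, hi = cfg.scaffold_length_range
    if cfg.gene_length_range[1] > lo:
        raise ValidationError("gene_length_range exceeds shortest scaffold")

    names, lengths, linkage = [], [], []
    for i in range(cfg.n_autosomal_scaffolds + cfg.n_x_scaffolds):
        names.append(f"scaffold_{i + 1}")
        lengths.append(int(rng.integers(lo, hi + 1)))
        linkage.append("X" if i >= cfg.n_autosomal_scaffolds else "A")
    scaffolds = pd.DataFrame({"scaffold": names, "length": lengths,
                              "linkage": linkage})

    genes: List[GeneModel] = []
    gene_rows = []
    for scaf, L, link in zip(names, lengths, linkage):
        cursor = int(rng.integers(200, 1200))
        for j in range(cfg.genes_per_scaffold):
            glen = int(rng.integers(*cfg.gene_length_range))
            if cursor + glen > L - 200:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            k = int(rng.integers(cfg.exons_per_gene[0],
                                 cfg.exons_per_gene[1] + 1))
            gid = f"{scaf}_g{j + 1}"
            gm = _gene_structure(rng, gid, scaf, strand, cursor, glen, k)
            genes.append(gm)
            methylated = rng.random() < cfg.prop_methylated_genes
            is_dm = bool(methylated and rng.random() < cfg.frac_dm_genes)
            gene_rows.append(dict(gene_id=gid, scaffold=scaf, linkage=link,
                                  strand=strand, start0=cursor,
                                  end0=cursor + glen, methylated=methylated,
                                  is_dm=is_dm))
            cursor += glen + int(rng.integers(500, 2000))
    gene_df = pd.DataFrame(gene_rows)
    if gene_df.empty:
        raise ValidationError("no genes fit on the simulated scaffolds")

    # --- site placement -----------------------------------------------------
    a, b = cfg.methylated_level_beta
    site_rows = []
    gene_by_scaf: Dict[str, list] = {}
    for row in gene_rows:
        gene_by_scaf.setdefault(row["scaffold"], []).append(row)

    for scaf, L, link in zip(names, lengths, linkage):
        rows_here = gene_by_scaf.get(scaf, [])
        meth_spans = [(r["start0"], r["end0"], r) for r in rows_here
                      if r["methylated"]]
        # methylated genes: 3'-biased CpG placement, Beta per-site levels
        for s0, e0, r in meth_spans:
            n_sites = rng.poisson((e0 - s0) * cfg.cpg_density / 1000.0)
            frac = _sample_3prime_biased(rng, n_sites, cfg.three_prime_bias)
            if r["strand"] == "+":
                pos0 = s0 + (frac * (e0 - s0)).astype(int)
            else:                      # 3' end is the low-coordinate end
                pos0 = e0 - 1 - (frac * (e0 - s0)).astype(int)
            lev_F = rng.beta(a, b, n_sites)
            shift = (cfg.male_x_hyper_shift if link == "X"
                     else cfg.male_autosome_hypo_shift) if r["is_dm"] else 0.0
            lev_M = np.clip(lev_F + shift, 0.0, 1.0)
            for p0, lf, lm in zip(pos0, lev_F, lev_M):
                site_rows.append((scaf, int(p0) + 1,
                                  "+" if rng.random() < 0.5 else "-", "CpG",
                                  r["gene_id"], float(lf), float(lm)))
        # everywhere else: unmethylated CpGs at the same density
        meth_len = sum(e - s for s, e, _ in meth_spans)
        n_bg = rng.poisson((L - meth_len) * cfg.cpg_density / 1000.0)
        bg_pos = _uniform_outside(rng, n_bg, L, [(s, e) for s, e, _ in meth_spans])
        for p0 in bg_pos:
            gid = _containing_gene(rows_here, p0)
            site_rows.append((scaf, int(p0) + 1,
                              "+" if rng.random() < 0.5 else "-", "CpG",
                              gid, cfg.unmethylated_level,
                              cfg.unmethylated_level))
        # non-CpG contexts, truly unmethylated
        n_h = rng.poisson(L * cfg.chg_chh_density / 1000.0)
        for p0 in rng.integers(0, L, n_h):
            ctx = "CHG" if rng.random() < 0.5 else "CHH"
            site_rows.append((scaf, int(p0) + 1,
                              "+" if rng.random() < 0.5 else "-", ctx,
                              _containing_gene(rows_here, p0), 0.0, 0.0))

    sites = pd.DataFrame(site_rows, columns=["scaffold", "pos", "strand",
                                             "context", "gene_id",
                                             "level_F", "level_M"])
    sites = (sites.drop_duplicates(subset=["scaffold", "pos", "strand"])
             .sort_values(["scaffold", "pos", "strand"], kind="mergesort")
             .reset_index(drop=True))

    # gene-level true levels = mean of member CpG site levels
    cpg = sites[sites["context"] == "CpG"]
    means = cpg[cpg["gene_id"] != ""].groupby("gene_id")[
        ["level_F", "level_M"]].mean()
    gene_df = gene_df.merge(means, left_on="gene_id", right_index=True,
                            how="left")
    gene_df[["level_F", "level_M"]] = gene_df[["level_F", "level_M"]].fillna(0.0)

    truth = GroundTruth(scaffolds=scaffolds, genes=gene_df, sites=sites)
    _attach_expression_truth(truth, cfg, rng)
    return genes, scaffolds, truth


def _uniform_outside(rng, n, L, spans):
    """n uniform 0-based positions on [0,L) avoiding the given spans."""
    spans = sorted(spans)
    gaps, cum = [], []
    prev, total = 0, 0
    for s, e in spans + [(L, L)]:
        if s > prev:
            gaps.append((prev, s))
            total += s - prev
            cum.append(total)
        prev = max(prev, e)
    if not gaps or total <= 0:
        return np.empty(0, dtype=int)
    u = rng.random(n) * total
    idx = np.searchsorted(cum, u, side="right")
    starts = np.array([g[0] for g in gaps])
    offs = u - np.concatenate([[0], np.asarray(cum)[:-1]])[idx]
    return (starts[idx] + offs).astype(int)


def _containing_gene(rows, p0):
    for r in rows:
        if r["start0"] <= p0 < r["end0"]:
            return r["gene_id"]
    return ""


def _attach_expression_truth(truth: GroundTruth, cfg: SimulationConfig, rng):
    g = truth.genes
    n = len(g)
    lo, hi = cfg.expr_mean_log2_range
    base = rng.uniform(lo, hi, n)
    base = base + cfg.meth_expr_coupling * g["level_F"].to_numpy()
    biased = rng.random(n) < cfg.frac_sex_biased_genes
    p_male = cfg.male_bias_excess / (1.0 + cfg.male_bias_excess)
    male_dir = rng.random(n) < p_male
    p_ext = np.full(n, cfg.frac_extreme_biased)
    on_x = (g["linkage"] == "X").to_numpy()
    odds = p_ext / (1 - p_ext) * np.where(on_x & male_dir,
                                          cfg.x_mb_enrichment, 1.0)
    p_ext = odds / (1 + odds)
    extreme = rng.random(n) < p_ext
    fc = np.where(extreme, cfg.extreme_log2fc, cfg.sex_bias_log2fc)
    log2fc = np.where(biased, np.where(male_dir, fc, -fc), 0.0)
    # methylation-change coupling (drives the FC_Expr ~ FC_Meth association)
    dlevel = (g["level_M"] - g["level_F"]).to_numpy()
    slope = np.where(on_x, cfg.fc_coupling_x, cfg.fc_coupling_autosome)
    log2fc = log2fc + slope * dlevel
    disp = np.where(g["methylated"].to_numpy(),
                    cfg.expr_dispersion * cfg.cv_reduction_for_methylated ** 2,
                    cfg.expr_dispersion)
    cls = np.where(~biased, "UB",
                   np.where(male_dir, np.where(extreme, "MB+", "MB"),
                            np.where(extreme, "FAB+", "FAB")))
    g["expr_base_log2"] = base
    g["true_log2fc"] = log2fc
    g["expr_dispersion"] = disp
    g["expr_class"] = cls


# ---------------------------------------------------------------------------
# bisulphite counts
# ---------------------------------------------------------------------------

def bs_sample_ids(cfg: SimulationConfig) -> Dict[str, List[str]]:
    return {ASEXUAL_FEMALE: [f"F{i + 1}" for i in range(cfg.n_bs_replicates)],
            MALE: [f"M{i + 1}" for i in range(cfg.n_bs_replicates)]}


def _draw_coverage(rng, mean, size, cfg: SimulationConfig):
    if cfg.coverage_model == "nb":
        alpha = cfg.coverage_nb_dispersion
        lam = rng.gamma(1.0 / alpha, np.asarray(mean) * alpha, size=size)
        return rng.poisson(lam)
    return rng.poisson(mean, size=size)


def simulate_bisulphite_counts(truth: GroundTruth, cfg: SimulationConfig,
                               rng: np.random.Generator):
    """Observed per-site counts per sample, plus control-genome counts.

    Coverage ~ Poisson(coverage_mean x linkage/sex factor); the methylated
    read count is Binomial(n, m_true + (1 - m_true) * lambda): incomplete
    conversion only ever inflates methylation, never deflates it.
    """
    sites = truth.sites
    link = sites["scaffold"].map(
        truth.scaffolds.set_index("scaffold")["linkage"]).to_numpy()
    lam = cfg.conversion_error_lambda
    n_sites = len(sites)
    df = sites[["scaffold", "pos", "strand", "context"]].copy()
    samples = []
    for group, ids in bs_sample_ids(cfg).items():
        level = (sites["level_M"] if group == MALE else
                 sites["level_F"]).to_numpy()
        p_obs = level + (1.0 - level) * lam
        for sid in ids:
            mean = np.full(n_sites, cfg.coverage_mean)
            if group == MALE:
                mean = mean * cfg.male_depth_scale
                mean[link == "X"] *= cfg.male_x_coverage_factor
            n = _draw_coverage(rng, mean, n_sites, cfg)
            m = rng.binomial(n, p_obs)
            df["m_" + sid] = m
            df["u_" + sid] = n - m
            samples.append(sid)
    counts = SiteCounts(df, samples)

    # control genome: truly unmethylated everywhere
    ctrl = pd.DataFrame({
        "scaffold": "control_1",
        "pos": np.arange(1, cfg.n_control_sites + 1) * 3,
        "strand": np.where(np.arange(cfg.n_control_sites) % 2 == 0, "+", "-"),
        "context": np.tile(["CpG", "CHG", "CHH"],
                           cfg.n_control_sites // 3 + 1)[:cfg.n_control_sites],
    })
    for sid in samples:
        n = _draw_coverage(rng, np.full(cfg.n_control_sites,
                                        cfg.coverage_mean),
                           cfg.n_control_sites, cfg)
        m = rng.binomial(n, lam)
        ctrl["m_" + sid] = m
        ctrl["u_" + sid] = n - m
    control = SiteCounts(ctrl, samples)
    return counts, control


# ---------------------------------------------------------------------------
# depth summaries
# ---------------------------------------------------------------------------

def simulate_depth(truth: GroundTruth, cfg: SimulationConfig,
                   rng: np.random.Generator):
    """Pooled per-group depth at positions sampled every ``depth_bin`` bases.

    Female pooled mean = coverage_mean x replicates; male pooled mean is
    scaled by ``male_depth_scale`` genome-wide and halved on X scaffolds.
    """
    rows_F, rows_M = [], []
    meanF = cfg.coverage_mean * cfg.n_bs_replicates
    for r in truth.scaffolds.itertuples():
        pos = np.arange(1, r.length + 1, cfg.depth_bin)
        f = rng.poisson(meanF, len(pos))
        m_mean = meanF * cfg.male_depth_scale * (
            cfg.male_x_coverage_factor if r.linkage == "X" else 1.0)
        m = rng.poisson(m_mean, len(pos))
        rows_F.append(pd.DataFrame({"scaffold": r.scaffold, "pos": pos,
                                    "depth": f}))
        rows_M.append(pd.DataFrame({"scaffold": r.scaffold, "pos": pos,
                                    "depth": m}))
    return (pd.concat(rows_F, ignore_index=True),
            pd.concat(rows_M, ignore_index=True))


# ---------------------------------------------------------------------------
# expression counts
# ---------------------------------------------------------------------------

def expr_sample_ids(cfg: SimulationConfig) -> Dict[str, List[str]]:
    return {ASEXUAL_FEMALE: [f"FE{i + 1}" for i in range(cfg.n_expr_replicates)],
            MALE: [f"ME{i + 1}" for i in range(cfg.n_expr_replicates)]}


def simulate_expression_counts(truth: GroundTruth, cfg: SimulationConfig,
                               rng: np.random.Generator):
    """Gene x sample negative-binomial counts plus effective lengths."""
    g = truth.genes
    n = len(g)
    base = 2.0 ** g["expr_base_log2"].to_numpy()
    fc = g["true_log2fc"].to_numpy()
    disp = g["expr_dispersion"].to_numpy()
    cols = {}
    for group, ids in expr_sample_ids(cfg).items():
        sign = 0.5 if group == MALE else -0.5
        mu = base * 2.0 ** (sign * fc)
        for sid in ids:
            lam = rng.gamma(1.0 / disp, mu * disp)
            cols[sid] = rng.poisson(lam)
    counts = pd.DataFrame(cols, index=g["gene_id"].to_numpy())
    counts.index.name = "gene_id"
    lengths = pd.Series((g["end0"] - g["start0"]).to_numpy(dtype=float) * 0.6,
                        index=counts.index, name="effective_length")
    return counts, lengths


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

def sample_sheet_for(cfg: SimulationConfig) -> SampleSheet:
    samples = []
    for group, ids in bs_sample_ids(cfg).items():
        samples += [SampleMeta(sid, group, i + 1, "bisulphite")
                    for i, sid in enumerate(ids)]
    for group, ids in expr_sample_ids(cfg).items():
        samples += [SampleMeta(sid, group, i + 1, "expression")
                    for i, sid in enumerate(ids)]
    return SampleSheet(samples)


def simulate_dataset(cfg: SimulationConfig):
    """One full in-memory dataset: the primary entry point for tests.

    Returns a dict with keys ``genes, scaffolds, truth, counts, control,
    depth_F, depth_M, expr_counts, expr_lengths, sheet``.
    """
    rng = np.random.default_rng(cfg.seed)
    genes, scaffolds, truth = simulate_genome(cfg, rng)
    counts, control = simulate_bisulphite_counts(truth, cfg, rng)
    depth_F, depth_M = simulate_depth(truth, cfg, rng)
    expr_counts, expr_lengths = simulate_expression_counts(truth, cfg, rng)
    return dict(genes=genes, scaffolds=scaffolds, truth=truth, counts=counts,
                control=control, depth_F=depth_F, depth_M=depth_M,
                expr_counts=expr_counts, expr_lengths=expr_lengths,
                sheet=sample_sheet_for(cfg))


def simulate_to_dir(cfg: SimulationConfig, outdir) -> dict:
    """Emit exactly the formats the readers accept, plus ground_truth.json."""
    from . import io as aio
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    data = simulate_dataset(cfg)
    aio.write_gff3(data["genes"], out / "annotation.gff3")
    for sid in data["counts"].samples:
        aio.write_cytosine_report(data["counts"].df, out / f"{sid}.cov.tsv",
                                  m_col="m_" + sid, u_col="u_" + sid)
        aio.write_cytosine_report(data["control"].df,
                                  out / f"{sid}.control.tsv",
                                  m_col="m_" + sid, u_col="u_" + sid)
    aio.write_counts_table(data["expr_counts"], data["expr_lengths"],
                           out / "expression_counts.tsv")
    aio.write_depth_table(data["depth_F"], out / "depth_F.tsv")
    aio.write_depth_table(data["depth_M"], out / "depth_M.tsv")
    aio.write_sample_sheet(data["sheet"], out / "samples.tsv")
    data["scaffolds"].to_csv(out / "scaffolds.tsv", sep="\t", index=False)
    data["truth"].to_json(out / "ground_truth.json")
    (out / "sim_config.json").write_text(json.dumps(cfg.to_dict()))
    return data
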