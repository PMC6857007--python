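"""End-to-end orchestration: call -> aggregate -> dm -> de -> assign-x ->
integrate, with a reproducibility manifest.

Inputs are a directory of the plain-text formats the readers accept (the
same layout :func:`aphimeth.simulate.simulate_to_dir` emits); outputs are a
directory of TSVs plus ``manifest.json``.  Stages are skipped on rerun when
their inputs, config and seed are unchanged (checksum comparison).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import io as aio
from .model import ASEXUAL_FEMALE, MALE, AnalysisConfig, ValidationError
from . import calling, dm, expression, integrate, sexchrom

log = logging.getLogger("aphimeth")

STAGES = ("call", "aggregate", "metagene", "dm_sites", "dm_genes", "de",
          "assign_x", "integrate")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: AnalysisConfig, seed: int) -> str:
    payload = json.dumps({"config": config.to_dict(), "seed": seed},
                         sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


class PipelineRun:
    """One pipeline invocation over an input directory."""

    def __init__(self, input_dir, outdir,
                 config: Optional[AnalysisConfig] = None, seed: int = 0,
                 force: bool = False):
        self.input_dir = Path(input_dir)
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.config = config or AnalysisConfig()
        self.seed = seed
        self.force = force
        self.sheet = aio.read_sample_sheet(self.input_dir / "samples.tsv")
        self.manifest: Dict = {"config_hash": _config_hash(self.config, seed),
                               "seed": seed, "inputs": {}, "stages": {},
                               "started": time.strftime("%Y-%m-%dT%H:%M:%S")}
        self._prev = self._load_previous_manifest()
        self._cache: Dict = {}

    # -- manifest / skip machinery -----------------------------------------

    def _load_previous_manifest(self):
        p = self.outdir / "manifest.json"
        if p.exists():
            try:
                return json.loads(p.read_text())
            except json.JSONDecodeError:
                return None
        return None

    def _input_hashes(self, paths) -> Dict[str, str]:
        out = {}
        for p in paths:
            p = Path(p)
            if not p.exists():
                raise ValidationError(f"missing input file {p}")
            out[p.name] = _sha256(p)
        return out

    def _up_to_date(self, stage: str, in_hashes: Dict[str, str],
                    outputs) -> bool:
        if self.force or self._prev is None:
            return False
        prev = self._prev.get("stages", {}).get(stage)
        if not prev:
            return False
        if self._prev.get("config_hash") != self.manifest["config_hash"]:
            return False
        if prev.get("inputs") != in_hashes:
            return False
        return all((self.outdir / o).exists() for o in outputs)

    def _record(self, stage: str, in_hashes, outputs, rows: int,
                skipped: bool):
        self.manifest["inputs"].update(in_hashes)
        self.manifest["stages"][stage] = {
            "inputs": in_hashes, "outputs": list(outputs), "rows": rows,
            "skipped": skipped,
            "finished": time.strftime("%Y-%m-%dT%H:%M:%S")}

    def _write_manifest(self):
        (self.outdir / "manifest.json").write_text(
            json.dumps(self.manifest, indent=1, sort_keys=True))

    # -- data loading -------------------------------------------------------

    def _bs_groups(self):
        return {g: self.sheet.ids("bisulphite", g)
                for g in (ASEXUAL_FEMALE, MALE)}

    def _expr_groups(self):
        return {g: self.sheet.ids("expression", g)
                for g in (ASEXUAL_FEMALE, MALE)}

    def _load_sites(self):
        if "sites" not in self._cache:
            ids = self.sheet.ids("bisulphite")
            self._cache["sites"] = aio.read_site_counts(
                {s: self.input_dir / f"{s}.cov.tsv" for s in ids})
            self._cache["control"] = aio.read_site_counts(
                {s: self.input_dir / f"{s}.control.tsv" for s in ids})
        return self._cache["sites"], self._cache["control"]

    def _load_genes(self):
        if "genes" not in self._cache:
            self._cache["genes"] = aio.read_gff3(
                self.input_dir / "annotation.gff3")
        return self._cache["genes"]

    # -- stages -------------------------------------------------------------

    def stage_call(self):
        ids = self.sheet.ids("bisulphite")
        inputs = [self.input_dir / f"{s}.cov.tsv" for s in ids] + \
            [self.input_dir / f"{s}.control.tsv" for s in ids]
        hashes = self._input_hashes(inputs)
        outputs = ["site_calls.tsv", "conversion_error.json",
                   "context_summary.tsv"]
        if self._up_to_date("call", hashes, outputs):
            log.info("call: up to date, skipping")
            self._record("call", hashes, outputs, 0, skipped=True)
            return
        sites, control = self._load_sites()
        err = calling.estimate_conversion_error(control)
        calls = calling.call_methylated_sites(sites, err.lam, self.config)
        ctx = calling.context_methylation_summary(sites)
        calls.to_csv(self.outdir / "site_calls.tsv", sep="\t", index=False)
        (self.outdir / "conversion_error.json").write_text(json.dumps(
            {"lambda": err.lam, "n_control_sites": err.n_control_sites,
             "per_sample": err.per_sample_lambdas}))
        ctx.to_csv(self.outdir / "context_summary.tsv", sep="\t")
        self._cache["lambda"] = err.lam
        self._cache["calls"] = calls
        self._record("call", hashes, outputs, len(calls), skipped=False)

    def stage_aggregate(self):
        ids = self.sheet.ids("bisulphite")
        inputs = [self.input_dir / f"{s}.cov.tsv" for s in ids] + \
            [self.input_dir / "annotation.gff3"]
        hashes = self._input_hashes(inputs)
        outputs = ["feature_methylation.tsv", "gene_methylation.tsv"]
        if self._up_to_date("aggregate", hashes, outputs):
            log.info("aggregate: up to date, skipping")
            self._record("aggregate", hashes, outputs, 0, skipped=True)
            return
        sites, _ = self._load_sites()
        genes = self._load_genes()
        feat = calling.aggregate_feature_methylation(sites, genes)
        gm = calling.gene_methylation_levels(
            sites, genes, {"F": self._bs_groups()[ASEXUAL_FEMALE],
                           "M": self._bs_groups()[MALE]})
        feat.to_csv(self.outdir / "feature_methylation.tsv", sep="\t",
                    index=False)
        gm.to_csv(self.outdir / "gene_methylation.tsv", sep="\t")
        self._cache["gene_meth"] = gm
        self._record("aggregate", hashes, outputs, len(feat), skipped=False)

    def stage_metagene(self):
        ids = self.sheet.ids("bisulphite")
        inputs = [self.input_dir / f"{s}.cov.tsv" for s in ids] + \
            [self.input_dir / "annotation.gff3"]
        hashes = self._input_hashes(inputs)
        outputs = ["metagene.tsv"]
        if self._up_to_date("metagene", hashes, outputs):
            log.info("metagene: up to date, skipping")
            self._record("metagene", hashes, outputs, 0, skipped=True)
            return
        sites, _ = self._load_sites()
        genes = self._load_genes()
        calls = self._cache.get("calls")
        cpg = sites.in_context("CpG")
        if calls is not None:
            meth_keys = calling.sites_methylated_in_any_sample(calls)
            key = cpg.df.merge(meth_keys.assign(_m=True),
                               on=["scaffold", "pos", "strand"], how="left")
            mask = key["_m"].notna().to_numpy()
        else:
            mask = None
        prof = calling.metagene_profile(cpg.df, genes, methylated_mask=mask)
        prof.to_frame().to_csv(self.outdir / "metagene.tsv", sep="\t",
                               index=False)
        self._record("metagene", hashes, outputs, len(prof.covered),
                     skipped=False)

    def stage_dm_sites(self):
        ids = self.sheet.ids("bisulphite")
        inputs = [self.input_dir / f"{s}.cov.tsv" for s in ids]
        hashes = self._input_hashes(inputs)
        outputs = ["dm_sites.tsv", "calibration_report.tsv",
                   "pca_scores.tsv"]
        if self._up_to_date("dm_sites", hashes, outputs):
            log.info("dm_sites: up to date, skipping")
            self._record("dm_sites", hashes, outputs, 0, skipped=True)
            return
        sites, _ = self._load_sites()
        cpg = sites.in_context("CpG")
        keep = dm.filter_dm_sites(cpg, self.config)
        sub = cpg.subset(keep)
        groups = self._bs_groups()
        rec = dm.dm_logistic_test(sub, groups)
        rec = dm.classify_dm(rec, self.config.site_dm_min_diff,
                             self.config.fdr)
        rec.to_csv(self.outdir / "dm_sites.tsv", sep="\t", index=False)
        self._cache["dm_sites"] = rec
        # calibration over pseudo-groupings
        gps = dm.enumerate_pair_groupings(groups[ASEXUAL_FEMALE],
                                          groups[MALE])
        calib = dm.calibrate_dm_threshold(
            cpg, gps, thresholds=[5, 10, 15, 20, 25], config=self.config)
        calib.to_csv(self.outdir / "calibration_report.tsv", sep="\t",
                     index=False)
        # PCA on sites methylated in >= 1 sample
        calls = self._cache.get("calls")
        if calls is not None:
            keys = calling.sites_methylated_in_any_sample(calls)
            if len(keys) >= 2:
                mat = dm.site_level_matrix(cpg, keys)
                if mat.shape[1] >= 2:
                    pca = dm.methylation_pca(mat)
                    scores = pca["scores"]
                    scores["variance_fraction"] = np.resize(
                        pca["variance_fraction"], len(scores))
                    scores.to_csv(self.outdir / "pca_scores.tsv", sep="\t")
        if not (self.outdir / "pca_scores.tsv").exists():
            pd.DataFrame().to_csv(self.outdir / "pca_scores.tsv", sep="\t")
        self._record("dm_sites", hashes, outputs, len(rec), skipped=False)

    def stage_dm_genes(self):
        ids = self.sheet.ids("bisulphite")
        inputs = [self.input_dir / f"{s}.cov.tsv" for s in ids] + \
            [self.input_dir / "annotation.gff3"]
        hashes = self._input_hashes(inputs)
        outputs = ["dm_genes.tsv"]
        if self._up_to_date("dm_genes", hashes, outputs):
            log.info("dm_genes: up to date, skipping")
            self._record("dm_genes", hashes, outputs, 0, skipped=True)
            return
        sites, _ = self._load_sites()
        genes = self._load_genes()
        cpg = sites.in_context("CpG")
        owner = calling.assign_sites_to_intervals(cpg.df, genes, "gene")
        gene_counts = _pool_gene_counts(cpg, owner)
        cov = pd.DataFrame({s: gene_counts["m_" + s] + gene_counts["u_" + s]
                            for s in cpg.samples})
        keep = dm.filter_dm_units(cov, self.config.gene_min_reads,
                                  self.config.gene_coverage_top_quantile_drop)
        gene_counts = gene_counts[keep]
        rec = dm.dm_gene_test(gene_counts, self._bs_groups())
        rec = dm.classify_dm(rec, self.config.gene_dm_min_diff,
                             self.config.fdr)
        rec.to_csv(self.outdir / "dm_genes.tsv", sep="\t", index=False)
        self._cache["dm_genes"] = rec
        self._record("dm_genes", hashes, outputs, len(rec), skipped=False)

    def stage_de(self):
        inputs = [self.input_dir / "expression_counts.tsv"]
        hashes = self._input_hashes(inputs)
        outputs = ["expression.tsv"]
        if self._up_to_date("de", hashes, outputs):
            log.info("de: up to date, skipping")
            self._record("de", hashes, outputs, 0, skipped=True)
            return
        counts, lengths = aio.read_counts_table(
            self.input_dir / "expression_counts.tsv",
            samples=self.sheet.ids("expression"))
        groups = self._expr_groups()
        keep = expression.expression_filter(counts, self.config.cpm_threshold,
                                            self.config.cpm_min_samples)
        fpkm = expression.compute_fpkm(counts, lengths)
        de = expression.de_test(counts[keep.to_numpy()].copy()
                                if keep.dtype == bool else counts[keep],
                                groups, self.config)
        de = expression.classify_sex_bias(de, fpkm, groups, self.config)
        for g, name in ((ASEXUAL_FEMALE, "cv_F"), (MALE, "cv_M")):
            de[name] = expression.compute_cv(fpkm, groups[g]).reindex(de.index)
        de.to_csv(self.outdir / "expression.tsv", sep="\t")
        self._cache["de"] = de
        self._cache["fpkm"] = fpkm
        self._record("de", hashes, outputs, len(de), skipped=False)

    def stage_assign_x(self):
        inputs = [self.input_dir / "depth_F.tsv",
                  self.input_dir / "depth_M.tsv",
                  self.input_dir / "scaffolds.tsv"]
        hashes = self._input_hashes(inputs)
        outputs = ["assignments.tsv", "assignments.bed"]
        if self._up_to_date("assign_x", hashes, outputs):
            log.info("assign_x: up to date, skipping")
            self._record("assign_x", hashes, outputs, 0, skipped=True)
            return
        dF = aio.read_depth_table(self.input_dir / "depth_F.tsv")
        dM = aio.read_depth_table(self.input_dir / "depth_M.tsv")
        scaf = pd.read_csv(self.input_dir / "scaffolds.tsv", sep="\t")
        lengths = scaf.set_index("scaffold")["length"]
        asg = sexchrom.assign_linkage(
            sexchrom.scaffold_depth_summary(dF),
            sexchrom.scaffold_depth_summary(dM), lengths, self.config)
        asg.to_csv(self.outdir / "assignments.tsv", sep="\t", index=False)
        with open(self.outdir / "assignments.bed", "w") as fh:
            for r in asg.itertuples():
                fh.write(f"{r.scaffold}\t0\t{r.length}\t{r.linkage}\n")
        self._cache["assignments"] = asg
        self._record("assign_x", hashes, outputs, len(asg), skipped=False)

    def stage_integrate(self):
        hashes = {}          # depends on upstream outputs, re-derived in-run
        outputs = ["joint_table.tsv", "enrichment.tsv", "glm_report.json"]
        gm = self._cache.get("gene_meth")
        de = self._cache.get("de")
        asg = self._cache.get("assignments")
        for name, obj, fname in (("aggregate", gm, "gene_methylation.tsv"),
                                 ("de", de, "expression.tsv"),
                                 ("assign_x", asg, "assignments.tsv")):
            if obj is None and not (self.outdir / fname).exists():
                raise ValidationError(
                    f"integrate: missing upstream stage {name} ({fname})")
        if gm is None:
            gm = pd.read_csv(self.outdir / "gene_methylation.tsv", sep="\t",
                             index_col=0)
        if de is None:
            de = pd.read_csv(self.outdir / "expression.tsv", sep="\t",
                             index_col=0)
        if asg is None:
            asg = pd.read_csv(self.outdir / "assignments.tsv", sep="\t")
        genes = self._load_genes()
        gene_scaf = pd.Series({g.gene_id: g.scaffold for g in genes})
        jt = integrate.joint_table(gm, de, asg, self.config)
        jt = integrate.attach_linkage(jt, gene_scaf, asg)
        dm_rec = self._cache.get("dm_genes")
        if dm_rec is None and (self.outdir / "dm_genes.tsv").exists():
            dm_rec = pd.read_csv(self.outdir / "dm_genes.tsv", sep="\t")
        if dm_rec is not None:
            jt = jt.join(dm_rec.set_index("unit_id")["bias_class"]
                         .rename("dm_class"), how="left")
            jt["dm_class"] = jt["dm_class"].fillna("UB")
        jt.to_csv(self.outdir / "joint_table.tsv", sep="\t")
        enr = integrate.enrichment_contrasts(jt)
        enr.to_csv(self.outdir / "enrichment.tsv", sep="\t", index=False)
        report = {}
        try:
            corr = integrate.fc_correlation(jt)
            report["spearman"] = corr
            if (jt["linkage"] == "X").sum() >= 3 and \
                    (jt["linkage"] == "A").sum() >= 3:
                report["spearman_X"] = integrate.fc_correlation(jt, "X")
                report["spearman_A"] = integrate.fc_correlation(jt, "A")
                report["interaction"] = integrate.interaction_glm(jt)
        except ValidationError as exc:
            report["error"] = str(exc)
        (self.outdir / "glm_report.json").write_text(
            json.dumps(report, default=float))
        self._record("integrate", hashes, outputs, len(jt), skipped=False)

    # -- driver -------------------------------------------------------------

    def run_all(self) -> dict:
        handlers = {"call": self.stage_call, "aggregate": self.stage_aggregate,
                    "metagene": self.stage_metagene,
                    "dm_sites": self.stage_dm_sites,
                    "dm_genes": self.stage_dm_genes, "de": self.stage_de,
                    "assign_x": self.stage_assign_x,
                    "integrate": self.stage_integrate}
        for stage in STAGES:
            log.info("running stage %s", stage)
            try:
                handlers[stage]()
            except Exception:
                log.error("stage %s failed", stage)
                self._write_manifest()
                raise
        self.manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        self._write_manifest()
        return self.manifest


def _pool_gene_counts(sites, owner) -> pd.DataFrame:
    df = sites.df.copy()
    df["_owner"] = owner
    df = df[df["_owner"] != ""]
    cols = [c for c in df.columns if c.startswith(("m_", "u_"))]
    return df.groupby("_owner")[cols].sum()


def run_all(input_dir, outdir, config: Optional[AnalysisConfig] = None,
            seed: int = 0, force: bool = False) -> dict:
    """Convenience wrapper: run every stage and return the manifest."""
    return PipelineRun(input_dir, outdir, config=config, seed=seed,
                       force=force).run_all()
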