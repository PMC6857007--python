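"""Readers and writers for every external format the pipeline touches.

Formats: per-cytosine report TSV (7 columns, the dialect bisulphite aligners
emit), GFF3 gene annotation, gene x sample count tables with effective
lengths, sample sheets, and per-position depth summaries.  All on-disk
coordinates are 1-based inclusive; see :mod:`aphimeth.model` for the internal
convention.
"""

from __future__ import annotations

import gzip
import warnings
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .model import (GeneModel, ParseError, SampleSheet, SiteCounts,
                    ValidationError, normalize_context)

REPORT_COLUMNS = ["scaffold", "pos", "strand", "m", "u", "context", "tri"]


def _open(path, mode="rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# cytosine reports
# ---------------------------------------------------------------------------

def read_cytosine_report(path, sample_id: str) -> pd.DataFrame:
    """Read one sample's per-cytosine report.

    Columns: chromosome, position, strand, count_methylated,
    count_unmethylated, context, trinucleotide.  Zero-coverage rows are
    retained.  Returns a frame with columns
    ``scaffold, pos, strand, context, m, u`` for :meth:`SiteCounts.merge`.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=REPORT_COLUMNS,
                         dtype={"scaffold": str, "strand": str,
                                "context": str, "tri": str},
                         comment="#")
    except Exception as exc:  # delegate precise line to a slow re-scan
        raise ParseError(f"cannot parse cytosine report {path}: {exc}") from exc
    if df.empty:
        return pd.DataFrame(columns=["scaffold", "pos", "strand", "context",
                                     "m", "u"])
    for col in ("pos", "m", "u"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            raise ParseError(f"non-numeric value in column {col!r}",
                             line=int(bad.idxmax()) + 1)
        df[col] = vals.astype(np.int64)
    neg = (df["m"] < 0) | (df["u"] < 0)
    if neg.any():
        raise ValidationError(
            f"negative counts at line {int(neg.idxmax()) + 1} in {path}")
    if (df["pos"] < 1).any():
        raise ValidationError(f"non-positive coordinate in {path}")
    if not df["strand"].isin(["+", "-"]).all():
        raise ValidationError(f"bad strand value in {path}")
    df["context"] = df["context"].map(normalize_context)
    dup = df.duplicated(subset=["scaffold", "pos", "strand"])
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise ValidationError(
            f"duplicate site ({row.scaffold},{row.pos},{row.strand}) in {path}")
    df.attrs["sample_id"] = sample_id
    return df[["scaffold", "pos", "strand", "context", "m", "u"]]


def write_cytosine_report(df: pd.DataFrame, path,
                          m_col: str = "m", u_col: str = "u") -> None:
    out = df[["scaffold", "pos", "strand", m_col, u_col, "context"]].copy()
    out["tri"] = df["tri"] if "tri" in df.columns else out["context"].map(
        {"CpG": "CGN", "CHG": "CHG", "CHH": "CHH"})
    with _open(path, "wt") as fh:
        out.to_csv(fh, sep="\t", header=False, index=False)


def read_site_counts(paths: Dict[str, str]) -> SiteCounts:
    """Read one report per sample and outer-join them into a SiteCounts."""
    return SiteCounts.merge({sid: read_cytosine_report(p, sid)
                             for sid, p in paths.items()})


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path) -> List[GeneModel]:
    """Parse gene models from GFF3 via an in-memory gffutils database.

    Per gene: the union of exons over all mRNAs, and the CDS intervals of the
    mRNA with the longest total CDS.  UTRs follow the chosen CDS's mRNA.
    Features without a resolvable gene parent are skipped with a warning.
    """
    import gffutils
    from gffutils.exceptions import EmptyInputError
    try:
        db = gffutils.create_db(str(path), ":memory:", force=True,
                                merge_strategy="create_unique",
                                keep_order=True)
    except EmptyInputError:
        return []
    genes: List[GeneModel] = []
    for g in db.features_of_type("gene"):
        gid = g.id
        span = (g.start - 1, g.end)
        exon_ivs = set()
        best_cds: List = []
        best_cds_len = -1
        best_mrna = None
        mrnas = list(db.children(g, featuretype="mRNA"))
        parents = mrnas if mrnas else [g]
        for mr in parents:
            for ex in db.children(mr, featuretype="exon"):
                if ex.start - 1 < span[0] or ex.end > span[1]:
                    raise ValidationError(
                        f"exon outside gene span for {gid}")
                exon_ivs.add((ex.start - 1, ex.end))
            cds = sorted((c.start - 1, c.end)
                         for c in db.children(mr, featuretype="CDS"))
            clen = sum(b - a for a, b in cds)
            if clen > best_cds_len:
                best_cds_len, best_cds, best_mrna = clen, cds, mr
        utr5, utr3 = [], []
        if best_mrna is not None:
            for t, dest in (("five_prime_UTR", utr5),
                            ("three_prime_UTR", utr3)):
                for u in db.children(best_mrna, featuretype=t):
                    dest.append((u.start - 1, u.end))
        exons = _merge_intervals(sorted(exon_ivs))
        genes.append(GeneModel(gene_id=gid, scaffold=g.seqid,
                               strand=g.strand, start0=span[0], end0=span[1],
                               exons=exons, cds=best_cds,
                               utr5=sorted(utr5), utr3=sorted(utr3)))
    orphans = [f.id for f in db.features_of_type("exon")
               if not list(db.parents(f))]
    if orphans:
        warnings.warn(f"skipped {len(orphans)} exon(s) without a gene parent")
    genes.sort(key=lambda g: (g.scaffold, g.start0))
    return genes


def _merge_intervals(ivs):
    out = []
    for a, b in ivs:
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def write_gff3(genes: Sequence[GeneModel], path) -> None:
    """Write gene models back to GFF3 (one mRNA per gene)."""
    with _open(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.start0 + 1, g.end0
            base = f"{g.scaffold}\taphimeth\t"
            tail = f"\t.\t{g.strand}\t.\t"
            fh.write(base + f"gene\t{s}\t{e}" + tail + f"ID={g.gene_id}\n")
            mid = g.gene_id + ".t1"
            fh.write(base + f"mRNA\t{s}\t{e}" + tail +
                     f"ID={mid};Parent={g.gene_id}\n")
            for kind, ivs in (("exon", g.exons), ("CDS", g.cds),
                              ("five_prime_UTR", g.utr5),
                              ("three_prime_UTR", g.utr3)):
                for a, b in ivs:
                    fh.write(base + f"{kind}\t{a + 1}\t{b}" + tail +
                             f"Parent={mid}\n")


# ---------------------------------------------------------------------------
# expression counts
# ---------------------------------------------------------------------------

def read_counts_table(path, samples: Optional[Sequence[str]] = None):
    """Read a gene x sample count table.

    First column gene_id, second effective_length (bases), remaining columns
    one per sample.  Returns ``(counts DataFrame indexed by gene, lengths
    Series)``.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise ParseError(f"counts table {path} needs gene_id, "
                         "effective_length and at least one sample column")
    if df.columns[1] != "effective_length":
        raise ParseError("second column must be effective_length")
    df = df.set_index(df.columns[0])
    lengths = pd.to_numeric(df["effective_length"], errors="coerce")
    if lengths.isna().any():
        raise ParseError("missing or non-numeric effective_length")
    counts = df.drop(columns="effective_length")
    mat = counts.apply(pd.to_numeric, errors="coerce")
    if mat.isna().any().any():
        gene = mat.index[mat.isna().any(axis=1)][0]
        raise ParseError(f"non-numeric count for gene {gene}")
    if (mat < 0).any().any():
        raise ValidationError("negative counts in table")
    if samples is not None:
        unknown = set(mat.columns) - set(samples)
        if unknown:
            raise ValidationError(f"unknown sample columns: {sorted(unknown)}")
        mat = mat[[s for s in samples if s in mat.columns]]
    return mat, lengths.astype(float)


def write_counts_table(counts: pd.DataFrame, lengths: pd.Series, path) -> None:
    out = counts.copy()
    out.insert(0, "effective_length", lengths.reindex(out.index))
    out.index.name = "gene_id"
    with _open(path, "wt") as fh:
        out.to_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# sample sheet, depth summaries
# ---------------------------------------------------------------------------

def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t")
    need = {"sample_id", "group", "replicate", "assay"}
    if not need <= set(df.columns):
        raise ParseError(f"sample sheet missing columns {need - set(df.columns)}")
    return SampleSheet.from_frame(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.to_frame().to_csv(path, sep="\t", index=False)


def read_depth_table(path) -> pd.DataFrame:
    """Read a per-position (or binned-position) depth summary TSV:
    columns scaffold, pos, depth."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["scaffold", "pos", "depth"],
                     dtype={"scaffold": str})
    if df.empty:
        raise ParseError(f"empty depth table {path}")
    for col in ("pos", "depth"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            raise ParseError(f"non-numeric {col} in {path}")
        df[col] = vals
    return df


def write_depth_table(df: pd.DataFrame, path) -> None:
    with _open(path, "wt") as fh:
        df[["scaffold", "pos", "depth"]].to_csv(fh, sep="\t", header=False,
                                                index=False)
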