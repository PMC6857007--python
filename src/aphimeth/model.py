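"""Core data model shared by every pipeline stage.

Coordinate convention
---------------------
All external interfaces (cytosine reports, GFF3, BED) use 1-based inclusive
coordinates.  Internally every interval is stored 0-based half-open
(``start0 <= x < end0``) so interval arithmetic needs no off-by-one care;
conversion happens exactly once, at the I/O boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

ASEXUAL_FEMALE = "asexual_female"
MALE = "male"
GROUPS = (ASEXUAL_FEMALE, MALE)

CONTEXTS = ("CpG", "CHG", "CHH")

#: canonical context spellings accepted at I/O
_CONTEXT_ALIASES = {
    "CPG": "CpG", "CG": "CpG", "CPG.": "CpG",
    "CHG": "CHG", "CHH": "CHH",
}


class ValidationError(ValueError):
    """Input violated a model invariant (duplicate site, bad coordinate...)."""


class ParseError(ValueError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        super().__init__(f"{message}" + (f" (line {line})" if line else ""))


def normalize_context(raw: str) -> str:
    ctx = _CONTEXT_ALIASES.get(str(raw).upper())
    if ctx is None:
        raise ValidationError(f"unknown cytosine context {raw!r}")
    return ctx


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleMeta:
    """One sequenced sample: which morph, which replicate, which assay."""

    sample_id: str
    group: str              # asexual_female | male
    replicate: int
    assay: str              # bisulphite | expression

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}")
        if self.assay not in ("bisulphite", "expression"):
            raise ValidationError(f"unknown assay {self.assay!r}")
        if self.replicate < 1:
            raise ValidationError("replicate must be a positive integer")


class SampleSheet:
    """Collection of :class:`SampleMeta` with uniqueness checks per assay."""

    def __init__(self, samples: Sequence[SampleMeta]):
        self.samples = list(samples)
        for assay in ("bisulphite", "expression"):
            ids = [s.sample_id for s in self.samples if s.assay == assay]
            if len(ids) != len(set(ids)):
                raise ValidationError(f"duplicate sample_id within assay {assay}")

    def ids(self, assay: str, group: Optional[str] = None) -> List[str]:
        return [s.sample_id for s in self.samples
                if s.assay == assay and (group is None or s.group == group)]

    def group_of(self, sample_id: str, assay: str) -> str:
        for s in self.samples:
            if s.sample_id == sample_id and s.assay == assay:
                return s.group
        raise KeyError(sample_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(s) for s in self.samples])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SampleSheet":
        return cls([SampleMeta(str(r.sample_id), str(r.group),
                               int(r.replicate), str(r.assay))
                    for r in df.itertuples()])


# ---------------------------------------------------------------------------
# per-site methylation counts
# ---------------------------------------------------------------------------

class SiteCounts:
    """Per-cytosine methylated/unmethylated read counts across samples.

    Wraps a DataFrame with index columns ``scaffold, pos, strand, context``
    (``pos`` 1-based, the position of the cytosine) and, per sample ``s``,
    count columns ``m_<s>`` and ``u_<s>``.  Zero-coverage sites are retained;
    analysis stages apply their own coverage filters.
    """

    KEY = ["scaffold", "pos", "strand", "context"]

    def __init__(self, df: pd.DataFrame, samples: Sequence[str]):
        self.df = df.reset_index(drop=True)
        self.samples = list(samples)
        for s in self.samples:
            for pre in ("m_", "u_"):
                col = pre + s
                if col not in df.columns:
                    raise ValidationError(f"missing count column {col}")
                if (df[col] < 0).any():
                    raise ValidationError(f"negative counts in {col}")
        dup = self.df.duplicated(subset=["scaffold", "pos", "strand"])
        if dup.any():
            i = int(np.flatnonzero(dup.to_numpy())[0])
            row = self.df.iloc[i]
            raise ValidationError(
                f"duplicate site ({row.scaffold},{row.pos},{row.strand})")

    def __len__(self) -> int:
        return len(self.df)

    def m(self, sample: str) -> np.ndarray:
        return self.df["m_" + sample].to_numpy()

    def u(self, sample: str) -> np.ndarray:
        return self.df["u_" + sample].to_numpy()

    def coverage(self, sample: str) -> np.ndarray:
        return self.m(sample) + self.u(sample)

    def subset(self, mask: np.ndarray) -> "SiteCounts":
        return SiteCounts(self.df.loc[np.asarray(mask)], self.samples)

    def in_context(self, context: str) -> "SiteCounts":
        return self.subset((self.df["context"] == context).to_numpy())

    @classmethod
    def merge(cls, per_sample: Dict[str, pd.DataFrame]) -> "SiteCounts":
        """Outer-join single-sample report frames on the site key.

        Sites absent from a sample get m=u=0 (no coverage there).
        """
        merged = None
        for sid, df in per_sample.items():
            d = df.rename(columns={"m": "m_" + sid, "u": "u_" + sid})
            d = d[cls.KEY + ["m_" + sid, "u_" + sid]]
            merged = d if merged is None else merged.merge(
                d, on=cls.KEY, how="outer")
        assert merged is not None, "no samples given"
        cnt = [c for c in merged.columns if c.startswith(("m_", "u_"))]
        merged[cnt] = merged[cnt].fillna(0).astype(np.int64)
        merged = merged.sort_values(["scaffold", "pos", "strand"],
                                    kind="mergesort").reset_index(drop=True)
        return cls(merged, list(per_sample))


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

Interval = Tuple[int, int]   # 0-based half-open


def _check_intervals(ivs: Sequence[Interval], lo: int, hi: int, what: str,
                     gene_id: str) -> List[Interval]:
    out = sorted((int(a), int(b)) for a, b in ivs)
    last = lo
    for a, b in out:
        if a < lo or b > hi:
            raise ValidationError(f"{what} outside gene span in {gene_id}")
        if b <= a:
            raise ValidationError(f"empty {what} interval in {gene_id}")
        if a < last:
            raise ValidationError(f"overlapping {what} intervals in {gene_id}")
        last = b
    return out


@dataclass
class GeneModel:
    """A scaffold-anchored gene with exon/intron/UTR structure.

    Intervals are 0-based half-open on the forward genome strand; the 5'->3'
    orientation of the gene follows ``strand``.
    """

    gene_id: str
    scaffold: str
    strand: str
    start0: int
    end0: int
    exons: List[Interval] = field(default_factory=list)
    cds: List[Interval] = field(default_factory=list)
    utr5: List[Interval] = field(default_factory=list)
    utr3: List[Interval] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValidationError(f"bad strand {self.strand!r} in {self.gene_id}")
        if self.end0 <= self.start0:
            raise ValidationError(f"empty span in {self.gene_id}")
        self.exons = _check_intervals(self.exons, self.start0, self.end0,
                                      "exon", self.gene_id)
        self.cds = _check_intervals(self.cds, self.start0, self.end0,
                                    "CDS", self.gene_id)

    @property
    def length(self) -> int:
        return self.end0 - self.start0

    @property
    def exon_length(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(b - a for a, b in self.cds)

    @property
    def introns(self) -> List[Interval]:
        out = []
        for (a1, b1), (a2, b2) in zip(self.exons, self.exons[1:]):
            if a2 > b1:
                out.append((b1, a2))
        return out

    def exons_5to3(self) -> List[Interval]:
        """Exons in transcription order (reversed for minus-strand genes)."""
        return self.exons if self.strand == "+" else self.exons[::-1]


# ---------------------------------------------------------------------------
# conversion-error estimate
# ---------------------------------------------------------------------------

@dataclass
class ConversionError:
    """Bisulphite false-positive methylation rate from an unmethylated control.

    ``lam`` is the pooled fraction of apparently-methylated reads over the
    control genome, i.e. the probability that an unmethylated C survives
    conversion and reads as methylated.
    """

    lam: float
    n_control_sites: int
    per_sample_lambdas: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.lam <= 1.0):
            raise ValidationError("conversion error rate must be in [0,1]")


# ---------------------------------------------------------------------------
# analysis configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Thresholds for every analysis stage; defaults follow common WGBS practice
    for insect methylomes (5-read site floor, 15/10-point DM thresholds,
    5% FDR, 1.5/10-fold expression-bias classes)."""

    min_site_coverage: int = 5
    site_coverage_top_quantile_drop: float = 0.001
    gene_min_reads: int = 20
    gene_coverage_top_quantile_drop: float = 0.01
    site_dm_min_diff: float = 15.0      # percent points
    gene_dm_min_diff: float = 10.0
    fdr: float = 0.05
    de_fc_threshold: float = 1.5
    de_extreme_fc: float = 10.0
    cpm_threshold: float = 2.0
    cpm_min_samples: int = 3
    min_scaffold_length: int = 20_000
    methylated_gene_floor: float = 1.0  # percent
    expressed_gene_floor: float = 1.0   # FPKM
    fc_offset: float = 0.01             # added before log2 fold changes
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.fdr < 1.0):
            raise ValidationError("fdr must be in (0,1)")
        for name in ("min_site_coverage", "gene_min_reads", "site_dm_min_diff",
                     "gene_dm_min_diff", "de_fc_threshold", "de_extreme_fc",
                     "cpm_threshold", "min_scaffold_length"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        text = open(path).read()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            return cls.from_dict(yaml.safe_load(text) or {})
        return cls.from_dict(json.loads(text))
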