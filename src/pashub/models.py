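"""Shared domain types for the paired-omics hub-gene pipeline.

The pipeline compares placental case (PAS, placenta accreta spectrum) and
control samples across an mRNA count layer and a protein intensity layer.
Everything downstream consumes the containers defined here: a two-group
sample design, genes-by-samples expression matrices, 1-based genomic
intervals, and tidy record tables for variants, splice events and fusions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CASE = "case"
CONTROL = "control"

LAYER_MRNA = "mrna_counts"
LAYER_PROTEIN = "protein_intensity"
VALID_LAYERS = (LAYER_MRNA, LAYER_PROTEIN)

BIOTYPE_MRNA = "mrna"
BIOTYPE_LNCRNA = "lncrna"

#: SNP effect classes modelled by the variant-association stage; annotator
#: categories outside this vocabulary must be mapped to "other" upstream.
EFFECT_CLASSES = ("intron", "intergenic", "synonymous", "missense", "utr", "other")

#: The seven alternative-splicing event types: alternative exon ends,
#: alternative 5' first exon, alternative 3' last exon, intron retention,
#: multi-intron retention, skipped exon, multi-exon skip.
SPLICE_EVENT_TYPES = ("AE", "TSS", "TTS", "IR", "MIR", "SKIP", "MSKIP")

#: Positional lncRNA-target relation vocabulary (plus "trans"/"none").
CIS_RELATIONS = ("cis_up10k", "cis_dw20k", "cis_overlap")


@dataclass(frozen=True)
class SampleDesign:
    """Ordered samples with a case/control label each."""

    sample_ids: tuple[str, ...]
    groups: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.groups):
            raise ValueError("sample_ids and groups must be parallel")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample id in design")
        bad = set(self.groups) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"unknown group label(s): {sorted(bad)}")
        if CASE not in self.groups or CONTROL not in self.groups:
            raise ValueError("both case and control groups must be non-empty")

    @classmethod
    def from_mapping(cls, mapping: dict[str, str]) -> "SampleDesign":
        return cls(tuple(mapping.keys()), tuple(mapping.values()))

    @property
    def case_ids(self) -> tuple[str, ...]:
        return tuple(s for s, g in zip(self.sample_ids, self.groups) if g == CASE)

    @property
    def control_ids(self) -> tuple[str, ...]:
        return tuple(s for s, g in zip(self.sample_ids, self.groups) if g == CONTROL)

    @property
    def n_case(self) -> int:
        return len(self.case_ids)

    @property
    def n_control(self) -> int:
        return len(self.control_ids)

    def case_mask(self) -> np.ndarray:
        return np.array([g == CASE for g in self.groups], dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids, "group": self.groups})


@dataclass
class ExpressionMatrix:
    """Genes-by-samples non-negative expression values for one omics layer.

    ``values`` is indexed by gene id with columns in the design's sample
    order; ``layer`` tags the measurement kind (read counts vs intensities).
    """

    values: pd.DataFrame
    layer: str
    design: SampleDesign

    def __post_init__(self) -> None:
        if self.layer not in VALID_LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {VALID_LAYERS}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene id(s): {dups[:5]}")
        if tuple(self.values.columns) != self.design.sample_ids:
            missing = set(self.design.sample_ids) - set(self.values.columns)
            extra = set(self.values.columns) - set(self.design.sample_ids)
            if missing or extra:
                raise ValueError(
                    f"sample mismatch with design (missing={sorted(missing)}, extra={sorted(extra)})"
                )
            # Same samples, different order: align to the design.
            self.values = self.values.loc[:, list(self.design.sample_ids)]
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite (missing values are rejected)")
        if (arr < 0).any():
            raise ValueError("negative expression value")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def case_values(self) -> np.ndarray:
        return self.values.loc[:, list(self.design.case_ids)].to_numpy()

    def control_values(self) -> np.ndarray:
        return self.values.loc[:, list(self.design.control_ids)].to_numpy()


@dataclass(frozen=True)
class GenomicInterval:
    """Stranded 1-based inclusive genomic interval (GTF convention)."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start <= other.end and other.start <= self.end


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    biotype: str
    locus: GenomicInterval

    def __post_init__(self) -> None:
        if self.biotype not in (BIOTYPE_MRNA, BIOTYPE_LNCRNA):
            raise ValueError(f"unknown biotype {self.biotype!r}")


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} table missing column(s): {missing}")


def validate_variant_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a tidy (gene, effect_class, sample, present) table."""
    _require_columns(df, ["gene_id", "effect_class", "sample_id", "present"], "variant")
    bad = set(df["effect_class"]) - set(EFFECT_CLASSES)
    if bad:
        raise ValueError(
            f"unknown effect class(es) {sorted(bad)}; valid classes are {list(EFFECT_CLASSES)}"
        )
    if df.duplicated(["gene_id", "effect_class", "sample_id"]).any():
        raise ValueError("duplicate (gene, effect_class, sample) record")
    out = df.copy()
    out["present"] = out["present"].astype(bool)
    return out


def validate_splice_table(df: pd.DataFrame, design: SampleDesign | None = None) -> pd.DataFrame:
    """Validate a splice-event table: event type, gene, locus, per-sample expression."""
    _require_columns(df, ["event_type", "gene_id", "chrom", "start", "end"], "splice")
    bad = set(df["event_type"]) - set(SPLICE_EVENT_TYPES)
    if bad:
        raise ValueError(
            f"unknown event type(s) {sorted(bad)}; the 7 valid types are {list(SPLICE_EVENT_TYPES)}"
        )
    sample_cols = [c for c in df.columns if c not in ("event_type", "gene_id", "chrom", "start", "end")]
    if design is not None:
        missing = set(design.sample_ids) - set(sample_cols)
        if missing:
            raise ValueError(f"splice table missing expression column(s) for: {sorted(missing)}")
    expr = df[sample_cols].to_numpy(dtype=float)
    if not np.isfinite(expr).all() or (expr < 0).any():
        raise ValueError("splice-event expression must be finite and non-negative")
    return df


def validate_fusion_table(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, ["gene_a", "gene_b", "chrom", "sample_id", "present"], "fusion")
    if (df["gene_a"] == df["gene_b"]).any():
        raise ValueError("fusion partners must differ (gene_a != gene_b)")
    out = df.copy()
    out["present"] = out["present"].astype(bool)
    return out


def splice_sample_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c not in ("event_type", "gene_id", "chrom", "start", "end")]
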