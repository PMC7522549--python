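"""Readers and writers for every delimited table the pipeline touches.

All external tables are TSV. Annotations may also arrive as BED6 (0-based
half-open) or minimal GTF (1-based inclusive); both are normalised at the
boundary to the internal 1-based inclusive convention, because the study
domain reports coordinates that way (e.g. splice loci quoted as inclusive
site ranges).
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd
import pyranges as pr

from .models import (
    BIOTYPE_LNCRNA,
    BIOTYPE_MRNA,
    ExpressionMatrix,
    GeneAnnotation,
    GenomicInterval,
    SampleDesign,
    validate_fusion_table,
    validate_splice_table,
    validate_variant_table,
)


def read_expression_matrix(path, layer: str, design: SampleDesign) -> ExpressionMatrix:
    """Read a genes-by-samples TSV (first column gene id) into a matrix.

    Columns may appear in any order; they are aligned to the design order.
    Duplicate gene ids, missing values, samples not in the design and
    negative values are all rejected by the ExpressionMatrix invariants.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene id(s) in {path}: {dups[:5]}")
    return ExpressionMatrix(values=df, layer=layer, design=design)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")


def read_annotation(path, dialect: str) -> list[GeneAnnotation]:
    """Read BED6 or minimal GTF gene annotations.

    The gene id comes from the BED name field or the GTF ``gene_id``
    attribute; biotype from the GTF ``gene_biotype`` attribute when present
    (default mrna), or from a ``#biotype=`` suffix ``gene|lncrna`` appended
    to the BED name as ``name|biotype``.
    """
    if dialect == "bed":
        gr = pr.read_bed(str(path))
        df = gr.df
        records = []
        for row in df.itertuples(index=False):
            start = int(row.Start) + 1  # BED 0-based half-open -> 1-based inclusive
            end = int(row.End)
            if end < start:
                raise ValueError(f"zero-length feature after BED normalisation: {row}")
            name = str(getattr(row, "Name", "."))
            if "|" in name:
                gene_id, biotype = name.split("|", 1)
            else:
                gene_id, biotype = name, BIOTYPE_MRNA
            strand = str(getattr(row, "Strand", "."))
            records.append(
                GeneAnnotation(gene_id, biotype, GenomicInterval(str(row.Chromosome), start, end, strand))
            )
        return records
    if dialect == "gtf":
        gr = pr.read_gtf(str(path))
        df = gr.df
        records = []
        for row in df.itertuples(index=False):
            start = int(row.Start) + 1  # pyranges stores GTF internally 0-based
            end = int(row.End)
            if end < start:
                raise ValueError(f"invalid GTF interval: {row}")
            biotype_raw = str(getattr(row, "gene_biotype", BIOTYPE_MRNA)).lower()
            biotype = BIOTYPE_LNCRNA if "lnc" in biotype_raw else BIOTYPE_MRNA
            strand = str(getattr(row, "Strand", "."))
            records.append(
                GeneAnnotation(str(row.gene_id), biotype, GenomicInterval(str(row.Chromosome), start, end, strand))
            )
        return records
    raise ValueError(f"unknown annotation dialect {dialect!r}; expected 'bed' or 'gtf'")


def write_annotation_bed(annotations: Iterable[GeneAnnotation], path) -> None:
    """Write annotations as BED6 (internal 1-based inclusive -> 0-based half-open)."""
    with open(path, "w") as fh:
        for ann in annotations:
            iv = ann.locus
            name = f"{ann.gene_id}|{ann.biotype}"
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_variant_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "effect_class": str, "sample_id": str})
    return validate_variant_table(df)


def write_variant_table(df: pd.DataFrame, path) -> None:
    validate_variant_table(df).to_csv(path, sep="\t", index=False)


def read_splice_table(path, design: SampleDesign | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return validate_splice_table(df, design)


def write_splice_table(df: pd.DataFrame, path) -> None:
    validate_splice_table(df).to_csv(path, sep="\t", index=False)


def read_fusion_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str, "chrom": str, "sample_id": str})
    return validate_fusion_table(df)


def write_fusion_table(df: pd.DataFrame, path) -> None:
    validate_fusion_table(df).to_csv(path, sep="\t", index=False)


def write_design(design: SampleDesign, path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


def read_design(path) -> SampleDesign:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SampleDesign(tuple(df["sample_id"]), tuple(df["group"]))


def write_report(results: dict[str, pd.DataFrame], out_dir, manifest: dict) -> list[Path]:
    """Emit one TSV per analysis stage plus a JSON run manifest.

    ``results`` maps stage name -> tidy DataFrame. The manifest records the
    parameters and seed of the run so any stage can be re-run from disk.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in results.items():
        p = out_dir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        written.append(p)
    manifest = dict(manifest)
    manifest.setdefault("record_counts", {name: int(len(df)) for name, df in results.items()})
    mpath = out_dir / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    written.append(mpath)
    return written


def load_reference_hub_genes() -> pd.DataFrame:
    """Load the packaged reference table of 23 PAS hub genes.

    Published log2 fold changes and BH FDRs of the hub genes in the
    transcriptome and proteome layers of the placenta accreta spectrum
    case-control study this pipeline's design follows. FDRs censored below
    0.001 in the source are stored as 0.001 (an upper bound); only signs and
    the <0.05 comparison are consumed downstream.
    """
    with resources.files("pashub.data").joinpath("pas_hub_genes.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
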