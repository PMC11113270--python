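"""Gene annotations, lesion maps, sample metadata, and their file formats.

All internal coordinates are 0-based, half-open.  GTF (1-based, inclusive) is
converted at the boundary.  Lesion files are BED-like single-nucleotide
records: ``end == start + 1`` with an explicit strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_AGE_LABELS = (3.0, 12.0, 19.0, 22.0, 24.0)
DEFAULT_TISSUES = ("bone_marrow", "brain", "heart", "liver", "pbmc", "sperm")


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation/lesion/metadata input."""


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union-merge half-open intervals; adjacent intervals are fused.

    Returns a sorted, pairwise non-overlapping, non-adjacent list.
    """
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if e <= s:
            raise AnnotationError(f"empty or inverted interval [{s}, {e})")
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass(frozen=True)
class GeneModel:
    """A gene's exon-union territory on one chromosome.

    ``exons`` are 0-based half-open, sorted and union-merged; ``span`` covers
    the first exon start to the last exon end (exons + introns).
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise AnnotationError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        merged = merge_intervals(self.exons)
        if tuple(merged) != tuple(self.exons):
            object.__setattr__(self, "exons", tuple(merged))
        if self.exon_union_length < 1:
            raise AnnotationError(f"{self.gene_id}: zero exon length")

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def exon_union_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span_length(self) -> int:
        s, e = self.span
        return e - s

    def length(self, region_mode: str) -> int:
        """Territory length in bp for a region mode (``exon`` | ``whole_gene``)."""
        if region_mode == "exon":
            return self.exon_union_length
        if region_mode == "whole_gene":
            return self.span_length
        raise ValueError(f"unknown region_mode {region_mode!r}")


@dataclass
class LesionMap:
    """One sample's deduplicated single-nucleotide lesion positions.

    Identity of a record is (chrom, position, strand): the same position hit
    on both strands yields two records, mirroring position-level (not
    read-level) counting.
    """

    sample_id: str
    lesion_type: str
    records: pd.DataFrame  # columns: chrom, position, strand
    n_duplicates: int = 0

    def __post_init__(self) -> None:
        if self.lesion_type not in {"SSB", "AP"}:
            raise AnnotationError(f"lesion_type must be SSB or AP, got {self.lesion_type!r}")
        df = self.records
        if not {"chrom", "position", "strand"}.issubset(df.columns):
            raise AnnotationError("lesion records need chrom, position, strand columns")
        deduped = df.drop_duplicates(["chrom", "position", "strand"])
        dups = len(df) - len(deduped)
        if dups:
            logger.info("%s: dropped %d duplicate lesion records", self.sample_id, dups)
            self.n_duplicates += dups
        self.records = deduped.sort_values(["chrom", "position", "strand"]).reset_index(drop=True)

    @property
    def total_positions(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    age_months: float
    tissue: str


def _parse_gtf_attributes(attr_field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for piece in attr_field.strip().split(";"):
        piece = piece.strip()
        if not piece:
            continue
        key, _, value = piece.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Read exon features from a GTF file into per-gene exon-union models.

    GTF coordinates (1-based, inclusive) are converted to 0-based half-open;
    exons of a gene are union-merged.  Genes whose exons sit on more than one
    chromosome are rejected.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    chroms: dict[str, str] = {}
    strands: dict[str, str] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(f"{path}: line {lineno}: expected 9 tab-separated fields, got {len(fields)}")
            chrom, _source, feature, start, end, _score, strand, _frame, attr = fields
            if feature != "exon":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise AnnotationError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if start_i < 1 or end_i < start_i:
                raise AnnotationError(f"{path}: line {lineno}: bad coordinates {start}-{end}")
            attrs = _parse_gtf_attributes(attr)
            gene_id = attrs.get("gene_id")
            if not gene_id:
                raise AnnotationError(f"{path}: line {lineno}: exon without gene_id attribute")
            if gene_id not in exons:
                exons[gene_id] = []
                chroms[gene_id] = chrom
                strands[gene_id] = strand
                order.append(gene_id)
            elif chroms[gene_id] != chrom:
                raise AnnotationError(
                    f"{path}: gene {gene_id} has exons on multiple chromosomes "
                    f"({chroms[gene_id]} and {chrom})"
                )
            # 1-based inclusive -> 0-based half-open
            exons[gene_id].append((start_i - 1, end_i))
    if not exons:
        logger.warning("%s: no exon features found", path)
        return []
    return [GeneModel(gid, chroms[gid], strands[gid], tuple(exons[gid])) for gid in order]


def write_gtf(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as minimal GTF exon rows (inverse of :func:`read_gtf`)."""
    with open(path, "w") as fh:
        for gene in genes:
            for s, e in gene.exons:
                fh.write(
                    f"{gene.chrom}\tbreakclock\texon\t{s + 1}\t{e}\t.\t{gene.strand}\t.\t"
                    f'gene_id "{gene.gene_id}";\n'
                )


def read_lesion_bed(path: str | Path, sample_id: str, lesion_type: str) -> LesionMap:
    """Read single-nucleotide lesion positions from a BED6-like file.

    Each row must satisfy end == start + 1 and carry a strand; name and score
    columns are ignored.  Records are deduplicated on (chrom, position,
    strand) and the duplicate count is logged.
    """
    chroms: list[str] = []
    positions: list[int] = []
    strands: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise AnnotationError(f"{path}: line {lineno}: need 6 BED columns (strand required)")
            chrom, start, end, _name, _score, strand = fields[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise AnnotationError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if end_i != start_i + 1:
                raise AnnotationError(
                    f"{path}: line {lineno}: lesions are single-nucleotide (end must equal start+1)"
                )
            if strand not in {"+", "-"}:
                raise AnnotationError(f"{path}: line {lineno}: missing or invalid strand {strand!r}")
            chroms.append(chrom)
            positions.append(start_i)
            strands.append(strand)
    records = pd.DataFrame({"chrom": chroms, "position": positions, "strand": strands})
    return LesionMap(sample_id=sample_id, lesion_type=lesion_type, records=records)


def write_lesion_bed(lesion_map: LesionMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in lesion_map.records.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.position}\t{row.position + 1}\t.\t0\t{row.strand}\n")


def read_metadata(
    path: str | Path,
    age_labels: Sequence[float] = DEFAULT_AGE_LABELS,
    tissues: Sequence[str] | None = None,
) -> list[SampleMetadata]:
    """Read sample metadata (TSV: sample_id, age_months, tissue).

    ``age_labels`` is the allowed age-group set; pass ``tissues`` to also
    enforce a tissue vocabulary.  Duplicate sample ids are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "tissue": str})
    required = {"sample_id", "age_months", "tissue"}
    if not required.issubset(df.columns):
        raise AnnotationError(f"{path}: metadata needs columns {sorted(required)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise AnnotationError(f"{path}: duplicate sample_id {dup!r}")
    if df[["age_months", "tissue"]].isna().any().any():
        raise AnnotationError(f"{path}: missing age_months or tissue")
    allowed_ages = set(float(a) for a in age_labels)
    bad_age = set(df["age_months"].astype(float)) - allowed_ages
    if bad_age:
        raise AnnotationError(
            f"{path}: unknown age labels {sorted(bad_age)}; allowed: {sorted(allowed_ages)}"
        )
    if tissues is not None:
        bad_tissue = set(df["tissue"]) - set(tissues)
        if bad_tissue:
            raise AnnotationError(
                f"{path}: unknown tissues {sorted(bad_tissue)}; allowed: {sorted(tissues)}"
            )
    samples = [
        SampleMetadata(row.sample_id, float(row.age_months), row.tissue)
        for row in df.itertuples(index=False)
    ]
    n_strata = df.groupby(["age_months", "tissue"], observed=True).ngroups
    logger.info("%s: %d samples in %d (age, tissue) strata", path, len(samples), n_strata)
    return samples


def metadata_frame(samples: Sequence[SampleMetadata]) -> pd.DataFrame:
    """Sample metadata as a DataFrame indexed by sample_id."""
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "age_months": [s.age_months for s in samples],
            "tissue": [s.tissue for s in samples],
        }
    ).set_index("sample_id")


def write_metadata(samples: Sequence[SampleMetadata], path: str | Path) -> None:
    metadata_frame(samples).reset_index().to_csv(path, sep="\t", index=False)
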