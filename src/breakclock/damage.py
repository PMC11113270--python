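"""Per-gene DNA damage and expression metrics.

Turns lesion maps into LPKM (lesions per kb per million) matrices and read
counts into naive gene-level TPM, and applies the nonzero-fraction gene
filters applied before feature selection.

LPKM for gene *i* in sample *j* is

    LPKM_ij = R_ij * scale / (L_i * N_j)

where R_ij is the number of deduplicated lesion positions (either strand)
inside the gene's territory, L_i the territory length in bp (exon union or
whole-gene span), N_j the sample's total lesion positions, and ``scale``
defaults to 1e9 — exactly "per kb per million" (1e3 * 1e6).  Any fixed
positive scale is rank-preserving, so the choice does not affect downstream
gene ranking or model evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, LesionMap

logger = logging.getLogger(__name__)

METRICS = ("LPKM_SSB", "LPKM_AP", "TPM")
REGION_MODES = ("exon", "whole_gene")

DEFAULT_LPKM_SCALE = 1e9
DEFAULT_MIN_NONZERO = {"TPM": 0.40, "LPKM_SSB": 0.20, "LPKM_AP": 0.20}


@dataclass
class FeatureMatrix:
    """A genes × samples matrix for one metric and one region mode."""

    metric: str
    region_mode: str
    values: pd.DataFrame  # index: gene_ids, columns: sample_ids

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}, got {self.metric!r}")
        if self.region_mode not in REGION_MODES:
            raise ValueError(f"region_mode must be one of {REGION_MODES}, got {self.region_mode!r}")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("feature matrix contains non-finite values")
        if (arr < 0).any():
            raise ValueError("feature matrix contains negative values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def _strand_mask(records: pd.DataFrame, strand: str) -> pd.DataFrame:
    if strand == "both":
        return records
    if strand in {"+", "-"}:
        return records[records["strand"] == strand]
    raise ValueError(f"strand must be 'both', '+' or '-', got {strand!r}")


def count_lesions_in_gene(
    lesion_map: LesionMap, gene: GeneModel, region_mode: str = "exon", strand: str = "both"
) -> int:
    """Number of deduplicated lesion positions inside one gene's territory.

    Both strands are pooled by default; a position hit on both strands
    contributes two.
    """
    records = _strand_mask(lesion_map.records, strand)
    on_chrom = records[records["chrom"] == gene.chrom]
    if on_chrom.empty:
        return 0
    pos = np.sort(on_chrom["position"].to_numpy())
    intervals = gene.exons if region_mode == "exon" else (gene.span,)
    if region_mode not in REGION_MODES:
        raise ValueError(f"unknown region_mode {region_mode!r}")
    total = 0
    for s, e in intervals:
        total += int(np.searchsorted(pos, e, "left") - np.searchsorted(pos, s, "left"))
    return total


def count_lesions(
    lesion_maps: Mapping[str, LesionMap],
    genes: Sequence[GeneModel],
    region_mode: str = "exon",
    strand: str = "both",
) -> pd.DataFrame:
    """Genes × samples matrix of raw lesion-position counts R_ij.

    Vectorized over genes per chromosome; a lesion inside the territory of
    several overlapping genes is counted for each of them.
    """
    gene_ids = [g.gene_id for g in genes]
    # flatten interval bounds grouped by chromosome
    bounds_by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for gi, gene in enumerate(genes):
        intervals = gene.exons if region_mode == "exon" else (gene.span,)
        bounds_by_chrom.setdefault(gene.chrom, []).extend((s, e, gi) for s, e in intervals)
    out = np.zeros((len(genes), len(lesion_maps)), dtype=np.int64)
    for sj, (sample_id, lmap) in enumerate(lesion_maps.items()):
        records = _strand_mask(lmap.records, strand)
        for chrom, bounds in bounds_by_chrom.items():
            pos = records.loc[records["chrom"] == chrom, "position"].to_numpy()
            if pos.size == 0:
                continue
            pos = np.sort(pos)
            starts = np.array([b[0] for b in bounds])
            ends = np.array([b[1] for b in bounds])
            gidx = np.array([b[2] for b in bounds])
            per_interval = np.searchsorted(pos, ends, "left") - np.searchsorted(pos, starts, "left")
            np.add.at(out[:, sj], gidx, per_interval)
    return pd.DataFrame(out, index=gene_ids, columns=list(lesion_maps.keys()))


def compute_lpkm(
    counts: pd.DataFrame,
    genes: Sequence[GeneModel],
    totals: Mapping[str, int] | pd.Series,
    lesion_type: str = "SSB",
    region_mode: str = "exon",
    scale: float = DEFAULT_LPKM_SCALE,
) -> FeatureMatrix:
    """LPKM matrix from raw counts, gene lengths, and per-sample totals.

    ``totals`` are each sample's total lesion positions (genome-wide, not just
    gene-mapped).  A sample with zero total positions cannot be normalized and
    is an error.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    by_id = {g.gene_id: g for g in genes}
    missing = [gid for gid in counts.index if gid not in by_id]
    if missing:
        raise ValueError(f"counts contain unknown genes: {missing[:5]}")
    lengths = np.array([by_id[gid].length(region_mode) for gid in counts.index], dtype=float)
    totals = pd.Series(totals).reindex(counts.columns)
    if totals.isna().any():
        raise ValueError(f"missing totals for samples: {list(totals.index[totals.isna()])[:5]}")
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise ValueError(f"sample {bad!r} has zero total lesion positions; cannot normalize")
    values = counts.to_numpy(dtype=float) * scale / (lengths[:, None] * totals.to_numpy()[None, :])
    metric = f"LPKM_{lesion_type}"
    return FeatureMatrix(metric=metric, region_mode=region_mode,
                         values=pd.DataFrame(values, index=counts.index, columns=counts.columns))


def lpkm_from_maps(
    lesion_maps: Mapping[str, LesionMap],
    genes: Sequence[GeneModel],
    lesion_type: str = "SSB",
    region_mode: str = "exon",
    scale: float = DEFAULT_LPKM_SCALE,
    strand: str = "both",
) -> FeatureMatrix:
    """Count lesions per gene and normalize to LPKM in one step."""
    counts = count_lesions(lesion_maps, genes, region_mode=region_mode, strand=strand)
    totals = {sid: m.total_positions for sid, m in lesion_maps.items()}
    return compute_lpkm(counts, genes, totals, lesion_type=lesion_type,
                        region_mode=region_mode, scale=scale)


def compute_tpm(read_counts: pd.DataFrame, genes: Sequence[GeneModel]) -> FeatureMatrix:
    """Naive gene-level TPM with exon-union effective length.

    rate_ij = count_ij / L_i; TPM_ij = 1e6 * rate_ij / sum_g rate_gj.  No
    isoform-level expectation-maximization and no fragment-length correction.
    """
    by_id = {g.gene_id: g for g in genes}
    missing = [gid for gid in read_counts.index if gid not in by_id]
    if missing:
        raise ValueError(f"read counts contain unknown genes: {missing[:5]}")
    arr = read_counts.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("read counts must be non-negative")
    lengths = np.array([by_id[gid].exon_union_length for gid in read_counts.index], dtype=float)
    rates = arr / lengths[:, None]
    col_sums = rates.sum(axis=0)
    if (col_sums == 0).any():
        bad = read_counts.columns[np.flatnonzero(col_sums == 0)[0]]
        raise ValueError(f"sample {bad!r} has all-zero counts; TPM undefined")
    tpm = 1e6 * rates / col_sums[None, :]
    return FeatureMatrix(metric="TPM", region_mode="exon",
                         values=pd.DataFrame(tpm, index=read_counts.index, columns=read_counts.columns))


def filter_genes(matrix: FeatureMatrix, min_nonzero_fraction: float | None = None) -> FeatureMatrix:
    """Keep genes nonzero in at least ``min_nonzero_fraction`` of samples.

    Defaults mirror the pipeline's pre-selection filters: 0.40 for TPM, 0.20
    for the LPKM metrics.  Row order is preserved.
    """
    if min_nonzero_fraction is None:
        min_nonzero_fraction = DEFAULT_MIN_NONZERO[matrix.metric]
    if not 0 < min_nonzero_fraction <= 1:
        raise ValueError("min_nonzero_fraction must be in (0, 1]")
    frac = (matrix.values.to_numpy() > 0).mean(axis=1)
    keep = frac >= min_nonzero_fraction
    if not keep.any():
        raise ValueError(
            f"no genes pass the {min_nonzero_fraction:.0%} nonzero filter; lower the threshold"
        )
    return FeatureMatrix(metric=matrix.metric, region_mode=matrix.region_mode,
                         values=matrix.values.loc[keep])


def write_feature_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    """Write a feature matrix as TSV with a one-line provenance header."""
    with open(path, "w") as fh:
        fh.write(f"# metric={matrix.metric}\tregion_mode={matrix.region_mode}\n")
        matrix.values.to_csv(fh, sep="\t", index_label="gene_id", float_format="%.17g")


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# metric="):
            raise ValueError(f"{path}: missing feature-matrix provenance header")
        fields = dict(p.split("=", 1) for p in header[2:].strip().split("\t"))
        # round_trip parsing keeps read(write(x)) bit-exact with %.17g output
        values = pd.read_csv(fh, sep="\t", index_col="gene_id", float_precision="round_trip")
    if values.isna().any().any():
        raise ValueError(f"{path}: NA values are not allowed in feature matrices")
    return FeatureMatrix(metric=fields["metric"], region_mode=fields["region_mode"], values=values)
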