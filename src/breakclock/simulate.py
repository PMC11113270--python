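"""Synthetic breakome and transcriptome generator with a ground-truth manifest.

Emulates the statistical structure of a multi-tissue mouse aging study: 5 age
groups (3, 12, 19, 22, 24 months) × 6 tissues, 3 replicates per cell except
the oldest group (2), with one brain sample dropped to mirror a QC exclusion
— 83 samples.  Per gene g and sample j with min-max-scaled age a ∈ [0, 1]
and tissue t:

    lesion count  R_gj ~ Poisson( depth_j * share_gj ),
    share_gj ∝ w_g * exp( s_g * beta * a_j + gamma * [t_j = marker tissue of g] )

with s_g ∈ {+1, -1, 0} (positively / negatively age-correlated / null) and
shares normalized per sample, so each sample's raw lesion total is exactly
Poisson(lesion_depth).  Lesion positions are placed uniformly in the gene's
exon union with a random strand, sampled with replacement and then
deduplicated (position semantics); the duplication count is retained on each
map.  Expression counts follow a negative binomial (gamma-Poisson) with the
same planted effect structure and their own baseline weights.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import (
    DEFAULT_TISSUES,
    GeneModel,
    LesionMap,
    SampleMetadata,
    write_gtf,
    write_lesion_bed,
    write_metadata,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    ages: tuple[float, ...] = (3.0, 12.0, 19.0, 22.0, 24.0)
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    replicates_per_cell: int = 3
    oldest_age_replicates: int = 2
    drop_one_sample: bool = True  # drop one brain sample (QC-exclusion analogue)
    n_genes: int = 2000
    exon_length_range: tuple[int, int] = (2000, 8000)  # total exonic bp per gene
    max_exons: int = 5
    intron_length_range: tuple[int, int] = (200, 2000)
    intergenic_gap_range: tuple[int, int] = (500, 2000)
    genes_per_chromosome: int = 200
    n_age_pos: int = 65
    n_age_neg: int = 35
    n_tissue_markers: int = 60
    age_effect: float = 1.0  # beta: log-rate slope per unit scaled age
    tissue_effect: float = 2.0  # gamma: log-rate bump in the marker tissue (~7.4-fold)
    lesion_depth: float = 2e5  # expected total lesion positions per sample
    expression_depth: float = 2e6  # expected total reads per sample
    nb_dispersion: float = 0.1
    baseline_sigma: float = 0.5  # lognormal spread of per-gene baseline rates
    lesion_types: tuple[str, ...] = ("SSB", "AP")

    def __post_init__(self) -> None:
        if self.n_age_pos + self.n_age_neg + self.n_tissue_markers > self.n_genes:
            raise ValueError("planted gene sets exceed n_genes")
        if self.lesion_depth <= 0 or self.expression_depth <= 0:
            raise ValueError("depths must be positive")
        if self.age_effect < 0:
            raise ValueError("age_effect must be >= 0 (sign is applied per gene)")


@dataclass
class TruthManifest:
    """Ground truth of the planted signal: per-gene role and effect parameters."""

    table: pd.DataFrame  # index gene_id; columns role, s, marker_tissue, beta, gamma

    def genes_with_role(self, role: str) -> list[str]:
        return list(self.table.index[self.table["role"] == role])

    @property
    def age_genes(self) -> list[str]:
        return list(self.table.index[self.table["role"].isin(["age_pos", "age_neg"])])

    @property
    def tissue_marker_genes(self) -> list[str]:
        return self.genes_with_role("tissue_marker")


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genes: list[GeneModel]
    lesion_maps: dict[str, dict[str, LesionMap]]  # lesion_type -> sample_id -> map
    read_counts: pd.DataFrame  # genes × samples
    metadata: pd.DataFrame  # index sample_id; columns age_months, tissue
    manifest: TruthManifest


def generate_annotation(config: SyntheticConfig, rng: np.random.Generator | None = None) -> list[GeneModel]:
    """Tile non-overlapping multi-exon genes on synthetic chromosomes."""
    if config.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    genes: list[GeneModel] = []
    pos = 0
    chrom_i = 1
    width = len(str(config.n_genes))
    for gi in range(config.n_genes):
        if gi % config.genes_per_chromosome == 0:
            chrom_i = gi // config.genes_per_chromosome + 1
            pos = 1000
        n_exons = int(rng.integers(1, config.max_exons + 1))
        exonic = int(rng.integers(*config.exon_length_range))
        # split exonic length into n_exons parts of >= 50 bp each
        spare = exonic - 50 * n_exons
        cuts = np.sort(rng.integers(0, spare + 1, size=n_exons - 1))
        exon_lengths = 50 + np.diff(np.concatenate([[0], cuts, [spare]]))
        exons = []
        cursor = pos + int(rng.integers(*config.intergenic_gap_range))
        for ei, elen in enumerate(exon_lengths):
            exons.append((cursor, cursor + int(elen)))
            cursor += int(elen)
            if ei < n_exons - 1:
                cursor += int(rng.integers(*config.intron_length_range))
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        genes.append(GeneModel(f"gene{gi + 1:0{width}d}", f"chrS{chrom_i}", strand, tuple(exons)))
        pos = exons[-1][1]
    return genes


def _build_metadata(config: SyntheticConfig) -> pd.DataFrame:
    rows = []
    oldest = max(config.ages)
    for age in config.ages:
        reps = config.oldest_age_replicates if age == oldest else config.replicates_per_cell
        for tissue in config.tissues:
            for r in range(1, reps + 1):
                rows.append((f"{tissue}_a{age:g}_r{r}", float(age), tissue))
    df = pd.DataFrame(rows, columns=["sample_id", "age_months", "tissue"]).set_index("sample_id")
    if config.drop_one_sample:
        brainlike = [t for t in config.tissues if "brain" in t] or [config.tissues[0]]
        drop_age = sorted(config.ages)[len(config.ages) // 2]
        drop_id = f"{brainlike[0]}_a{drop_age:g}_r{config.replicates_per_cell}"
        if drop_id in df.index:
            df = df.drop(index=drop_id)
    return df


def _assign_roles(config: SyntheticConfig, gene_ids: list[str], rng: np.random.Generator) -> TruthManifest:
    n = len(gene_ids)
    roles = np.array(["null"] * n, dtype=object)
    s = np.zeros(n)
    marker = np.array([""] * n, dtype=object)
    perm = rng.permutation(n)
    k = 0
    roles[perm[k:k + config.n_age_pos]] = "age_pos"
    s[perm[k:k + config.n_age_pos]] = 1.0
    k += config.n_age_pos
    roles[perm[k:k + config.n_age_neg]] = "age_neg"
    s[perm[k:k + config.n_age_neg]] = -1.0
    k += config.n_age_neg
    marker_idx = perm[k:k + config.n_tissue_markers]
    roles[marker_idx] = "tissue_marker"
    for j, gi in enumerate(marker_idx):
        marker[gi] = config.tissues[j % len(config.tissues)]
    table = pd.DataFrame(
        {
            "role": roles,
            "s": s,
            "marker_tissue": marker,
            "beta": np.where(s != 0, config.age_effect, 0.0),
            "gamma": np.where(roles == "tissue_marker", config.tissue_effect, 0.0),
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return TruthManifest(table=table)


def _effect_matrix(config: SyntheticConfig, manifest: TruthManifest, metadata: pd.DataFrame) -> np.ndarray:
    """exp(effect) per gene × sample from the planted roles."""
    ages = metadata["age_months"].to_numpy(dtype=float)
    a = (ages - ages.min()) / (ages.max() - ages.min())  # scaled age in [0, 1]
    s = manifest.table["s"].to_numpy()
    beta = manifest.table["beta"].to_numpy()
    eta = (s * beta)[:, None] * a[None, :]
    marker = manifest.table["marker_tissue"].to_numpy()
    gamma = manifest.table["gamma"].to_numpy()
    tissue = metadata["tissue"].to_numpy()
    eta += gamma[:, None] * (marker[:, None] == tissue[None, :])
    return np.exp(eta)


def _positions_from_offsets(
    genes: Sequence[GeneModel], gene_idx: np.ndarray, offsets: np.ndarray
) -> np.ndarray:
    """Map (gene, exonic offset) pairs to genomic positions via the exon unions."""
    # global flattened exon table in gene order
    exon_starts, exon_cumlens, gene_base = [], [], []
    cum = 0
    for g in genes:
        gene_base.append(cum)
        for s, e in g.exons:
            exon_starts.append(s)
            cum += e - s
            exon_cumlens.append(cum)
    exon_starts = np.asarray(exon_starts)
    exon_cumlens = np.asarray(exon_cumlens)
    gene_base = np.asarray(gene_base)
    global_offset = gene_base[gene_idx] + offsets
    exon_i = np.searchsorted(exon_cumlens, global_offset, side="right")
    prev_cum = np.concatenate([[0], exon_cumlens[:-1]])
    return exon_starts[exon_i] + (global_offset - prev_cum[exon_i])


def generate_dataset(
    config: SyntheticConfig, annotation: Sequence[GeneModel] | None = None
) -> SyntheticDataset:
    """Generate lesion maps, expression counts, metadata, and the truth manifest.

    Deterministic given the config seed.  Lesion positions are drawn with
    replacement and deduplicated; each map retains its duplicate count.
    """
    root = np.random.SeedSequence(config.seed)
    ss_ann, ss_roles, ss_lesion, ss_expr = root.spawn(4)
    genes = list(annotation) if annotation is not None else generate_annotation(
        config, np.random.default_rng(ss_ann)
    )
    gene_ids = [g.gene_id for g in genes]
    metadata = _build_metadata(config)
    manifest = _assign_roles(config, gene_ids, np.random.default_rng(ss_roles))
    effects = _effect_matrix(config, manifest, metadata)

    lengths = np.array([g.exon_union_length for g in genes], dtype=float)
    chroms = np.array([g.chrom for g in genes], dtype=object)
    sample_ids = list(metadata.index)

    lesion_maps: dict[str, dict[str, LesionMap]] = {}
    for lt_i, lesion_type in enumerate(config.lesion_types):
        rng = np.random.default_rng(ss_lesion.spawn(lt_i + 1)[-1])
        w = lengths * rng.lognormal(0.0, config.baseline_sigma, size=len(genes))
        rates = w[:, None] * effects
        rates = config.lesion_depth * rates / rates.sum(axis=0, keepdims=True)
        maps: dict[str, LesionMap] = {}
        for sj, sample_id in enumerate(sample_ids):
            R = rng.poisson(rates[:, sj])
            gene_idx = np.repeat(np.arange(len(genes)), R)
            offsets = rng.integers(0, lengths.astype(np.int64)[gene_idx])
            positions = _positions_from_offsets(genes, gene_idx, offsets)
            strands = np.where(rng.integers(0, 2, size=len(positions)) == 0, "+", "-")
            records = pd.DataFrame(
                {
                    "chrom": pd.Categorical(chroms[gene_idx]),
                    "position": positions.astype(np.int64),
                    "strand": pd.Categorical(strands, categories=["+", "-"]),
                }
            )
            maps[sample_id] = LesionMap(sample_id=sample_id, lesion_type=lesion_type, records=records)
        dup_rate = np.mean([m.n_duplicates / max(m.total_positions + m.n_duplicates, 1)
                            for m in maps.values()])
        logger.info("%s maps: mean duplicate rate %.3f%%", lesion_type, 100 * dup_rate)
        lesion_maps[lesion_type] = maps

    rng_e = np.random.default_rng(ss_expr)
    w_expr = lengths * rng_e.lognormal(0.0, config.baseline_sigma, size=len(genes))
    mu = w_expr[:, None] * effects
    mu = config.expression_depth * mu / mu.sum(axis=0, keepdims=True)
    phi = config.nb_dispersion
    if phi > 0:
        lam = rng_e.gamma(shape=1.0 / phi, scale=mu * phi)
    else:
        lam = mu
    counts = rng_e.poisson(lam)
    read_counts = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                               columns=sample_ids)
    zero_frac = (read_counts.sum(axis=1) == 0).mean()
    if zero_frac > 0.5:
        logger.warning("expression depth leaves %.0f%% of genes with all-zero counts", 100 * zero_frac)

    return SyntheticDataset(
        config=config,
        genes=genes,
        lesion_maps=lesion_maps,
        read_counts=read_counts,
        metadata=metadata,
        manifest=manifest,
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> None:
    """Write GTF, per-sample BED lesion files, counts, metadata, and truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_gtf(dataset.genes, outdir / "annotation.gtf")
    for lesion_type, maps in dataset.lesion_maps.items():
        sub = outdir / lesion_type.lower()
        sub.mkdir(exist_ok=True)
        for sample_id, lmap in maps.items():
            write_lesion_bed(lmap, sub / f"{sample_id}.bed")
    dataset.read_counts.to_csv(outdir / "counts.tsv", sep="\t", index_label="gene_id")
    dataset.metadata.reset_index().to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    dataset.manifest.table.to_csv(outdir / "truth.tsv", sep="\t")
    with open(outdir / "config.json", "w") as fh:
        json.dump(dataclasses.asdict(dataset.config), fh, indent=2, sort_keys=True)
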