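"""Shared fixtures: tiny hand-built gene models and session-scoped synthetic datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import breakclock as bc


@pytest.fixture
def two_exon_gene() -> bc.GeneModel:
    return bc.GeneModel("g1", "chr1", "+", ((100, 200), (300, 400)))


@pytest.fixture
def four_lesion_map() -> bc.LesionMap:
    records = pd.DataFrame(
        {
            "chrom": ["chr1"] * 4,
            "position": [150, 150, 250, 399],
            "strand": ["+", "-", "+", "+"],
        }
    )
    return bc.LesionMap("s1", "SSB", records)


@pytest.fixture(scope="session")
def small_config() -> bc.SyntheticConfig:
    """A fast, small synthetic design for unit tests (not the study-scale defaults)."""
    return bc.SyntheticConfig(
        seed=42,
        n_genes=80,
        n_age_pos=8,
        n_age_neg=4,
        n_tissue_markers=12,
        lesion_depth=2e4,
        expression_depth=2e5,
        genes_per_chromosome=25,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config) -> bc.SyntheticDataset:
    return bc.generate_dataset(small_config)


@pytest.fixture(scope="session")
def planted_dataset() -> bc.SyntheticDataset:
    """Study-scale dataset at generator defaults (SSB maps only, for speed)."""
    return bc.generate_dataset(bc.SyntheticConfig(seed=1, lesion_types=("SSB",)))


@pytest.fixture(scope="session")
def planted_lpkm(planted_dataset) -> bc.FeatureMatrix:
    return bc.lpkm_from_maps(
        planted_dataset.lesion_maps["SSB"], planted_dataset.genes, "SSB", "exon"
    )


@pytest.fixture(scope="session")
def null_dataset() -> bc.SyntheticDataset:
    """Zero planted effect at the study-scale design (2000 genes, 83 samples)."""
    cfg = bc.SyntheticConfig(
        seed=5, lesion_types=("SSB",), age_effect=0.0, tissue_effect=0.0,
        n_age_pos=0, n_age_neg=0, n_tissue_markers=0,
    )
    return bc.generate_dataset(cfg)


@pytest.fixture(scope="session")
def null_lpkm(null_dataset) -> bc.FeatureMatrix:
    return bc.lpkm_from_maps(null_dataset.lesion_maps["SSB"], null_dataset.genes, "SSB", "exon")
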