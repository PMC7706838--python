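"""Shared fixtures: one mid-sized synthetic dataset, processed once."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import erymix as em
from erymix.matrix import ProteomeMatrix


@pytest.fixture(scope="session")
def default_dataset():
    """Default-condition synthetic proteome plus ground truth (seed 0)."""
    cfg = em.SynthConfig(n_proteins=2000, seed=0)
    matrix, truth = em.generate_proteome(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def processed(default_dataset):
    """Filtered, imputed, ANOVA-tested and clustered default dataset."""
    _, matrix, truth = default_dataset
    filtered = em.filter_completeness(matrix)
    imputed = em.impute_missing(filtered.log2(), seed=1)
    stats = em.anova_stage_test(imputed, filtered.design(), n_permutations=100, seed=2)
    stats = em.cluster_profiles(stats)
    return matrix, truth, filtered, stats


@pytest.fixture(scope="session")
def default_panels(processed):
    matrix, truth, filtered, stats = processed
    return em.assemble_panels(
        stats, truth.marker_panels, filtered.protein_ids, seed=3
    )


def toy_matrix(values: dict, stages, mol_mass=None) -> ProteomeMatrix:
    """Build a small ProteomeMatrix from a {column: row-values} dict."""
    df = pd.DataFrame(values, dtype=float)
    df.index = [f"P{i}" for i in range(len(df))]
    if mol_mass is None:
        mass = pd.Series(4.0e4, index=df.index)
    else:
        mass = pd.Series(np.asarray(mol_mass, dtype=float), index=df.index)
    return ProteomeMatrix(intensities=df, mol_mass=mass, stages=tuple(stages))
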