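"""Histone proteomic-ruler copy-number estimation.

The ruler's premise: the summed mass of histones per cell equals the mass
of genomic DNA (ploidy x haploid genome mass), and MS intensity is
proportional to protein mass within a sample.  Per sample, the copy
number of protein p is therefore

    copies_p = I_p * m_DNA * N_A / (sum_h I_h * MW_p),

with the sum over the histone set.  Total protein mass per cell and cell
volume (at an assumed total protein concentration) follow by summation.
Because the scaling is a within-sample ratio, copy numbers are invariant
under any global per-sample intensity rescaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import ProteomeMatrix, parse_sample_name
from .simulate import AVOGADRO, HAPLOID_DNA_PG

__all__ = ["RulerSettings", "RulerResult", "estimate_copy_numbers", "summarize_copies"]

log = logging.getLogger(__name__)


@dataclass
class RulerSettings:
    """Ruler parameters.

    ploidy: genome copies per cell (2 for diploid precursors);
    total_protein_concentration: cytosolic total protein concentration in
    g/L used to convert protein mass to cell volume (200 g/L is the
    literature consensus for mammalian cells);
    dna_mass_per_haploid_genome_pg: haploid genome mass in picograms;
    averaging_mode: 'per-column' scales each sample by its own histone sum,
    'pooled' averages samples into one column first.
    """

    ploidy: int = 2
    total_protein_concentration: float = 200.0
    dna_mass_per_haploid_genome_pg: float = HAPLOID_DNA_PG
    averaging_mode: str = "per-column"

    def __post_init__(self) -> None:
        if self.ploidy < 1:
            raise ValueError("ploidy must be >= 1")
        if self.total_protein_concentration <= 0:
            raise ValueError("total protein concentration must be positive")
        if self.averaging_mode not in ("per-column", "pooled"):
            raise ValueError("averaging_mode must be 'per-column' or 'pooled'")

    @property
    def dna_mass_g(self) -> float:
        return self.ploidy * self.dna_mass_per_haploid_genome_pg * 1e-12


@dataclass
class RulerResult:
    """Per-protein, per-sample copies plus derived per-sample totals."""

    copies: pd.DataFrame  # proteins x samples (NaN where unobserved)
    total_protein_mass_pg: pd.Series  # per sample
    cell_volume_fl: pd.Series  # per sample
    histone_ids: tuple[str, ...]
    settings: RulerSettings


def estimate_copy_numbers(
    matrix: ProteomeMatrix,
    histone_ids: Sequence[str],
    settings: RulerSettings | None = None,
) -> RulerResult:
    """Convert intensities to per-cell copy numbers via the histone ruler."""
    settings = settings or RulerSettings()
    histone_ids = list(histone_ids)
    if not histone_ids:
        raise ValueError("histone id set is empty")
    absent = [h for h in histone_ids if h not in matrix.protein_ids]
    if absent:
        raise KeyError(f"histone ids absent from matrix: {absent[:5]}")

    intens = matrix.intensities
    if settings.averaging_mode == "pooled":
        intens = intens.mean(axis=1).to_frame("pooled")

    mw = matrix.mol_mass
    no_mass = mw.isna() | (mw <= 0)
    if no_mass.any():
        log.warning("skipping %d proteins without molecular mass", int(no_mass.sum()))
        intens = intens.loc[~no_mass]
        mw = mw.loc[~no_mass]

    hist_sum = intens.loc[[h for h in histone_ids if h in intens.index]].sum(axis=0)
    bad = hist_sum <= 0
    if bad.any():
        raise ValueError(
            f"histone intensity sum is zero in samples: {list(hist_sum.index[bad])}"
        )

    scale = settings.dna_mass_g * AVOGADRO  # copies x Da per unit intensity share
    copies = intens.div(hist_sum, axis=1).div(mw, axis=0) * scale

    mass_pg = copies.mul(mw, axis=0).sum(axis=0) / AVOGADRO * 1e12
    volume_fl = mass_pg * 1e-12 / settings.total_protein_concentration * 1e15
    return RulerResult(
        copies=copies,
        total_protein_mass_pg=mass_pg,
        cell_volume_fl=volume_fl,
        histone_ids=tuple(histone_ids),
        settings=settings,
    )


def summarize_copies(
    result: RulerResult,
    protein_sets: Mapping[str, Iterable[str]],
    stages: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-stage median and mean copies per named protein set.

    For each (set, stage): the median (and mean) over the set is computed
    within each replicate sample, then averaged across replicates with its
    standard error.  Returns a tidy frame with columns set, stage,
    median_copies, median_sem, mean_copies, mean_sem, n_proteins.
    """
    if result.settings.averaging_mode == "pooled":
        raise ValueError("stage summaries require per-column copy numbers")
    stage_of = {c: parse_sample_name(c)[0] for c in result.copies.columns}
    if stages is None:
        stages = list(dict.fromkeys(stage_of.values()))
    rows = []
    for name, ids in protein_sets.items():
        ids = [i for i in ids if i in result.copies.index]
        if not ids:
            log.warning("set %s: no members in ruler result, skipped", name)
            continue
        sub = result.copies.loc[ids]
        for stage in stages:
            cols = [c for c in sub.columns if stage_of[c] == stage]
            med = sub[cols].median(axis=0)
            mean = sub[cols].mean(axis=0)
            rows.append(
                {
                    "set": name,
                    "stage": stage,
                    "median_copies": med.mean(),
                    "median_sem": med.sem(ddof=1) if len(cols) > 1 else np.nan,
                    "mean_copies": mean.mean(),
                    "mean_sem": mean.sem(ddof=1) if len(cols) > 1 else np.nan,
                    "n_proteins": len(ids),
                }
            )
    return pd.DataFrame(rows)
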