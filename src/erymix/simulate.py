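"""Synthetic stage-resolved proteome generator with known ground truth.

Emulates a DIA-style bulk proteome of an ordered differentiation series
(five erythroid maturation stages by default, four biological replicates
each): several thousand protein groups whose true per-stage abundances
follow one of six temporal co-expression archetypes, multiplicative
log-normal replicate noise, intensity-dependent (left-censored, MNAR)
dropout, a histone subset whose total abundance declines with maturation,
and planted stage-specific marker proteins of graded separability.

Absolute scale is anchored the way the histone proteomic ruler assumes:
at the first stage, the summed histone mass per cell equals the DNA mass
of a diploid genome, so per-cell copy numbers planted here are recoverable
by ruler estimation on the noiseless matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .matrix import ProteomeMatrix, sample_name

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_proteome",
    "ARCHETYPES",
    "AVOGADRO",
    "HAPLOID_DNA_PG",
]

AVOGADRO = 6.022_140_76e23
#: human haploid genome DNA mass in picograms (~3.1 Gbp)
HAPLOID_DNA_PG = 3.25

#: the six temporal co-expression archetypes, in fixed label order
ARCHETYPES = (
    "monotone_up",
    "monotone_down",
    "early_peak",
    "late_peak",
    "transient_mid",
    "u_shaped",
)

DEFAULT_STAGES = ("Prog", "ProE_EBaso", "LBaso", "Poly", "Ortho")


def _archetype_shapes(n_stages: int) -> dict[str, np.ndarray]:
    """Unit-range temporal shapes over `n_stages` ordered stages."""
    t = np.linspace(0.0, 1.0, n_stages)
    width = 0.30

    def bump(center: float) -> np.ndarray:
        s = np.exp(-0.5 * ((t - center) / width) ** 2)
        return (s - s.min()) / (s.max() - s.min())

    shapes = {
        "monotone_up": t.copy(),
        "monotone_down": 1.0 - t,
        "early_peak": bump(1.0 / (n_stages - 1)),
        "late_peak": bump(1.0 - 1.0 / (n_stages - 1)),
        "transient_mid": bump(0.5),
        "u_shaped": 1.0 - bump(0.5),
    }
    return shapes


@dataclass
class SynthConfig:
    """Parameters of the synthetic proteome.

    noise_cv is the target within-stage coefficient of variation of
    replicate intensities (a fraction; 0.15 means 15%).  Dropout is
    logistic in log2 intensity: an observation at log2 intensity x is
    missing with probability sigmoid(steepness * (midpoint - x)).  When
    ``dropout_midpoint`` is None the midpoint is placed at the
    ``dropout_quantile`` quantile of the realized log2 intensities, which
    concentrates missingness in the low-abundance tail.
    """

    n_proteins: int = 4000
    stages: tuple[str, ...] = DEFAULT_STAGES
    n_replicates: int = 4
    archetype_weights: tuple[float, ...] = (1 / 6,) * 6
    noise_cv: float = 0.15
    dropout_midpoint: float | None = None
    dropout_steepness: float = 0.8
    dropout_quantile: float = 0.06
    n_histones: int = 10
    histone_decline: float = 0.8
    marker_spec: tuple[tuple[str, int, float], ...] = (
        ("sorting", 5, 0.65),
        ("known", 22, 0.6),
        ("slc", 18, 0.7),
    )
    #: relative stage coverage of planted panels; historically curated
    #: erythroid marker sets over-represent the extreme stages, while
    #: data-driven sets cover the axis evenly (None = even round-robin)
    marker_stage_bias: dict = field(
        default_factory=lambda: {
            "known": (0.25, 0.1, 0.1, 0.1, 0.45),
        }
    )
    #: how much marker separability is attenuated at the middle of the
    #: maturation axis (0 = none); intermediate stages differ less at the
    #: proteome level than the extremes, so even good markers resolve them
    #: less cleanly
    midstage_attenuation: float = 0.4
    ploidy: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins <= 0 or self.n_replicates <= 0 or self.n_histones < 0:
            raise ValueError("counts must be positive")
        if len(self.stages) < 2:
            raise ValueError("need at least two ordered stages")
        if len(self.archetype_weights) != len(ARCHETYPES):
            raise ValueError(f"archetype_weights must have {len(ARCHETYPES)} entries")
        w = np.asarray(self.archetype_weights, dtype=float)
        if (w < 0).any() or not np.isclose(w.sum(), 1.0, atol=1e-9):
            raise ValueError("archetype_weights must be non-negative and sum to 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        n_markers = sum(n for _, n, _ in self.marker_spec)
        if n_markers + self.n_histones > self.n_proteins:
            raise ValueError("markers plus histones exceed n_proteins")


@dataclass
class GroundTruth:
    """What the generator planted, for downstream validation.

    copies holds true per-cell copy numbers per (protein, stage) on the
    histone-ruler-anchored absolute scale; stage_mean_intensity is the
    noiseless intensity (copies x molecular mass x instrument response).
    """

    archetype: pd.Series
    stage_mean_intensity: pd.DataFrame
    copies: pd.DataFrame
    marker_panels: dict[str, list[str]]
    histone_ids: list[str]
    marker_stage: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))

    def to_tsv(self, path: str | Path) -> None:
        out = self.copies.copy()
        out.columns = [f"copies_{c}" for c in out.columns]
        out.insert(0, "archetype", self.archetype)
        out["is_histone"] = out.index.isin(self.histone_ids)
        panel = pd.Series("", index=out.index)
        for name, ids in self.marker_panels.items():
            panel.loc[ids] = name
        out["planted_panel"] = panel
        out.index.name = "protein_id"
        out.to_csv(path, sep="\t")


#: intensity per (copy x Dalton): arbitrary instrument response constant
_INTENSITY_PER_DALTON_COPY = 1e-4


def _assign_marker_stages(
    count: int, n_stages: int, bias: Sequence[float] | None
) -> list[int]:
    """Deterministic stage assignment for a panel's markers.

    With no bias, markers are spread round-robin over stages.  With a bias
    (relative coverage weights, one per stage) per-stage counts follow the
    largest-remainder apportionment of count x weights.
    """
    if bias is None:
        return [j % n_stages for j in range(count)]
    w = np.asarray(bias, dtype=float)
    if w.shape != (n_stages,) or (w < 0).any() or w.sum() == 0:
        raise ValueError("stage bias must be non-negative weights, one per stage")
    quota = count * w / w.sum()
    base = np.floor(quota).astype(int)
    remainder = count - base.sum()
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:remainder]] += 1
    out: list[int] = []
    for stage_idx, n in enumerate(base):
        out.extend([stage_idx] * int(n))
    return out


def generate_proteome(config: SynthConfig) -> tuple[ProteomeMatrix, GroundTruth]:
    """Draw one synthetic proteome matrix plus its ground truth.

    Replicate noise is log-normal with sigma = sqrt(ln(1 + cv^2)) and unit
    mean, so the within-stage CV of linear intensities equals ``noise_cv``.
    Output is byte-deterministic in ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_stages = len(config.stages)
    shapes = _archetype_shapes(n_stages)

    marker_ids: dict[str, list[str]] = {}
    rows: list[str] = []
    n_markers_total = sum(n for _, n, _ in config.marker_spec)
    n_bulk = config.n_proteins - n_markers_total - config.n_histones

    bulk_ids = [f"P{i:05d}" for i in range(n_bulk)]
    histone_ids = [f"HIST{i:02d}" for i in range(config.n_histones)]
    for panel, count, _ in config.marker_spec:
        marker_ids[panel] = [f"MK_{panel.upper()}{i:03d}" for i in range(count)]
        rows.extend(marker_ids[panel])
    all_ids = bulk_ids + histone_ids + rows

    # --- true per-stage copy numbers ---------------------------------------
    log2_amp = rng.uniform(0.5, 5.0, size=n_bulk)
    arch_idx = rng.choice(len(ARCHETYPES), size=n_bulk, p=config.archetype_weights)
    base_copies = 10 ** rng.uniform(2.0, 5.5, size=n_bulk)

    copies = {}
    archetype = {}
    for pid, a, amp, base in zip(bulk_ids, arch_idx, log2_amp, base_copies):
        shape = shapes[ARCHETYPES[a]]
        prof = 2.0 ** (amp * (shape - shape.mean()))
        copies[pid] = base * prof
        archetype[pid] = ARCHETYPES[a]

    # histones: abundant, declining multiplicatively with maturation
    hist_base = 10 ** rng.uniform(5.5, 6.5, size=config.n_histones)
    decline = config.histone_decline ** np.arange(n_stages)
    for pid, base in zip(histone_ids, hist_base):
        copies[pid] = base * decline
        archetype[pid] = "histone"

    # planted markers: a bump at an assigned stage; separability sets how
    # cleanly the bump stands above the off-stage floor
    marker_stage = {}
    for panel, count, sep in config.marker_spec:
        stage_assignment = _assign_marker_stages(
            count, n_stages, config.marker_stage_bias.get(panel)
        )
        for j, pid in enumerate(marker_ids[panel]):
            stage_idx = stage_assignment[j]
            # markers of intermediate stages are intrinsically less separable
            centrality = 1.0 - abs(stage_idx / (n_stages - 1) - 0.5) * 2.0
            eff_sep = sep * (1.0 - config.midstage_attenuation * centrality)
            # common on/off contrast; separability sets how cleanly the
            # on-stage signal stands above off-target leakage, not how
            # abundant the marker is
            amp = 5.0
            prof = np.full(n_stages, 1.0)
            prof[stage_idx] = 2.0**amp
            bleed = 2.0 ** (amp * (1.0 - eff_sep))
            if stage_idx > 0:
                prof[stage_idx - 1] = max(prof[stage_idx - 1], bleed)
            if stage_idx < n_stages - 1:
                prof[stage_idx + 1] = max(prof[stage_idx + 1], bleed)
            base = 10 ** rng.uniform(3.8, 4.2)
            copies[pid] = base * prof
            archetype[pid] = f"marker_{panel}"
            marker_stage[pid] = config.stages[stage_idx]

    copies_df = pd.DataFrame(copies, index=list(config.stages)).T.loc[all_ids]
    copies_df.columns = list(config.stages)

    # --- molecular masses ---------------------------------------------------
    mol_mass = pd.Series(
        np.exp(rng.normal(np.log(4.0e4), 0.5, size=len(all_ids))),
        index=all_ids,
        name="mol_mass_avg_Da",
    )
    mol_mass.loc[histone_ids] = rng.uniform(11_000, 22_000, size=config.n_histones)

    # --- anchor copies to the ruler's histone:DNA mass relation ------------
    if config.n_histones > 0:
        dna_mass_g = config.ploidy * HAPLOID_DNA_PG * 1e-12
        hist_mass = (
            copies_df.loc[histone_ids, config.stages[0]] * mol_mass.loc[histone_ids]
        ).sum() / AVOGADRO
        copies_df *= dna_mass_g / hist_mass

    # --- noiseless intensities and noisy replicates -------------------------
    stage_mean = copies_df.mul(mol_mass, axis=0) * _INTENSITY_PER_DALTON_COPY

    sigma = np.sqrt(np.log1p(config.noise_cv**2))
    columns = {}
    for stage in config.stages:
        mean = stage_mean[stage].to_numpy()
        for rep in range(1, config.n_replicates + 1):
            if sigma > 0:
                noise = rng.lognormal(-0.5 * sigma**2, sigma, size=len(all_ids))
            else:
                noise = np.ones(len(all_ids))
            columns[sample_name(stage, rep)] = mean * noise
    intensities = pd.DataFrame(columns, index=all_ids)

    # --- MNAR dropout --------------------------------------------------------
    if config.dropout_steepness > 0:
        log2_i = np.log2(intensities.to_numpy())
        if config.dropout_midpoint is None:
            midpoint = float(np.quantile(log2_i, config.dropout_quantile))
        else:
            midpoint = config.dropout_midpoint
        p_miss = 1.0 / (1.0 + np.exp(-config.dropout_steepness * (midpoint - log2_i)))
        drop = rng.random(size=log2_i.shape) < p_miss
        vals = intensities.to_numpy()
        vals[drop] = np.nan
        intensities = pd.DataFrame(vals, index=all_ids, columns=intensities.columns)

    matrix = ProteomeMatrix(
        intensities=intensities, mol_mass=mol_mass, stages=config.stages
    )
    truth = GroundTruth(
        archetype=pd.Series(archetype).loc[all_ids],
        stage_mean_intensity=stage_mean,
        copies=copies_df,
        marker_panels={k: list(v) for k, v in marker_ids.items()},
        histone_ids=list(histone_ids),
        marker_stage=pd.Series(marker_stage, dtype=object),
    )
    return matrix, truth


def write_curated_list(ids: Sequence[str], path: str | Path) -> None:
    """One protein id per line, the curated-list exchange format."""
    Path(path).write_text("\n".join(ids) + "\n")


def read_curated_list(path: str | Path) -> list[str]:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    ids = [ln for ln in lines if ln and not ln.startswith("#")]
    if len(set(ids)) != len(ids):
        warnings.warn(f"duplicate ids in curated list {path}; deduplicating")
        ids = list(dict.fromkeys(ids))
    return ids
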