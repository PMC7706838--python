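"""Core container for stage-resolved protein intensity matrices.

A :class:`ProteomeMatrix` holds linear-scale (non-logged) protein group
intensities for an ordered series of differentiation stages, each measured
in several biological replicates.  Missing values (proteins not quantified
in a sample) are encoded as NaN.  Column names follow the convention
``<stage>_r<replicate>``, e.g. ``LBaso_r2``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["ProteomeMatrix", "parse_sample_name", "sample_name"]

_SAMPLE_RE = re.compile(r"^(?P<stage>.+)_r(?P<rep>\d+)$")


def sample_name(stage: str, replicate: int) -> str:
    """Canonical column name for a (stage, replicate) sample."""
    return f"{stage}_r{replicate}"


def parse_sample_name(column: str) -> tuple[str, int]:
    """Split ``<stage>_r<k>`` into its stage label and replicate number."""
    m = _SAMPLE_RE.match(column)
    if m is None:
        raise ValueError(f"column {column!r} does not match '<stage>_r<replicate>'")
    return m.group("stage"), int(m.group("rep"))


@dataclass
class ProteomeMatrix:
    """Proteins x samples intensity matrix with stage/replicate metadata.

    Parameters
    ----------
    intensities
        DataFrame indexed by protein id; columns are ``<stage>_r<k>`` sample
        names; values are linear-scale intensities with NaN for missing.
    mol_mass
        Average molecular mass per protein in Daltons, aligned to the index.
    stages
        Ordered stage labels.  Order matters: it defines the maturation axis
        used by the deconvolution error metric.
    """

    intensities: pd.DataFrame
    mol_mass: pd.Series
    stages: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.stages = tuple(self.stages)
        if len(self.stages) < 2:
            raise ValueError("at least two ordered stages are required")
        if not self.intensities.index.is_unique:
            raise ValueError("protein ids must be unique")
        self.mol_mass = self.mol_mass.reindex(self.intensities.index)
        known = set(self.stages)
        for col in self.intensities.columns:
            stage, _ = parse_sample_name(col)
            if stage not in known:
                raise ValueError(f"column {col!r} references unknown stage {stage!r}")
        vals = self.intensities.to_numpy(dtype=float)
        if np.nanmin(vals, initial=np.inf) < 0:
            raise ValueError("linear intensities must be non-negative where present")

    # -- metadata -----------------------------------------------------------

    @property
    def protein_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def n_proteins(self) -> int:
        return len(self.intensities)

    def sample_stage(self, column: str) -> str:
        return parse_sample_name(column)[0]

    def stage_columns(self, stage: str, replicates: Sequence[int] | None = None) -> list[str]:
        """Columns of one stage, optionally restricted to given replicate numbers."""
        cols = []
        for col in self.intensities.columns:
            s, r = parse_sample_name(col)
            if s == stage and (replicates is None or r in set(replicates)):
                cols.append(col)
        return cols

    def replicate_numbers(self) -> list[int]:
        reps = sorted({parse_sample_name(c)[1] for c in self.intensities.columns})
        return reps

    def design(self) -> pd.Series:
        """Stage label per sample column, in column order."""
        return pd.Series(
            [parse_sample_name(c)[0] for c in self.intensities.columns],
            index=self.intensities.columns,
            name="stage",
        )

    # -- views --------------------------------------------------------------

    def log2(self) -> pd.DataFrame:
        """log2 intensities; zeros and missing both map to NaN."""
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.log2(self.intensities.where(self.intensities > 0))
        return out

    def subset(self, protein_ids: Iterable[str]) -> "ProteomeMatrix":
        ids = pd.Index(protein_ids)
        missing = ids.difference(self.intensities.index)
        if len(missing):
            raise KeyError(f"unknown protein ids: {list(missing)[:5]} ...")
        return ProteomeMatrix(
            intensities=self.intensities.loc[ids].copy(),
            mol_mass=self.mol_mass.loc[ids].copy(),
            stages=self.stages,
        )

    def with_intensities(self, intensities: pd.DataFrame) -> "ProteomeMatrix":
        return ProteomeMatrix(
            intensities=intensities,
            mol_mass=self.mol_mass.reindex(intensities.index),
            stages=self.stages,
        )

    # -- I/O ----------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Write the wide TSV dialect: protein_id, mol_mass_avg_Da, samples.

        Missing intensities are written as empty fields.
        """
        out = pd.DataFrame(index=self.intensities.index)
        out.index.name = "protein_id"
        out["mol_mass_avg_Da"] = self.mol_mass
        for col in self.intensities.columns:
            out[col] = self.intensities[col]
        out.to_csv(path, sep="\t", na_rep="")

    @classmethod
    def from_tsv(cls, path: str | Path, stages: Sequence[str]) -> "ProteomeMatrix":
        df = pd.read_csv(path, sep="\t", index_col="protein_id")
        if "mol_mass_avg_Da" not in df.columns:
            raise ValueError("matrix TSV must contain a 'mol_mass_avg_Da' column")
        mass = df.pop("mol_mass_avg_Da").astype(float)
        return cls(intensities=df.astype(float), mol_mass=mass, stages=tuple(stages))
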