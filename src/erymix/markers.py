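"""Assembly of stage-specific marker panels.

Six panels are compared downstream: three curated lists (FACS sorting
markers, literature-known markers, and a solute-carrier set), a data-driven
``cluster_top3`` panel (the most significant proteins of each temporal
cluster), their deduplicated union (``combined``), and a random ``any20``
negative control drawn from proteins outside every other panel.  All panels
except any20 are restricted to proteins passing the ANOVA q-value filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .profiles import StageStats

__all__ = ["MarkerPanel", "panel_cluster_top3", "assemble_panels", "write_panels", "read_panels"]

log = logging.getLogger(__name__)

PANEL_ORDER = ("sorting", "known", "cluster_top3", "slc", "combined", "any20")


@dataclass
class MarkerPanel:
    name: str
    protein_ids: tuple[str, ...]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.protein_ids = tuple(self.protein_ids)
        if len(set(self.protein_ids)) != len(self.protein_ids):
            raise ValueError(f"panel {self.name!r} contains duplicate ids")

    def __len__(self) -> int:
        return len(self.protein_ids)

    def __iter__(self):
        return iter(self.protein_ids)


def _rank_by_significance(table: pd.DataFrame) -> pd.DataFrame:
    """Sort ascending q, ties broken by larger F, then lexicographic id."""
    t = table.copy()
    t["_id"] = t.index
    return t.sort_values(["q", "F", "_id"], ascending=[True, False, True], kind="stable")


def panel_cluster_top3(stats: StageStats, per_cluster: int = 3) -> MarkerPanel:
    """Top `per_cluster` most significant proteins of each temporal cluster.

    A cluster with fewer members than requested contributes all of them.
    With six well-populated clusters and the default of three this yields
    an 18-protein stage-specific panel.
    """
    table = stats.table
    clustered = table[table["cluster"].notna()]
    if clustered.empty:
        raise ValueError("no cluster labels present; run cluster_profiles first")
    chosen: list[str] = []
    provenance: dict[str, str] = {}
    for label, group in clustered.groupby("cluster", observed=True, sort=True):
        ranked = _rank_by_significance(group)
        take = ranked.index[:per_cluster].tolist()
        if len(take) < per_cluster:
            log.warning("cluster %s has only %d members", label, len(take))
        chosen.extend(take)
        provenance.update({pid: f"cluster {label}" for pid in take})
    return MarkerPanel("cluster_top3", tuple(chosen), provenance)


def assemble_panels(
    stats: StageStats,
    curated: Mapping[str, Sequence[str]],
    universe: Iterable[str],
    q_threshold: float = 0.01,
    per_cluster: int = 3,
    any20_size: int = 20,
    seed: int = 0,
) -> list[MarkerPanel]:
    """Build the full six-panel comparison set.

    curated maps panel names (typically sorting/known/slc) to protein id
    lists; ids absent from the matrix are dropped with a warning, and every
    curated panel is filtered to q < ``q_threshold``.  ``combined`` is the
    deduplicated union of the curated panels and cluster_top3, in panel
    order.  ``any20`` is drawn uniformly (reproducibly in ``seed``) from
    the unfiltered universe minus all other panels.
    """
    universe = pd.Index(universe)
    table = stats.table
    panels: list[MarkerPanel] = []

    for name in ("sorting", "known"):
        if name in curated:
            panels.append(_curated_panel(name, curated[name], table, universe, q_threshold))
    panels.append(_qfilter_panel(panel_cluster_top3(stats, per_cluster), table, q_threshold))
    for name in curated:
        if name not in ("sorting", "known"):
            panels.append(_curated_panel(name, curated[name], table, universe, q_threshold))

    union: list[str] = []
    for p in panels:
        union.extend(pid for pid in p if pid not in union)
    panels.append(
        MarkerPanel("combined", tuple(union), {pid: "union" for pid in union})
    )

    taken = set(union)
    pool = [pid for pid in universe if pid not in taken]
    if len(pool) < any20_size:
        raise ValueError(f"any20 pool ({len(pool)}) smaller than {any20_size}")
    rng = np.random.default_rng(seed)
    any20 = tuple(sorted(rng.choice(pool, size=any20_size, replace=False)))
    panels.append(MarkerPanel("any20", any20, {pid: "random control" for pid in any20}))
    return panels


def _curated_panel(
    name: str,
    ids: Sequence[str],
    table: pd.DataFrame,
    universe: pd.Index,
    q_threshold: float,
) -> MarkerPanel:
    ids = list(dict.fromkeys(ids))
    absent = [i for i in ids if i not in universe]
    if absent:
        log.warning("panel %s: dropping %d ids absent from matrix", name, len(absent))
    present = [i for i in ids if i in universe]
    kept = [i for i in present if i in table.index and table.at[i, "q"] < q_threshold]
    n_failed = len(present) - len(kept)
    if n_failed:
        log.info("panel %s: %d ids failed q < %g", name, n_failed, q_threshold)
    return MarkerPanel(name, tuple(kept), {pid: "curated" for pid in kept})


def _qfilter_panel(panel: MarkerPanel, table: pd.DataFrame, q_threshold: float) -> MarkerPanel:
    kept = tuple(pid for pid in panel if table.at[pid, "q"] < q_threshold)
    return MarkerPanel(panel.name, kept, {p: panel.provenance.get(p, "") for p in kept})


def write_panels(panels: Iterable[MarkerPanel], path: str | Path) -> None:
    rows = [(p.name, pid) for p in panels for pid in p]
    pd.DataFrame(rows, columns=["panel_name", "protein_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_panels(path: str | Path) -> list[MarkerPanel]:
    df = pd.read_csv(path, sep="\t")
    return [
        MarkerPanel(name, tuple(sub["protein_id"]))
        for name, sub in df.groupby("panel_name", sort=False)
    ]
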