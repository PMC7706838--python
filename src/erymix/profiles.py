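"""Preprocessing and temporal profiling of stage-resolved proteomes.

Four steps, mirroring the standard DIA bulk-proteome workflow:

1. completeness filtering — keep proteins observed in enough replicates of
   at least one stage (left-censored MS data make global completeness too
   strict);
2. imputation of missing log2 intensities from a down-shifted normal per
   sample column, the classic left-censoring model;
3. a multi-stage one-way ANOVA with an S0-regularized F statistic and a
   permutation-based FDR;
4. hierarchical clustering of z-scored per-stage median profiles into k
   temporal clusters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats

from .matrix import ProteomeMatrix

__all__ = [
    "StageStats",
    "filter_completeness",
    "impute_missing",
    "anova_stage_test",
    "zscore_stage_medians",
    "cluster_profiles",
]

log = logging.getLogger(__name__)


@dataclass
class StageStats:
    """Per-protein differential statistics and temporal cluster labels.

    table has columns F, p, q and (after clustering) a nullable integer
    ``cluster`` column; z_profiles holds the z-scored stage-median profile
    of every tested protein (proteins x stages).
    """

    table: pd.DataFrame
    z_profiles: pd.DataFrame

    def significant(self, q_threshold: float) -> pd.Index:
        return self.table.index[self.table["q"] < q_threshold]

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "protein_id"
        out.to_csv(path, sep="\t")


def filter_completeness(
    matrix: ProteomeMatrix,
    min_fraction_per_stage: float = 0.75,
    n_stages_required: int = 1,
) -> ProteomeMatrix:
    """Keep proteins with enough observed replicates in enough stages.

    A protein is retained when at least ``min_fraction_per_stage`` of the
    replicates of a stage are observed, in at least ``n_stages_required``
    stages.  The default (>= 3 of 4 replicates in >= 1 stage) keeps any
    protein that is reliably quantified somewhere along the series.
    """
    if not 0 < min_fraction_per_stage <= 1:
        raise ValueError("min_fraction_per_stage must be in (0, 1]")
    ok_stages = pd.DataFrame(index=matrix.protein_ids)
    for stage in matrix.stages:
        cols = matrix.stage_columns(stage)
        if not cols:
            raise ValueError(f"stage {stage!r} has no sample columns")
        observed = matrix.intensities[cols].notna().sum(axis=1)
        ok_stages[stage] = observed / len(cols) >= min_fraction_per_stage
    keep = ok_stages.sum(axis=1) >= n_stages_required
    if keep.sum() == 0:
        log.warning("completeness filter removed every protein")
    return matrix.with_intensities(matrix.intensities.loc[keep].copy())


def impute_missing(
    log2_matrix: pd.DataFrame,
    width: float = 0.3,
    downshift: float = 1.8,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Replace missing log2 intensities by down-shifted normal draws.

    Per sample column with observed mean m and standard deviation s, each
    missing cell is drawn from Normal(m - downshift*s, (width*s)^2).  This
    places imputed values in the left tail of the column's distribution,
    the standard model for abundance-dependent censoring.  Observed cells
    are never altered.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out = log2_matrix.copy()
    for col in out.columns:
        vals = out[col]
        obs = vals.dropna()
        n_missing = vals.isna().sum()
        if n_missing == 0:
            continue
        if len(obs) < 2:
            raise ValueError(f"column {col!r} has < 2 observed values; sd undefined")
        m, s = obs.mean(), obs.std(ddof=1)
        draws = rng.normal(m - downshift * s, width * s, size=n_missing)
        out.loc[vals.isna(), col] = draws
    return out


def _f_statistic(
    values: np.ndarray, group_slices: list[np.ndarray], s0: float
) -> np.ndarray:
    """Vectorized one-way ANOVA F over proteins (rows), S0-regularized.

    With s0 > 0 the within-group scale sqrt(MSW) is inflated by s0 before
    squaring, damping the significance of proteins with tiny residual
    variance (the multi-sample analogue of the S0 trick in moderated
    t tests).  s0 = 0 recovers the textbook F.
    """
    n_total = sum(len(g) for g in group_slices)
    n_groups = len(group_slices)
    grand = values.mean(axis=1)
    ss_between = np.zeros(values.shape[0])
    ss_within = np.zeros(values.shape[0])
    for g in group_slices:
        sub = values[:, g]
        gm = sub.mean(axis=1)
        ss_between += len(g) * (gm - grand) ** 2
        ss_within += ((sub - gm[:, None]) ** 2).sum(axis=1)
    msb = ss_between / (n_groups - 1)
    msw = ss_within / (n_total - n_groups)
    denom = (np.sqrt(msw) + s0) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = msb / denom
    f[~np.isfinite(f)] = 0.0  # zero-variance rows: F defined as 0
    return f


def _permutation_q(
    f_obs: np.ndarray, f_null: np.ndarray, n_permutations: int
) -> np.ndarray:
    """Pooled-permutation FDR q-values, monotonized in significance rank.

    For a threshold t, the estimated FDR is (expected null exceedances per
    permutation) / (observed exceedances); each protein's raw q uses its
    own F as the threshold, and q-values are then made non-decreasing in
    p-value rank (step-up) and clipped to [0, 1].
    """
    order = np.argsort(-f_obs, kind="stable")
    sorted_f = f_obs[order]
    null_sorted = np.sort(f_null)
    # exceedances of each observed threshold among pooled null stats
    n_null_ge = len(null_sorted) - np.searchsorted(null_sorted, sorted_f, side="left")
    n_obs_ge = np.arange(1, len(sorted_f) + 1)
    raw = (n_null_ge / n_permutations) / n_obs_ge
    # suffix minimum: q non-decreasing as significance decreases
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def anova_stage_test(
    log2_matrix: pd.DataFrame,
    design: pd.Series,
    n_permutations: int = 250,
    s0: float = 0.1,
    seed: int = 0,
) -> StageStats:
    """Multi-stage differential test with permutation FDR.

    design maps each sample column to its stage label.  Stage labels are
    permuted across columns ``n_permutations`` times; permuted F statistics
    are pooled over proteins to estimate the null exceedance rate.
    Requires a complete (imputed) matrix.
    """
    if log2_matrix.isna().any().any():
        raise ValueError("matrix contains missing values; impute first")
    design = design.reindex(log2_matrix.columns)
    stages = list(dict.fromkeys(design))
    if len(stages) < 2:
        raise ValueError("need at least two stages")
    counts = design.value_counts()
    if (counts < 2).any():
        raise ValueError("need at least two replicates per stage")
    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations gives coarse q-values")

    values = log2_matrix.to_numpy(dtype=float)
    col_idx = {s: np.where((design == s).to_numpy())[0] for s in stages}
    slices = [col_idx[s] for s in stages]
    f_obs = _f_statistic(values, slices, s0)

    rng = np.random.default_rng(seed)
    n_cols = values.shape[1]
    sizes = [len(s) for s in slices]
    nulls = []
    for _ in range(n_permutations):
        perm = rng.permutation(n_cols)
        start, perm_slices = 0, []
        for sz in sizes:
            perm_slices.append(perm[start : start + sz])
            start += sz
        nulls.append(_f_statistic(values, perm_slices, s0))
    f_null = np.concatenate(nulls)

    q = _permutation_q(f_obs, f_null, n_permutations)

    # zero-variance proteins are uninformative by convention
    degenerate = values.std(axis=1) == 0
    if degenerate.any():
        log.info("%d zero-variance proteins set to q = 1", int(degenerate.sum()))
        q[degenerate] = 1.0

    dfn, dfd = len(stages) - 1, values.shape[1] - len(stages)
    p = scipy.stats.f.sf(f_obs, dfn, dfd)  # parametric reference (exact at s0=0)
    p[degenerate] = 1.0

    table = pd.DataFrame({"F": f_obs, "p": p, "q": q}, index=log2_matrix.index)
    table["cluster"] = pd.array([pd.NA] * len(table), dtype="Int64")
    z = zscore_stage_medians(log2_matrix, design, stages)
    return StageStats(table=table, z_profiles=z)


def zscore_stage_medians(
    log2_matrix: pd.DataFrame, design: pd.Series, stages: list[str] | None = None
) -> pd.DataFrame:
    """Median over replicates per stage, then z-score each protein's profile."""
    design = design.reindex(log2_matrix.columns)
    if stages is None:
        stages = list(dict.fromkeys(design))
    med = pd.DataFrame(
        {s: log2_matrix.loc[:, (design == s).to_numpy()].median(axis=1) for s in stages}
    )
    mu = med.mean(axis=1)
    sd = med.std(axis=1, ddof=1)
    z = med.sub(mu, axis=0).div(sd, axis=0)
    z[sd == 0] = 0.0  # flat profiles carry no shape information
    return z


def cluster_profiles(
    stats: StageStats,
    q_threshold: float = 0.01,
    k: int = 6,
    linkage: str = "ward",
) -> StageStats:
    """Cluster significant proteins' z-profiles into k temporal clusters.

    Agglomerative clustering with Euclidean distance on the z-scored
    stage-median profiles; the tree is cut into exactly k flat clusters.
    Ward linkage is the default: average linkage chains outlying profiles
    into singleton clusters and collapses the temporal structure, whereas
    Ward yields balanced shape clusters on this kind of data.
    Labels are renumbered 1..k by the stage at which the cluster's mean
    profile peaks, so label order follows the maturation axis.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    sig = stats.significant(q_threshold)
    if len(sig) < k:
        raise ValueError(f"only {len(sig)} significant proteins for k={k} clusters")
    z = stats.z_profiles.loc[sig]
    if k == 1:
        labels = np.ones(len(sig), dtype=int)
    else:
        tree = sch.linkage(z.to_numpy(), method=linkage, metric="euclidean")
        labels = sch.fcluster(tree, t=k, criterion="maxclust")

    # stable relabeling: order clusters by (peak stage, then mean profile)
    centroids = pd.DataFrame(z.to_numpy(), index=labels).groupby(level=0).mean()
    peak = centroids.to_numpy().argmax(axis=1)
    order = centroids.index.to_numpy()[np.lexsort((centroids.iloc[:, 0], peak))]
    remap = {old: new for new, old in enumerate(order, start=1)}
    new_labels = pd.Series([remap[v] for v in labels], index=sig, dtype="Int64")

    table = stats.table.copy()
    table["cluster"] = pd.array([pd.NA] * len(table), dtype="Int64")
    table.loc[sig, "cluster"] = new_labels
    return StageStats(table=table, z_profiles=stats.z_profiles)
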