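"""Scoring of estimated against true stage fractions.

The error metric respects the ordering of maturation stages: confusing
neighbouring stages is a smaller mistake than confusing distant ones.
With unit spacing between consecutive stages this is exactly the 1-D
earth-mover (Wasserstein-1) distance between the two fraction vectors,

    W1(a, b) = sum_{k=1}^{K-1} |cumsum_k(a) - cumsum_k(b)|,

a true metric on the simplex (zero iff equal, symmetric, triangle
inequality).  Three baselines calibrate the scale: a random simplex draw,
the uniform vector, and a one-hot vector at the middle stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .deconvolution import (
    MixtureSet,
    RatioMatrix,
    build_signature,
    estimate_fractions,
    generate_ratios,
    synthesize_mixtures,
)
from .markers import MarkerPanel
from .matrix import ProteomeMatrix

__all__ = ["EvaluationReport", "weighted_error", "control_estimate", "evaluate_panels"]

log = logging.getLogger(__name__)

CONTROL_KINDS = ("random", "uniform", "center")


def weighted_error(
    true_fractions: np.ndarray,
    est_fractions: np.ndarray,
    stage_spacing: np.ndarray | None = None,
) -> float:
    """Ordinal (earth-mover) distance between two stage-fraction vectors.

    stage_spacing optionally gives the K-1 distances between consecutive
    stages (default: all 1), for developmental axes with non-uniform gaps.
    """
    a = np.asarray(true_fractions, dtype=float)
    b = np.asarray(est_fractions, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("fraction vectors must be 1-D and of equal length")
    for v, name in ((a, "true"), (b, "estimated")):
        if (v < -1e-6).any() or abs(v.sum() - 1.0) > 1e-6:
            raise ValueError(f"{name} fractions are off the simplex")
    diff = np.cumsum(a - b)[:-1]
    if stage_spacing is None:
        return float(np.abs(diff).sum())
    spacing = np.asarray(stage_spacing, dtype=float)
    if spacing.shape != diff.shape:
        raise ValueError("stage_spacing must have K-1 entries")
    return float((np.abs(diff) * spacing).sum())


def control_estimate(
    kind: str, n_stages: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Baseline fraction estimates: 'random', 'uniform', or 'center'.

    uniform returns 1/K per stage; center a one-hot at the middle stage
    (index ceil(K/2) in 1-based counting, e.g. the third of five); random
    a fresh flat-Dirichlet simplex draw.
    """
    if n_stages < 2:
        raise ValueError("n_stages must be >= 2")
    if kind == "uniform":
        return np.full(n_stages, 1.0 / n_stages)
    if kind == "center":
        out = np.zeros(n_stages)
        out[int(np.ceil(n_stages / 2)) - 1] = 1.0
        return out
    if kind == "random":
        if isinstance(seed, np.random.Generator):
            return seed.dirichlet(np.ones(n_stages))
        return generate_ratios(1, n_stages, seed=seed).fractions[0]
    raise ValueError(f"unknown control kind {kind!r}")


@dataclass
class EvaluationReport:
    """Per-mixture weighted errors for every panel and control."""

    errors: pd.DataFrame  # rows: mixtures, columns: panel names
    control_errors: pd.DataFrame  # rows: mixtures, columns: control kinds
    skipped_panels: tuple[str, ...] = ()

    def summary(self) -> pd.DataFrame:
        """min, quartiles, median, mean, max per panel and control."""
        both = pd.concat([self.errors, self.control_errors], axis=1)
        rows = {}
        for name in both.columns:
            e = both[name].to_numpy()
            rows[name] = {
                "min": e.min(),
                "q1": np.quantile(e, 0.25),
                "median": np.median(e),
                "mean": e.mean(),
                "q3": np.quantile(e, 0.75),
                "max": e.max(),
            }
        return pd.DataFrame(rows).T

    def to_tsv(self, path) -> None:
        long = pd.concat([self.errors, self.control_errors], axis=1).reset_index(
            names="mixture_index"
        )
        long.melt(
            id_vars="mixture_index", var_name="panel", value_name="error"
        ).to_csv(path, sep="\t", index=False)


def evaluate_panels(
    matrix: ProteomeMatrix,
    panels: list[MarkerPanel],
    ratios: RatioMatrix,
    signature_replicates: tuple[int, ...] = (2, 4),
    mixture_replicates: tuple[int, ...] = (1, 3),
    retain_fraction: float = 0.90,
    control_seed: int = 0,
    stage_spacing: np.ndarray | None = None,
) -> EvaluationReport:
    """Run the full benchmark: every panel against the same set of mixtures.

    Mixtures are synthesized once from the designated mixture replicates
    and shared across panels, so panel comparisons are paired per mixture.
    A panel whose signature loses full column rank is skipped with a
    warning.  The random control is re-drawn per mixture, independently of
    the truth; uniform and center are deterministic.
    """
    mixtures = synthesize_mixtures(
        matrix,
        ratios,
        mixture_replicates=mixture_replicates,
        signature_replicates=signature_replicates,
    )
    truth = ratios.fractions
    n_stages = ratios.n_stages

    errors: dict[str, np.ndarray] = {}
    skipped: list[str] = []
    for panel in panels:
        try:
            sig = build_signature(matrix, panel, signature_replicates)
        except (ValueError, KeyError) as exc:
            log.warning("panel %s skipped: %s", panel.name, exc)
            skipped.append(panel.name)
            continue
        if sig.rank() < n_stages:
            log.warning("panel %s skipped: signature rank < %d", panel.name, n_stages)
            skipped.append(panel.name)
            continue
        errs = np.empty(ratios.n_mixtures)
        mix_sub = mixtures.intensities.reindex(sig.marker_ids)
        for m in range(ratios.n_mixtures):
            est = estimate_fractions(sig, mix_sub.iloc[:, m], retain_fraction)
            errs[m] = weighted_error(truth[m], est.fractions, stage_spacing)
        errors[panel.name] = errs

    rng = np.random.default_rng(control_seed)
    ctrl = {}
    for kind in CONTROL_KINDS:
        errs = np.empty(ratios.n_mixtures)
        for m in range(ratios.n_mixtures):
            est = control_estimate(kind, n_stages, seed=rng)
            errs[m] = weighted_error(truth[m], est, stage_spacing)
        ctrl[f"control_{kind}"] = errs

    index = pd.RangeIndex(ratios.n_mixtures, name="mixture_index")
    return EvaluationReport(
        errors=pd.DataFrame(errors, index=index),
        control_errors=pd.DataFrame(ctrl, index=index),
        skipped_panels=tuple(skipped),
    )
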