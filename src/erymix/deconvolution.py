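"""Reference-based mixture deconvolution over ordered maturation stages.

The model: a bulk sample mixed from S pure stage populations has, for each
marker protein k, an intensity

    I_mix_k = sum_i I_ik * a_i,        sum_i a_i = 1,  a_i >= 0,

where I_ik is the signature intensity of marker k in stage i and a_i is
the fraction of cells from stage i.  Given a signature matrix I (markers x
stages, averaged non-logged intensities from held-out replicates) and a
mixture vector i_mix, stage fractions are estimated by non-negative least
squares, refined in a second pass on the best-fitting markers, and finally
L1-normalized onto the simplex.

Signature and mixture intensities come from disjoint replicate subsets
(by default replicates 2+4 and 1+3 respectively), so the benchmark carries
genuine replicate noise rather than fitting the signature to itself.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize

from .markers import MarkerPanel
from .matrix import ProteomeMatrix

__all__ = [
    "SignatureMatrix",
    "RatioMatrix",
    "MixtureSet",
    "FractionEstimate",
    "build_signature",
    "generate_ratios",
    "synthesize_mixtures",
    "estimate_fractions",
]

log = logging.getLogger(__name__)

#: linear MS intensities are orders of magnitude above this; a matrix whose
#: largest value is below it has almost surely been log-transformed already
_LOG_SCALE_CEILING = 64.0


@dataclass
class SignatureMatrix:
    """Markers x stages reference intensities (linear scale, complete)."""

    values: pd.DataFrame  # index marker id, columns ordered stages
    panel_name: str = ""

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("signature must have no missing entries")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("signature intensities must be non-negative")

    @property
    def marker_ids(self) -> pd.Index:
        return self.values.index

    @property
    def stages(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    @property
    def n_stages(self) -> int:
        return self.values.shape[1]

    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.values.to_numpy()))


@dataclass
class RatioMatrix:
    """True mixing fractions, one simplex vector per in silico mixture."""

    fractions: np.ndarray  # (n_mixtures, n_stages)
    seed: int | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if f.ndim != 2:
            raise ValueError("fractions must be 2-D (mixtures x stages)")
        if (f < 0).any():
            raise ValueError("fractions must be non-negative")
        if not np.allclose(f.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("every mixture's fractions must sum to 1")
        self.fractions = f

    @property
    def n_mixtures(self) -> int:
        return self.fractions.shape[0]

    @property
    def n_stages(self) -> int:
        return self.fractions.shape[1]


@dataclass
class MixtureSet:
    """Mixture intensity vectors over a protein universe.

    intensities: proteins x mixtures; NaN rows mark proteins unobserved in
    the mixture-source replicates of at least one stage (such markers are
    dropped per mixture system rather than zero-filled).
    """

    intensities: pd.DataFrame
    ratios: RatioMatrix
    source_replicates: tuple[int, ...] = ()

    @property
    def n_mixtures(self) -> int:
        return self.intensities.shape[1]


@dataclass
class FractionEstimate:
    """Result of the two-pass constrained fit for one mixture."""

    fractions: np.ndarray  # L1-normalized, on the simplex
    stages: tuple[str, ...]
    retained_ids: tuple[str, ...]
    residual_norms: tuple[float, float]  # (iteration 1, iteration 2)
    raw_fractions: np.ndarray = field(default=None)  # pre-normalization solution


def build_signature(
    matrix: ProteomeMatrix,
    panel: MarkerPanel,
    signature_replicates: tuple[int, ...] = (2, 4),
) -> SignatureMatrix:
    """Average the designated replicates per stage for each marker.

    Entries are arithmetic means of linear (non-logged) intensities; a
    guard rejects matrices that look log-transformed.  Markers unobserved
    in all designated replicates of any stage are dropped with a warning.
    """
    if len(panel) == 0:
        raise ValueError("panel is empty")
    ids = pd.Index(panel.protein_ids)
    missing = ids.difference(matrix.protein_ids)
    if len(missing):
        raise KeyError(f"panel ids absent from matrix: {list(missing)[:5]}")
    sub = matrix.intensities.loc[ids]
    if np.nanmax(sub.to_numpy(), initial=0.0) < _LOG_SCALE_CEILING:
        raise ValueError(
            "intensities look log-transformed (all values < 64); "
            "signatures require linear-scale intensities"
        )
    cols = {}
    for stage in matrix.stages:
        stage_cols = matrix.stage_columns(stage, signature_replicates)
        if not stage_cols:
            raise ValueError(f"no designated signature replicates for stage {stage!r}")
        cols[stage] = sub[stage_cols].mean(axis=1)  # nan-aware
    sig = pd.DataFrame(cols)[list(matrix.stages)]
    incomplete = sig.isna().any(axis=1)
    if incomplete.any():
        log.warning(
            "panel %s: dropping %d markers unobserved in the signature "
            "replicates of some stage",
            panel.name,
            int(incomplete.sum()),
        )
        sig = sig[~incomplete]
    if sig.empty:
        raise ValueError(f"panel {panel.name!r}: signature is empty after dropping")
    return SignatureMatrix(values=sig, panel_name=panel.name)


def generate_ratios(
    n_mixtures: int = 500, n_stages: int = 5, seed: int = 0
) -> RatioMatrix:
    """Random stage-fraction vectors on the simplex.

    Drawn flat-Dirichlet (concentration 1), i.e. uniformly on the simplex,
    which is exchangeable across stages: no stage is favoured a priori.
    """
    if n_mixtures < 1:
        raise ValueError("n_mixtures must be >= 1")
    if n_stages < 1:
        raise ValueError("n_stages must be >= 1")
    if n_stages == 1:
        fractions = np.ones((n_mixtures, 1))
    else:
        rng = np.random.default_rng(seed)
        fractions = rng.dirichlet(np.ones(n_stages), size=n_mixtures)
        # guard against floating-point drift off the simplex
        fractions /= fractions.sum(axis=1, keepdims=True)
    return RatioMatrix(fractions=fractions, seed=seed)


def synthesize_mixtures(
    matrix: ProteomeMatrix,
    ratios: RatioMatrix,
    mixture_replicates: tuple[int, ...] = (1, 3),
    signature_replicates: tuple[int, ...] | None = (2, 4),
    allow_overlap: bool = False,
) -> MixtureSet:
    """Linear in silico mixtures of pure-stage profiles.

    Per stage, the designated mixture replicates are averaged into a pure
    profile; each mixture is the ratio-weighted sum of these profiles.
    Mixture replicates must be disjoint from the signature replicates
    unless ``allow_overlap`` is set.
    """
    if signature_replicates is not None and not allow_overlap:
        overlap = set(mixture_replicates) & set(signature_replicates)
        if overlap:
            raise ValueError(
                f"mixture replicates {sorted(overlap)} overlap the signature "
                "replicates; pass allow_overlap=True to permit"
            )
    if ratios.n_stages != len(matrix.stages):
        raise ValueError("ratio matrix stage count does not match the matrix")
    profiles = {}
    for stage in matrix.stages:
        cols = matrix.stage_columns(stage, mixture_replicates)
        if not cols:
            raise ValueError(f"no designated mixture replicates for stage {stage!r}")
        profiles[stage] = matrix.intensities[cols].mean(axis=1)
    pure = pd.DataFrame(profiles)[list(matrix.stages)]
    mixed = pure.to_numpy() @ ratios.fractions.T  # NaN propagates by design
    intensities = pd.DataFrame(
        mixed,
        index=pure.index,
        columns=[f"mix{i:04d}" for i in range(ratios.n_mixtures)],
    )
    return MixtureSet(
        intensities=intensities,
        ratios=ratios,
        source_replicates=tuple(mixture_replicates),
    )


def _nnls(signature: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, float]:
    coef, rnorm = scipy.optimize.nnls(signature, target)
    return coef, rnorm


def estimate_fractions(
    signature: SignatureMatrix,
    mixture: pd.Series | np.ndarray,
    retain_fraction: float = 0.90,
) -> FractionEstimate:
    """Two-pass non-negative least squares on the simplex.

    Pass 1 solves min ||I a - i_mix||_2 subject to a >= 0 over all markers.
    Markers are then ranked by scaled per-marker residual
    |I_k . a - i_mix_k| / ||I_k||_2 (scaling stops abundant markers from
    dominating retention) and the best ``retain_fraction`` are kept.
    Pass 2 re-solves on the retained markers; the solution is divided by
    its L1 norm to yield stage fractions.
    """
    if not 0 < retain_fraction <= 1:
        raise ValueError("retain_fraction must be in (0, 1]")
    sig = signature.values
    if isinstance(mixture, pd.Series):
        common = sig.index.intersection(mixture.index)
        mix = mixture.loc[common]
        mix = mix.dropna()
        sig = sig.loc[mix.index]
        target = mix.to_numpy(dtype=float)
    else:
        target = np.asarray(mixture, dtype=float)
        keep = ~np.isnan(target)
        sig = sig.iloc[keep]
        target = target[keep]
    n_markers, n_stages = sig.shape
    if n_markers < n_stages:
        raise ValueError(
            f"only {n_markers} usable markers for {n_stages} stages"
        )
    if np.all(target == 0):
        raise ValueError("all-zero mixture vector")
    if np.linalg.matrix_rank(sig.to_numpy()) < n_stages:
        warnings.warn("signature is rank-deficient; fractions may be unstable")

    A = sig.to_numpy(dtype=float)
    coef1, rnorm1 = _nnls(A, target)

    row_norms = np.linalg.norm(A, axis=1)
    row_norms[row_norms == 0] = 1.0
    marker_residual = np.abs(A @ coef1 - target) / row_norms
    n_keep = max(n_stages, int(round(retain_fraction * n_markers)))
    keep_idx = np.argsort(marker_residual, kind="stable")[:n_keep]
    keep_idx.sort()

    if rnorm1 <= 1e-9 * np.linalg.norm(target):
        # perfect fit: every marker is consistent, the residual ranking is
        # pure numerical noise and a refit on a flat landscape can wander;
        # iteration 2 keeps the exact iteration-1 solution
        coef2 = coef1
        rnorm2 = float(np.linalg.norm(A[keep_idx] @ coef1 - target[keep_idx]))
    else:
        coef2, rnorm2 = _nnls(A[keep_idx], target[keep_idx])
    total = np.abs(coef2).sum()
    if total == 0:
        raise ValueError("degenerate fit: estimated fractions sum to zero")
    fractions = coef2 / total
    return FractionEstimate(
        fractions=fractions,
        stages=signature.stages,
        retained_ids=tuple(sig.index[keep_idx]),
        residual_norms=(float(rnorm1), float(rnorm2)),
        raw_fractions=coef2,
    )
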