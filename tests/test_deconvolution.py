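import numpy as np
import pandas as pd
import pytest

import erymix as em
from erymix.deconvolution import (
    RatioMatrix,
    SignatureMatrix,
    build_signature,
    estimate_fractions,
    generate_ratios,
    synthesize_mixtures,
)
from erymix.markers import MarkerPanel

from conftest import toy_matrix


def _simplex_grid(n_stages: int, step: float) -> np.ndarray:
    ticks = np.round(np.arange(0, 1 + step / 2, step), 9)
    if n_stages == 2:
        return np.column_stack([ticks, 1 - ticks])
    if n_stages == 3:
        a, b = np.meshgrid(ticks, ticks, indexing="ij")
        keep = a + b <= 1 + 1e-12
        return np.column_stack([a[keep], b[keep], 1 - a[keep] - b[keep]])
    raise ValueError("oracle supports 2 or 3 stages")


def grid_search_simplex(signature: np.ndarray, mixture: np.ndarray, step=1e-3):
    """Independent oracle: exhaustive search over simplex directions.

    The estimator minimizes over all non-negative coefficient vectors and
    L1-normalizes afterwards, so every candidate direction u on the simplex
    is scored at its best non-negative scale t(u) = max(0, <Su, m>/|Su|^2),
    and the direction with the smallest scaled residual wins.  For
    consistent mixtures this coincides with the best point on the simplex
    itself.
    """
    grid = _simplex_grid(signature.shape[1], step)
    proj = grid @ signature.T  # candidate signature responses
    norms2 = (proj**2).sum(axis=1)
    t = np.clip((proj @ mixture) / np.where(norms2 > 0, norms2, 1.0), 0.0, None)
    resid = ((t[:, None] * proj - mixture) ** 2).sum(axis=1)
    return grid[np.argmin(resid)]


def two_stage_matrix():
    return toy_matrix(
        {
            "A_r1": [100.0, 1000.0], "A_r2": [100.0, 1000.0],
            "A_r3": [100.0, 1000.0], "A_r4": [100.0, 1000.0],
            "B_r1": [900.0, 200.0], "B_r2": [900.0, 200.0],
            "B_r3": [900.0, 200.0], "B_r4": [900.0, 200.0],
        },
        stages=("A", "B"),
    )


# ---------------------------------------------------------------- signature
class TestBuildSignature:
    def test_mean_of_designated_replicates(self):
        m = toy_matrix(
            {
                "A_r1": [1.0e6], "A_r2": [100.0], "A_r3": [5.0e6], "A_r4": [300.0],
                "B_r1": [70.0], "B_r2": [80.0], "B_r3": [90.0], "B_r4": [100.0],
            },
            stages=("A", "B"),
        )
        sig = build_signature(m, MarkerPanel("p", ("P0",)), signature_replicates=(2, 4))
        # replicate values 100 and 300 average to 200; reps 1 and 3 ignored
        assert sig.values.loc["P0", "A"] == 200.0
        assert sig.values.loc["P0", "B"] == 90.0

    def test_rejects_log_scale_input(self):
        m = toy_matrix(
            {f"{s}_r{r}": [20.5] for s in ("A", "B") for r in (1, 2)},
            stages=("A", "B"),
        )
        with pytest.raises(ValueError, match="log-transformed"):
            build_signature(m, MarkerPanel("p", ("P0",)), signature_replicates=(1, 2))

    def test_marker_missing_in_all_signature_reps_dropped(self):
        m = toy_matrix(
            {
                "A_r2": [np.nan, 500.0], "A_r4": [np.nan, 600.0],
                "B_r2": [100.0, 700.0], "B_r4": [200.0, 800.0],
            },
            stages=("A", "B"),
        )
        sig = build_signature(m, MarkerPanel("p", ("P0", "P1")), (2, 4))
        assert list(sig.marker_ids) == ["P1"]

    def test_empty_panel_errors(self, default_dataset):
        _, matrix, _ = default_dataset
        with pytest.raises(ValueError, match="empty"):
            build_signature(matrix, MarkerPanel("p", ()))


# ---------------------------------------------------------------- ratios
class TestGenerateRatios:
    def test_rows_on_simplex(self):
        r = generate_ratios(500, 5, seed=1)
        assert r.fractions.shape == (500, 5)
        assert (r.fractions >= 0).all()
        np.testing.assert_allclose(r.fractions.sum(axis=1), 1.0, atol=1e-12)

    def test_single_stage_forced_to_one(self):
        r = generate_ratios(10, 1, seed=0)
        np.testing.assert_array_equal(r.fractions, np.ones((10, 1)))

    def test_exchangeable_coordinate_means(self):
        # flat-Dirichlet symmetry: each coordinate has mean 1/5
        r = generate_ratios(100_000, 5, seed=2)
        np.testing.assert_allclose(r.fractions.mean(axis=0), 0.2, atol=0.005)

    def test_determinism_and_validation(self):
        np.testing.assert_array_equal(
            generate_ratios(50, 5, seed=3).fractions,
            generate_ratios(50, 5, seed=3).fractions,
        )
        with pytest.raises(ValueError):
            generate_ratios(0, 5)
        with pytest.raises(ValueError):
            RatioMatrix(np.array([[0.5, 0.6]]))
        with pytest.raises(ValueError):
            RatioMatrix(np.array([[-0.1, 1.1]]))


# ---------------------------------------------------------------- mixtures
class TestSynthesizeMixtures:
    def test_one_hot_ratio_returns_stage_profile(self):
        m = two_stage_matrix()
        ratios = RatioMatrix(np.array([[1.0, 0.0], [0.0, 1.0]]))
        mix = synthesize_mixtures(m, ratios, mixture_replicates=(1, 3))
        np.testing.assert_allclose(mix.intensities["mix0000"], [100.0, 1000.0])
        np.testing.assert_allclose(mix.intensities["mix0001"], [900.0, 200.0])

    def test_eq2_arithmetic(self):
        # stage profiles (10, 30) at weights (0.5, 0.5) mix to 20
        m = toy_matrix(
            {"A_r1": [10.0], "A_r3": [10.0], "B_r1": [30.0], "B_r3": [30.0]},
            stages=("A", "B"),
        )
        mix = synthesize_mixtures(
            m, RatioMatrix(np.array([[0.5, 0.5]])), mixture_replicates=(1, 3),
            signature_replicates=None,
        )
        assert mix.intensities.iloc[0, 0] == 20.0

    def test_linearity_in_ratios(self):
        m = two_stage_matrix()
        r = RatioMatrix(np.array([[0.25, 0.75], [0.0, 1.0], [0.5, 0.5]]))
        mix = synthesize_mixtures(m, r, mixture_replicates=(1, 3))
        avg = (mix.intensities["mix0001"] + mix.intensities["mix0002"]) / 2
        np.testing.assert_allclose(mix.intensities["mix0000"], avg, rtol=1e-12)

    def test_replicate_overlap_guard(self):
        m = two_stage_matrix()
        r = RatioMatrix(np.array([[0.5, 0.5]]))
        with pytest.raises(ValueError, match="overlap"):
            synthesize_mixtures(m, r, mixture_replicates=(2, 4), signature_replicates=(2, 4))
        # explicit opt-out allows it
        synthesize_mixtures(
            m, r, mixture_replicates=(2, 4), signature_replicates=(2, 4),
            allow_overlap=True,
        )


# ---------------------------------------------------------------- estimation
def make_signature(values, stages=("A", "B")):
    ids = [f"M{i}" for i in range(len(values))]
    return SignatureMatrix(pd.DataFrame(values, index=ids, columns=list(stages)))


class TestEstimateFractions:
    def test_noiseless_recovery_from_own_columns(self):
        rng = np.random.default_rng(0)
        sig = make_signature(
            rng.uniform(100, 10_000, size=(12, 5)), stages=list("ABCDE")
        )
        truth = np.array([0.1, 0.2, 0.3, 0.2, 0.2])
        mixture = sig.values.to_numpy() @ truth
        est = estimate_fractions(sig, mixture)
        np.testing.assert_allclose(est.fractions, truth, atol=1e-6)

    def test_two_stage_toy_matches_grid_oracle(self):
        sig = make_signature([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        mixture = np.array([0.3, 0.7, 1.0])
        est = estimate_fractions(sig, mixture, retain_fraction=1.0)
        np.testing.assert_allclose(est.fractions, [0.3, 0.7], atol=1e-9)
        oracle = grid_search_simplex(sig.values.to_numpy(), mixture)
        np.testing.assert_allclose(est.fractions, oracle, atol=1e-3)

    def test_retention_count_is_exact(self):
        rng = np.random.default_rng(1)
        sig = make_signature(rng.uniform(10, 1000, size=(100, 5)), stages=list("ABCDE"))
        mixture = sig.values.to_numpy() @ np.full(5, 0.2) * rng.uniform(
            0.9, 1.1, size=100
        )
        est = estimate_fractions(sig, mixture, retain_fraction=0.90)
        assert len(est.retained_ids) == 90

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        sig_vals = rng.uniform(10, 1000, size=(20, 5))
        mixture = sig_vals @ rng.dirichlet(np.ones(5)) * rng.uniform(0.95, 1.05, 20)
        a = estimate_fractions(make_signature(sig_vals, list("ABCDE")), mixture)
        b = estimate_fractions(
            make_signature(sig_vals * 37.5, list("ABCDE")), mixture * 37.5
        )
        np.testing.assert_allclose(a.fractions, b.fractions, atol=1e-10)
        assert a.retained_ids == b.retained_ids

    def test_second_pass_residual_not_worse(self):
        rng = np.random.default_rng(3)
        for trial in range(20):
            sig_vals = rng.uniform(10, 5000, size=(30, 5))
            mixture = sig_vals @ rng.dirichlet(np.ones(5)) * rng.uniform(
                0.8, 1.2, size=30
            )
            sig = make_signature(sig_vals, list("ABCDE"))
            est = estimate_fractions(sig, mixture)
            # the refit cannot fit the retained markers worse than the
            # iteration-1 solution restricted to them
            idx = [sig.values.index.get_loc(i) for i in est.retained_ids]
            restricted = np.linalg.norm(
                sig_vals[idx] @ _first_pass(sig_vals, mixture) - mixture[idx]
            )
            assert est.residual_norms[1] <= restricted + 1e-10

    def test_output_on_simplex(self):
        rng = np.random.default_rng(4)
        sig = make_signature(rng.uniform(1, 100, size=(15, 5)), stages=list("ABCDE"))
        mixture = rng.uniform(1, 100, size=15)
        est = estimate_fractions(sig, mixture)
        assert (est.fractions >= 0).all()
        assert est.fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_nan_markers_dropped_from_system(self):
        sig = make_signature([[100.0, 10.0], [10.0, 100.0], [50.0, 50.0]])
        mixture = pd.Series([55.0, 55.0, np.nan], index=sig.marker_ids)
        est = estimate_fractions(sig, mixture)
        assert "M2" not in est.retained_ids
        np.testing.assert_allclose(est.fractions, [0.5, 0.5], atol=1e-6)

    def test_degenerate_inputs_error(self):
        sig = make_signature([[1.0, 0.0], [0.0, 1.0]])
        with pytest.raises(ValueError, match="all-zero"):
            estimate_fractions(sig, np.zeros(2))
        with pytest.raises(ValueError, match="usable markers"):
            estimate_fractions(sig, pd.Series([np.nan, 1.0], index=sig.marker_ids))
        with pytest.raises(ValueError):
            estimate_fractions(sig, np.array([1.0, 1.0]), retain_fraction=0.0)


def _first_pass(sig_vals, mixture):
    import scipy.optimize

    return scipy.optimize.nnls(sig_vals, mixture)[0]


def test_oracle_equivalence_three_stage_perturbed():
    """Constrained least squares agrees with the exhaustive simplex grid on
    small systems, including mildly inconsistent (perturbed) mixtures."""
    rng = np.random.default_rng(8)
    for trial in range(5):
        sig_vals = rng.uniform(50, 5000, size=(8, 3))
        truth = rng.dirichlet(np.ones(3))
        mixture = sig_vals @ truth * (1 + rng.normal(0, 0.005, size=8))
        est = estimate_fractions(
            make_signature(sig_vals, list("ABC")), mixture, retain_fraction=1.0
        )
        oracle = grid_search_simplex(sig_vals, mixture, step=1e-3)
        np.testing.assert_allclose(est.fractions, oracle, atol=2e-3)
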