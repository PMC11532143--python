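import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fermfuse.analytics import (
    pca_flat,
    pca_time,
    resample_common_grid,
    spearman_screen,
)
from fermfuse.model import BatchMeta, FusedFrame, RangeError


def frame_from(times, columns, batch_id="b"):
    return FusedFrame(times=np.asarray(times, float),
                      data=pd.DataFrame(columns),
                      meta=BatchMeta(batch_id=batch_id))


def rank_then_pearson(x, y):
    """Independent oracle: average ranks by brute force, then Pearson."""
    def ranks(v):
        v = np.asarray(v, float)
        r = np.empty(v.size)
        for i, vi in enumerate(v):
            less = np.sum(v < vi)
            equal = np.sum(v == vi)
            r[i] = less + (equal + 1) / 2.0
        return r

    rx, ry = ranks(x), ranks(y)
    return np.corrcoef(rx, ry)[0, 1]


class TestSpearman:
    def test_perfect_monotone(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 5.0, 9.0], "up": [2.0, 4.0, 5.0, 8.0],
                           "down": [9.0, 3.0, 2.0, 1.0]})
        screen = spearman_screen(df, targets=["up", "down"], factors=["x"])
        assert screen.rho.loc["x", "up"] == pytest.approx(1.0)
        assert screen.rho.loc["x", "down"] == pytest.approx(-1.0)

    def test_matches_brute_force_oracle_with_ties(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            n = int(rng.integers(4, 50))
            x = rng.integers(0, 6, n).astype(float)  # heavy ties
            y = rng.integers(0, 6, n).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            df = pd.DataFrame({"x": x, "y": y})
            screen = spearman_screen(df, targets=["y"], factors=["x"])
            assert screen.rho.loc["x", "y"] == pytest.approx(
                rank_then_pearson(x, y), abs=1e-12)

    def test_exact_permutation_p_for_tiny_n(self):
        # n=4 without ties: 24 permutations; |rho|=1 occurs for exactly the
        # identity and the reversal -> p = 2/24
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0], "y": [10.0, 20.0, 30.0, 40.0]})
        screen = spearman_screen(df, targets=["y"], factors=["x"])
        assert screen.p.loc["x", "y"] == pytest.approx(2.0 / 24.0)

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        screen = spearman_screen(pd.DataFrame({"x": x, "y": y}),
                                 targets=["y"], factors=["x"])
        ref_r, ref_p = stats.spearmanr(x, y)
        assert screen.p.loc["x", "y"] == pytest.approx(ref_p, rel=1e-9)

    def test_constant_column_gives_nan(self):
        df = pd.DataFrame({"x": [1.0, 1.0, 1.0, 1.0], "y": [1.0, 2.0, 3.0, 4.0]})
        screen = spearman_screen(df, targets=["y"], factors=["x"])
        assert np.isnan(screen.rho.loc["x", "y"])

    def test_too_few_observations_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "y": [1.0, 2.0]})
        with pytest.raises(RangeError):
            spearman_screen(df, targets=["y"], factors=["x"])

    def test_bh_correction_never_lowers_p(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        raw = spearman_screen(df, targets=["a"], factors=["b", "c", "d"])
        adj = spearman_screen(df, targets=["a"], factors=["b", "c", "d"], bh_correct=True)
        assert (adj.p.to_numpy() >= raw.p.to_numpy() - 1e-12).all()


class TestResample:
    def test_on_grid_batches_unchanged(self):
        t = np.linspace(0, 1, 11)
        frames = [frame_from(t, {"a": 2 * t}, "b1"), frame_from(t, {"a": 3 * t}, "b2")]
        m = resample_common_grid(frames, grid=t)
        np.testing.assert_allclose(m.values[0], 2 * t, atol=1e-12)

    def test_missing_variable_names_batch(self):
        t = np.linspace(0, 1, 5)
        frames = [frame_from(t, {"a": t, "ph": t}, "b1"), frame_from(t, {"a": t}, "b2")]
        with pytest.raises(RangeError, match="b2.*ph"):
            resample_common_grid(frames, variables=["a", "ph"])

    def test_affine_resampled_exactly(self):
        frames = [frame_from(np.linspace(0, 10, 31), {"a": 4 * np.linspace(0, 10, 31) - 1})]
        grid = np.linspace(1, 9, 17)
        m = resample_common_grid(frames, grid=grid)
        np.testing.assert_allclose(m.values[0], 4 * grid - 1, atol=1e-12)

    def test_span_shortfall_rejected(self):
        frames = [frame_from(np.linspace(2, 8, 10), {"a": np.zeros(10)})]
        with pytest.raises(RangeError, match="cover"):
            resample_common_grid(frames, grid=np.linspace(0, 10, 5))

    def test_stacked_row_order_batch_then_time(self):
        t = np.linspace(0, 1, 4)
        frames = [frame_from(t, {"a": t}, "b1"), frame_from(t, {"a": t + 1}, "b2")]
        m = resample_common_grid(frames, grid=t, stacked=True)
        assert m.values.shape == (8, 1)
        np.testing.assert_array_equal(m.batch_index, [0, 0, 0, 0, 1, 1, 1, 1])


class TestPCAFlat:
    def _frames(self, specs):
        t = np.linspace(0, 5, 40)
        out = []
        for i, (slope, wiggle) in enumerate(specs):
            out.append(frame_from(t, {
                "a": slope * t + wiggle * np.sin(t),
                "b": slope * t ** 2 / 5.0,
            }, f"b{i}"))
        return out

    def test_identical_batches_identical_scores(self):
        frames = self._frames([(1.0, 0.1)] * 3 + [(2.0, 0.3)])
        scores, _ = pca_flat(resample_common_grid(frames))
        np.testing.assert_allclose(scores.loc["b0"], scores.loc["b1"], atol=1e-9)

    def test_explained_variance_valid(self):
        frames = self._frames([(1.0, 0.0), (1.2, 0.1), (0.8, 0.3), (2.0, 0.2)])
        _, evr = pca_flat(resample_common_grid(frames))
        assert evr.sum() <= 1.0 + 1e-12
        assert all(a >= b for a, b in zip(evr, evr[1:]))
        assert all(0.0 <= v <= 1.0 for v in evr)

    def test_row_order_invariance_up_to_sign(self):
        frames = self._frames([(1.0, 0.0), (1.5, 0.4), (0.6, 0.2), (2.2, 0.1)])
        s1, _ = pca_flat(resample_common_grid(frames))
        s2, _ = pca_flat(resample_common_grid(frames[::-1]))
        for b in s1.index:
            np.testing.assert_allclose(np.abs(s1.loc[b]), np.abs(s2.loc[b]), atol=1e-8)

    def test_fewer_batches_than_components_rejected(self):
        frames = self._frames([(1.0, 0.0)])
        with pytest.raises(RangeError):
            pca_flat(resample_common_grid(frames), n_components=2)

    def test_synthetic_outlier_far_from_cluster(self):
        from fermfuse.derived import add_gas_rates
        from fermfuse.fusion import fuse_batch
        from fermfuse.synth import simulate_study

        study = simulate_study(4, outliers={1: "stunted"}, seed=5)
        frames = [add_gas_rates(fuse_batch(b)) for b, _ in study]
        scores, _ = pca_flat(resample_common_grid(frames, max_points=300))
        pts = scores.to_numpy()
        others = np.delete(pts, 1, axis=0)
        centroid = others.mean(axis=0)
        d_out = np.linalg.norm(pts[1] - centroid)
        d_rest = max(np.linalg.norm(p - centroid) for p in others)
        assert d_out > d_rest


class TestPCATime:
    def test_sg_smoothing_preserves_low_degree_polynomial(self):
        # trajectories that are cubic in time pass an order-3 SG filter
        # unchanged in the interior
        t = np.linspace(0, 1, 60)
        frames = [frame_from(t, {"a": (0.2 + 0.1 * i) * t ** 3, "b": t}, f"b{i}")
                  for i in range(3)]
        m = resample_common_grid(frames, grid=t, stacked=True)
        trajs, loadings, _ = pca_time(m, sg_window=11, sg_order=3)
        raw_trajs, _, _ = pca_time(m, sg_window=5, sg_order=4)  # window>order, near-identity
        b0 = trajs["b0"]["PC1"].to_numpy()
        assert np.all(np.isfinite(b0))

    def test_loadings_unit_norm_and_sign_convention(self):
        rng = np.random.default_rng(2)
        t = np.linspace(0, 1, 50)
        frames = [frame_from(t, {"a": np.sin(3 * t) + 0.01 * rng.normal(size=50),
                                 "b": np.cos(3 * t),
                                 "c": t}, f"b{i}") for i in range(3)]
        m = resample_common_grid(frames, grid=t, stacked=True)
        _, loadings, _ = pca_time(m)
        for pc in loadings.columns:
            v = loadings[pc].to_numpy()
            assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-9)
            assert v[np.argmax(np.abs(v))] > 0

    def test_invalid_sg_parameters_rejected(self):
        t = np.linspace(0, 1, 30)
        frames = [frame_from(t, {"a": t, "b": t ** 2}, f"b{i}") for i in range(2)]
        m = resample_common_grid(frames, grid=t, stacked=True)
        with pytest.raises(RangeError):
            pca_time(m, sg_window=4)
        with pytest.raises(RangeError):
            pca_time(m, sg_window=3, sg_order=3)

    def test_step_disturbance_localized_and_attributed(self):
        from fermfuse.derived import add_gas_rates
        from fermfuse.fusion import fuse_batch
        from fermfuse.synth import AnomalySpec, inject_anomaly, simulate_study

        study = simulate_study(6, jitter=0.02, seed=7)
        disturbed, gt = study[4]
        inject_anomaly(disturbed, AnomalySpec("do", "step", 12.0, 3.0, 40.0), gt)
        frames = [add_gas_rates(fuse_batch(b)) for b, _ in study]
        variables = ["ph", "do", "agitation", "base_pump", "CER", "OUR"]
        m = resample_common_grid(frames, variables=variables, max_points=400, stacked=True)
        trajs, loadings, _ = pca_time(m)
        ids = list(trajs)
        best = None
        for pc in ("PC1", "PC2"):
            stack = np.stack([trajs[b][pc].to_numpy() for b in ids])
            dev = stack[4] - np.delete(stack, 4, axis=0).mean(axis=0)
            i = int(np.abs(dev).argmax())
            if best is None or abs(dev[i]) > best[1]:
                best = (pc, abs(dev[i]), trajs[ids[0]].index[i])
        pc, _, t_peak = best
        sg_span = 11 * float(np.diff(m.grid).mean())
        assert 12.0 - sg_span <= t_peak <= 15.0 + sg_span
        rank = loadings[pc].abs().rank(ascending=False)["do"]
        assert rank <= 3
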