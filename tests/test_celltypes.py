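import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import ortho_group

from rgctyping.celltypes import (
    ds_polar_summary,
    fisher_separation,
    group_characteristics,
    normalize,
    preferred_direction,
    separation_matrix,
    silhouette_mean,
    sweep_k,
    tiling_report,
)


def frame_from(columns):
    df = pd.DataFrame(columns)
    df["cell_id"] = np.arange(len(df))
    return df


from tests_oracles import brute_force_silhouette_oracle as brute_force_silhouette


class TestNormalize:
    BASE = dict(bias_index=[-1.0, 0.0, 1.0], transience=[0.2, 0.5, 0.7],
                ds_index=[0.0, 0.3, 0.6], speed_index=[0.3, 0.5, 0.9])

    def test_latency_min_max_scaled(self):
        df = frame_from(dict(self.BASE, latency_s=[0.1, 0.3, 0.5]))
        m = normalize(df)
        j = m.columns.index("latency_s")
        assert m.values[:, j] == pytest.approx([0.0, 0.5, 1.0])
        assert m.scaling["latency_s"] == (0.1, 0.5)

    def test_intrinsic_columns_pass_through(self):
        df = frame_from(dict(self.BASE, latency_s=[0.1, 0.3, 0.5]))
        m = normalize(df)
        assert m.values[:, 0] == pytest.approx(self.BASE["bias_index"])

    def test_idempotence(self):
        df = frame_from(dict(self.BASE, latency_s=[0.1, 0.3, 0.5]))
        once = normalize(df)
        renamed = pd.DataFrame(once.values, columns=once.columns)
        renamed["cell_id"] = np.arange(len(renamed))
        twice = normalize(renamed)
        assert np.allclose(once.values, twice.values)

    def test_constant_column_warns(self):
        df = frame_from(dict(self.BASE, latency_s=[0.2, 0.2, 0.2]))
        with pytest.warns(UserWarning, match="constant"):
            m = normalize(df)
        assert np.all(m.values[:, m.columns.index("latency_s")] == 0.0)

    def test_missing_values_rejected(self):
        df = frame_from(dict(self.BASE, latency_s=[0.1, np.nan, 0.5]))
        with pytest.raises(ValueError, match="missing"):
            normalize(df)


class TestSilhouette:
    def test_two_tight_far_pairs(self):
        X = np.array([[0, 0], [0.01, 0], [10, 10], [10.01, 10]])
        assert silhouette_mean(X, np.array([0, 0, 1, 1])) > 0.95

    def test_random_labels_on_homogeneous_cloud(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (500, 5))
        labels = rng.integers(0, 3, 500)
        assert abs(silhouette_mean(X, labels)) < 0.1

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            silhouette_mean(np.zeros((4, 2)), np.zeros(4, dtype=int))

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(6, 50)
        k = rng.integers(2, 5)
        X = rng.normal(0, 1, (n, 3))
        labels = rng.integers(0, k, n)
        if len(np.unique(labels)) < 2:
            return
        assert silhouette_mean(X, labels) == pytest.approx(
            brute_force_silhouette(X, labels), abs=1e-12)


class TestSweepK:
    def _blobs(self, k=3, n=40, seed=0):
        rng = np.random.default_rng(seed)
        centers = rng.uniform(-10, 10, (k, 4))
        X = np.concatenate([c + rng.normal(0, 0.3, (n, 4)) for c in centers])
        return X

    def test_planted_blob_count_recovered(self):
        X = self._blobs(3)
        from rgctyping.celltypes import ParameterMatrix
        m = ParameterMatrix(X, ("a", "b", "c", "d"),
                            np.arange(len(X)), {})
        model = sweep_k(m, range(2, 7), restarts=20, seed=0)
        assert model.k == 3
        assert len(np.unique(model.labels)) == 3
        assert model.labels.min() == 1

    def test_more_restarts_never_worse(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (120, 5))  # hard unstructured instance
        from sklearn.cluster import KMeans
        one = KMeans(8, n_init=1, random_state=0).fit(X).inertia_
        many = KMeans(8, n_init=200, random_state=0).fit(X).inertia_
        assert many <= one + 1e-9

    def test_infeasible_k_skipped_with_warning(self):
        from rgctyping.celltypes import ParameterMatrix
        X = self._blobs(2, n=4, seed=1)
        m = ParameterMatrix(X, ("a", "b", "c", "d"), np.arange(len(X)), {})
        with pytest.warns(UserWarning, match="skipping k="):
            model = sweep_k(m, range(2, 30), restarts=5, seed=0)
        assert model.k == 2


class TestFisherSeparation:
    def test_two_unit_sd_groups_four_apart(self):
        X = np.array([[-1.0], [0.0], [1.0], [3.0], [4.0], [5.0]])
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert fisher_separation(X, labels, (0, 1)) == pytest.approx(4.0)

    def test_identical_groups_zero(self):
        X = np.vstack([np.eye(3), np.eye(3)])
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert fisher_separation(X, labels, (0, 1)) == pytest.approx(0.0)

    def test_sampled_gaussians_three_sigma_apart(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, (200, 5))
        b = rng.normal(0, 1, (200, 5))
        b[:, 0] += 3.0
        X = np.vstack([a, b])
        labels = np.repeat([0, 1], 200)
        assert fisher_separation(X, labels, (0, 1)) == pytest.approx(3.0, rel=0.1)

    def test_symmetry_and_rigid_motion_invariance(self):
        rng = np.random.default_rng(11)
        X = rng.normal(0, 1, (60, 5))
        X[30:] += 2.5
        labels = np.repeat([0, 1], 30)
        s = fisher_separation(X, labels, (0, 1))
        assert fisher_separation(X, labels, (1, 0)) == pytest.approx(s)
        R = ortho_group.rvs(5, random_state=3)
        moved = X @ R + np.array([5, -2, 1, 0, 9.0])
        assert fisher_separation(moved, labels, (0, 1)) == pytest.approx(s)

    def test_zero_spread_capped(self):
        X = np.vstack([np.zeros((3, 2)), np.ones((3, 2))])
        labels = np.repeat([0, 1], 3)
        assert fisher_separation(X, labels, (0, 1)) == pytest.approx(1e6)

    def test_separation_matrix_symmetric(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (90, 5))
        X[30:60] += 3
        X[60:] -= 3
        from rgctyping.celltypes import ParameterMatrix
        m = ParameterMatrix(X, tuple("abcde"), np.arange(90), {})
        labels = np.repeat([1, 2, 3], 30)
        sep = separation_matrix(m, labels)
        assert np.allclose(sep.values, sep.values.T)
        assert np.all(np.diag(sep.values) == 0)


class TestGroupCharacteristics:
    def _frame(self):
        rows = []
        for i in range(10):  # ON DS cluster
            rows.append(dict(bias_index=0.9, latency_s=0.1, transience=0.2,
                             rf_diameter_um=250.0, ds_index=0.6,
                             speed_index=0.3, width_index=0.5))
        for i in range(10):  # OFF cluster
            rows.append(dict(bias_index=-0.9, latency_s=0.4, transience=0.6,
                             rf_diameter_um=280.0, ds_index=0.05,
                             speed_index=0.5, width_index=0.5))
        df = pd.DataFrame(rows)
        df["cell_id"] = np.arange(len(df))
        return df, np.repeat([1, 2], 10)

    def test_planted_labels(self):
        df, labels = self._frame()
        chars = group_characteristics(df, labels)
        on_ds = chars.loc[chars["cluster"] == 1, "suggested_label"].item()
        off = chars.loc[chars["cluster"] == 2, "suggested_label"].item()
        assert "ON" in on_ds and "DS" in on_ds
        assert off.startswith("OFF") and "DS" not in off

    def test_labels_invariant_to_monotone_latency_rescale(self):
        df, labels = self._frame()
        before = group_characteristics(df, labels)["suggested_label"]
        df2 = df.copy()
        df2["latency_s"] = np.exp(df2["latency_s"])
        after = group_characteristics(df2, labels)["suggested_label"]
        assert list(before) == list(after)


class TestTiling:
    def test_dense_cluster_covers_region(self):
        xs, ys = np.meshgrid(np.arange(5) * 50.0, np.arange(3) * 50.0)
        centers = np.column_stack([xs.ravel() + 300, ys.ravel() + 450])
        labels = np.zeros(len(centers), dtype=int)
        rep = tiling_report(labels, centers, np.full(len(centers), 120.0),
                            region=(300.0, 450.0, 500.0, 550.0))
        assert rep["coverage"].item() > 0.95
        assert rep["overlap_defined"].item()

    def test_disjoint_rfs_no_overlap(self):
        centers = np.array([[100.0, 100.0], [400.0, 100.0]])
        rep = tiling_report(np.zeros(2, dtype=int), centers,
                            np.array([100.0, 100.0]),
                            region=(0.0, 0.0, 500.0, 200.0))
        assert rep["mean_pairwise_iou"].item() == 0.0

    def test_single_cell_flagged(self):
        rep = tiling_report(np.zeros(1, dtype=int), np.array([[50.0, 50.0]]),
                            np.array([100.0]), region=(0.0, 0.0, 100.0, 100.0))
        assert not rep["overlap_defined"].item()
        assert rep["mean_pairwise_iou"].item() == 0.0


class TestDSPolarSummary:
    def _directions(self, modes, n_per=30, jitter=5.0, seed=0):
        rng = np.random.default_rng(seed)
        return np.concatenate([
            (m + rng.normal(0, jitter, n_per)) % 360 for m in modes])

    def test_three_lobed(self):
        out = ds_polar_summary(self._directions([0, 120, 240]))
        assert out["mode_count"] == 3

    def test_four_lobed(self):
        out = ds_polar_summary(self._directions([45, 135, 225, 315]))
        assert out["mode_count"] == 4

    def test_uniform_flagged_inconclusive(self):
        out = ds_polar_summary(np.arange(0, 360, 1.0))
        assert out["inconclusive"]
        assert out["mode_count"] == 0

    def test_preferred_direction_circular_mean(self):
        rates = np.zeros(8)
        rates[2] = 5.0  # 90 degrees
        assert preferred_direction(rates, np.arange(8) * 45.0) == pytest.approx(90.0)
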