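import numpy as np
import pytest

from gradmosaic import (
    assign_area_labels,
    bh_reject,
    extreme_area_test,
    global_strength,
    hierarchy_ttests,
    make_smooth_field,
    participation_coefficient,
    spin_nulls,
    spin_spearman,
)
from gradmosaic.inference import SpinNullStore, _pooled_t


@pytest.fixture(scope="module")
def labeling(atlas):
    return assign_area_labels(atlas)


def _area_map(field, labeling):
    return np.array(
        [field[labeling.label == a].mean() for a in labeling.area_ids]
    )


class TestSpinNulls:
    def test_identity_rotation_reproduces_observed(self, mesh, labeling):
        field = make_smooth_field(mesh, 40.0, seed=5)
        obs = _area_map(field, labeling)
        store = spin_nulls(obs, labeling, mesh, n_perm=3, seed=0,
                           include_identity=True)
        assert np.allclose(store.null_values[0], obs, atol=1e-12)

    def test_rotation_preserves_vertex_value_multiset(self, mesh):
        # one area per vertex: aggregation is the identity, so each null row
        # must be a permutation-with-replacement drawn from the projected map
        field = make_smooth_field(mesh, 40.0, seed=6)
        from gradmosaic import AreaLabeling
        ids = np.arange(1, mesh.n_vertices + 1)
        lab = AreaLabeling(label=ids.copy(), area_ids=ids)
        lab.label[mesh.midwall_mask] = -1
        store = spin_nulls(field[:], lab, mesh, n_perm=2, seed=1)
        observed_vals = set(np.round(field[mesh.cortex_mask], 12))
        for row in store.null_values:
            row_vals = set(np.round(row[np.isfinite(row)], 12))
            assert row_vals <= set(np.round(field, 12))
        # rotated values come from the full vertex map (midwall excluded
        # only at aggregation), and most cortical values should re-occur
        assert len(row_vals) > 0.5 * len(observed_vals)

    def test_null_mean_close_to_spatial_mean(self, mesh, labeling):
        field = make_smooth_field(mesh, 60.0, seed=7)
        obs = _area_map(field, labeling)
        store = spin_nulls(obs, labeling, mesh, n_perm=300, seed=2)
        grand = store.null_values.mean()
        se = store.null_values.mean(axis=1).std(ddof=1) / np.sqrt(300)
        assert abs(grand - obs.mean()) < 3 * se + 0.05

    def test_seeded_determinism(self, mesh, labeling):
        obs = np.linspace(0, 1, len(labeling.area_ids))
        a = spin_nulls(obs, labeling, mesh, n_perm=10, seed=42)
        b = spin_nulls(obs, labeling, mesh, n_perm=10, seed=42)
        assert np.array_equal(a.null_values, b.null_values)

    def test_label_rotation_variant_runs(self, mesh, labeling):
        obs = np.linspace(0, 1, len(labeling.area_ids))
        store = spin_nulls(obs, labeling, mesh, n_perm=5, seed=3,
                           rotate_labels=True)
        assert store.null_values.shape == (5, len(labeling.area_ids))


class TestExtremeAreaTest:
    def _store(self, nulls):
        nulls = np.asarray(nulls, float)
        return SpinNullStore(null_values=nulls,
                             area_ids=np.arange(1, nulls.shape[1] + 1),
                             rotations_seed=0, n_perm=nulls.shape[0])

    def test_observation_above_all_nulls(self, rng):
        nulls = rng.uniform(0, 1, (1000, 3))
        obs = np.array([2.0, 0.5, 0.5])
        res = extreme_area_test(obs, self._store(nulls))
        assert res["p_two_sided"][0] == pytest.approx(2 / 1001)
        assert res["flag_high"][0]

    def test_observation_at_null_median_not_flagged(self, rng):
        nulls = rng.standard_normal((999, 4))
        obs = np.median(nulls, axis=0)
        res = extreme_area_test(obs, self._store(nulls))
        assert (res["p_two_sided"] > 0.9).all()
        assert not res["flag_high"].any() and not res["flag_low"].any()

    def test_bh_step_up_arithmetic(self):
        assert bh_reject(np.array([0.001, 0.02, 0.8]), q=0.05).sum() == 2


class TestSpinSpearman:
    def _null_store(self, rng, n_perm, n_areas):
        return SpinNullStore(null_values=rng.standard_normal((n_perm, n_areas)),
                             area_ids=np.arange(1, n_areas + 1),
                             rotations_seed=0, n_perm=n_perm)

    def test_perfect_correlation(self, rng):
        x = rng.standard_normal(30)
        rho, p = spin_spearman(x, x.copy(), self._null_store(rng, 50, 30))
        assert rho == pytest.approx(1.0)
        assert 0 < p <= 1

    def test_partialling_on_itself_kills_correlation(self, rng):
        x = rng.standard_normal(40)
        y = 2 * x + rng.standard_normal(40)
        rho, _ = spin_spearman(x, y, self._null_store(rng, 20, 40),
                               covariate=x)
        assert abs(rho) < 1e-8

    def test_constant_vector_rejected(self, rng):
        with pytest.raises(ValueError):
            spin_spearman(np.ones(10), rng.standard_normal(10),
                          self._null_store(rng, 5, 10))


class TestHierarchyTTests:
    LEVELS = ("idiotypic", "unimodal", "heteromodal", "paralimbic")

    def _labels(self, sizes):
        return np.concatenate(
            [np.full(s, lv) for s, lv in zip(sizes, self.LEVELS)]
        )

    def test_pooled_t_hand_arithmetic(self):
        t, diff, sp, df = _pooled_t(np.array([1.0, 2, 3]), np.array([2.0, 3, 4]))
        assert diff == pytest.approx(-1.0)
        assert sp == pytest.approx(1.0)
        assert t == pytest.approx(-np.sqrt(1.5))

    def test_identical_groups_give_zero_contrast(self, rng):
        labels = self._labels([3, 3, 3, 3])
        values = np.tile([1.0, 2.0, 3.0], 4)
        nulls = SpinNullStore(
            null_values=rng.standard_normal((30, 12)),
            area_ids=np.arange(12), rotations_seed=0, n_perm=30,
        )
        res = hierarchy_ttests(values, labels, nulls)
        row = res[(res.level_a == "idiotypic") & (res.level_b == "unimodal")]
        assert row["t"].iloc[0] == pytest.approx(0.0)
        assert row["cohens_d"].iloc[0] == pytest.approx(0.0)
        assert row["ci_low"].iloc[0] < 0 < row["ci_high"].iloc[0]

    def test_specific_pair_matches_hand_example(self, rng):
        labels = self._labels([3, 3, 3, 3])
        values = np.array([1.0, 2, 3, 2, 3, 4, 10, 11, 12, 20, 21, 22])
        nulls = SpinNullStore(
            null_values=rng.standard_normal((30, 12)),
            area_ids=np.arange(12), rotations_seed=0, n_perm=30,
        )
        res = hierarchy_ttests(values, labels, nulls)
        row = res[(res.level_a == "idiotypic") & (res.level_b == "unimodal")]
        assert row["t"].iloc[0] == pytest.approx(-np.sqrt(1.5))
        assert row["cohens_d"].iloc[0] == pytest.approx(-1.0)

    def test_monotone_level_means_recover_planted_signs(self, rng):
        sizes = [6, 6, 6, 6]
        labels = self._labels(sizes)
        means = {lv: m for lv, m in zip(self.LEVELS, [0.0, 1.0, 2.0, 3.0])}
        values = np.concatenate(
            [means[lv] + 0.1 * rng.standard_normal(6) for lv in self.LEVELS]
        )
        nulls = SpinNullStore(
            null_values=rng.standard_normal((50, 24)),
            area_ids=np.arange(24), rotations_seed=0, n_perm=50,
        )
        res = hierarchy_ttests(values, labels, nulls)
        # level order in each pair follows the sensory-fugal ordering, so
        # every lower-level mean is below the higher-level mean
        assert (res["t"] < 0).all()


class TestGraphMetrics:
    def test_participation_closed_forms(self):
        w = np.zeros((5, 5))
        w[0, 1] = w[1, 0] = 1.0           # node 0: all strength in community A
        comm = np.array(["a", "a", "b", "c", "d"])
        assert participation_coefficient(w, comm)[0] == pytest.approx(0.0)
        w2 = np.zeros((5, 5))
        w2[0, 1:5] = 1.0                  # equal split across 4 communities
        comm2 = np.array(["x", "a", "b", "c", "d"])
        assert participation_coefficient(w2, comm2)[0] == pytest.approx(0.75)

    def test_participation_matches_loop_oracle(self, rng):
        w = np.abs(rng.standard_normal((20, 20)))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        comm = rng.choice(list("abcd"), 20)
        got = participation_coefficient(w, comm)
        for i in range(20):
            k = w[i].sum()
            acc = sum(
                (w[i, comm == s].sum() / k) ** 2 for s in np.unique(comm)
            )
            assert abs(got[i] - (1 - acc)) < 1e-12

    def test_zero_strength_node_gets_zero(self):
        w = np.zeros((3, 3))
        pc = participation_coefficient(w, np.array(["a", "b", "c"]))
        assert np.allclose(pc, 0.0)

    def test_global_strength(self, rng):
        n = 15
        w = np.full((n, n), 0.7)
        np.fill_diagonal(w, 0)
        assert np.allclose(global_strength(w), 0.7)
        assert np.allclose(global_strength(np.zeros((4, 4))), 0.0)
        w = rng.standard_normal((n, n))
        got = global_strength(w)
        for i in range(n):
            want = (w[i].sum() - w[i, i]) / (n - 1)
            assert abs(got[i] - want) < 1e-12
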