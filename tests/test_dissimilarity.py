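import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

from gradmosaic import (
    AreaLabeling,
    MultimodalGradients,
    cluster_areas,
    cosine_distance,
    inter_areal_dissimilarity,
    intra_areal_dissimilarity,
    similarity_affinity,
)
from gradmosaic.arealization import GradientProfileMatrix


def _pm(x):
    x = np.asarray(x, float)
    return GradientProfileMatrix(
        profiles=x, area_ids=np.arange(1, len(x) + 1),
        k_per_modality=3, column_names=[f"c{i}" for i in range(x.shape[1])],
    )


class TestCosineDistance:
    def test_closed_forms(self):
        assert cosine_distance([1, 2, 3], [1, 2, 3]) == pytest.approx(0.0)
        assert cosine_distance([1, 0], [0, 1]) == pytest.approx(1.0)
        assert cosine_distance([1, 1], [1, 0]) == pytest.approx(
            1 - 1 / np.sqrt(2), abs=1e-12
        )
        assert cosine_distance([1, 0], [-1, 0]) == pytest.approx(2.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_distance([0, 0], [1, 0])

    @given(st.floats(0.1, 100.0))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, c):
        a = np.array([0.3, -1.2, 0.7])
        b = np.array([1.1, 0.4, -0.2])
        assert cosine_distance(c * a, b) == pytest.approx(
            cosine_distance(a, b), abs=1e-12
        )


class TestInterAreal:
    def test_identical_profiles_zero(self):
        res = inter_areal_dissimilarity(_pm(np.tile([1.0, 2, 3], (4, 1))))
        assert np.allclose(res.per_area, 0.0)
        assert np.allclose(res.matrix, 0.0)

    def test_orthonormal_basis_example(self):
        e1 = [1.0, 0, 0]
        e2 = [0.0, 1, 0]
        res = inter_areal_dissimilarity(_pm([e1, e1, e2]))
        assert np.allclose(res.per_area, [0.5, 0.5, 1.0])

    def test_matches_double_loop_oracle(self, rng):
        x = rng.standard_normal((20, 7))
        res = inter_areal_dissimilarity(_pm(x))
        n = 20
        for i in range(n):
            vals = [
                cosine_distance(x[i], x[j]) for j in range(n) if j != i
            ]
            assert abs(res.per_area[i] - np.mean(vals)) < 1e-12

    def test_zero_profile_names_area(self):
        x = np.ones((3, 4))
        x[1] = 0.0
        with pytest.raises(ValueError, match="2"):
            inter_areal_dissimilarity(_pm(x))


class TestIntraAreal:
    def _mm(self, vals, k=2):
        vals = np.asarray(vals, float)
        scaled = vals / np.abs(vals).max(axis=0, keepdims=True)
        return MultimodalGradients(values=scaled, k_per_modality=k)

    def test_homogeneous_area_is_zero(self):
        mm = MultimodalGradients(values=np.ones((5, 6)), k_per_modality=2)
        lab = AreaLabeling(label=np.full(5, 1), area_ids=np.array([1]))
        res = intra_areal_dissimilarity(mm, lab)
        assert np.allclose(res.per_vertex, 0.0, atol=1e-12)

    def test_two_vertex_closed_form(self):
        vals = np.array([[1.0, 0], [0, 1.0]])
        mm = MultimodalGradients(
            values=np.hstack([vals, vals, vals]), k_per_modality=2
        )
        lab = AreaLabeling(label=np.array([1, 1]), area_ids=np.array([1]))
        res = intra_areal_dissimilarity(mm, lab)
        assert np.allclose(res.per_vertex, 1 - 1 / np.sqrt(2), atol=1e-12)

    def test_singleton_area_flagged_zero(self, rng):
        vals = rng.standard_normal((5, 6))
        mm = self._mm(vals)
        lab = AreaLabeling(
            label=np.array([1, 1, 1, 1, 2]), area_ids=np.array([1, 2])
        )
        res = intra_areal_dissimilarity(mm, lab)
        assert res.singleton_areas == [2]
        assert res.per_vertex[4] == pytest.approx(0.0)

    def test_size_adjustment_has_zero_rank_correlation_with_size(self, rng):
        from scipy.stats import spearmanr
        vals = rng.standard_normal((200, 6))
        label = np.repeat(np.arange(1, 11), [5, 10, 15, 20, 25, 25, 20, 30, 30, 20])
        mm = self._mm(vals)
        lab = AreaLabeling(label=label, area_ids=np.arange(1, 11))
        res = intra_areal_dissimilarity(mm, lab)
        sizes = [lab.area_sizes[int(a)] for a in res.area_ids]
        rho = spearmanr(res.per_area_size_adjusted, sizes).statistic
        assert abs(rho) < 0.35  # rank-regression removes the size trend


class TestSimilarityAndClustering:
    def test_similarity_closed_forms(self):
        x = np.array([[1.0, 0], [2.0, 0], [0, 1.0], [-1.0, 0]])
        s = similarity_affinity(_pm(x))
        assert s[0, 1] == pytest.approx(1.0)
        assert s[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert s[0, 3] == pytest.approx(-1.0)
        assert np.allclose(np.diag(s), 1.0)

    def _block_profiles(self, rng, n_blocks, per_block):
        centers = np.eye(n_blocks)
        rows, truth = [], []
        for b in range(n_blocks):
            for _ in range(per_block):
                rows.append(centers[b] + 0.02 * rng.standard_normal(n_blocks))
                truth.append(b)
        return np.array(rows), np.array(truth)

    def test_two_planted_blocks_recovered(self, rng):
        x, truth = self._block_profiles(rng, 2, 8)
        labels, k, _ = cluster_areas(similarity_affinity(_pm(x)), 2, 6)
        assert k == 2
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_four_planted_blocks_recovered(self, rng):
        x, truth = self._block_profiles(rng, 4, 6)
        labels, k, _ = cluster_areas(similarity_affinity(_pm(x)), 2, 8)
        assert k == 4
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_flat_criterion_ties_resolve_to_k_min(self):
        n = 8
        s = np.full((n, n), 0.4)
        np.fill_diagonal(s, 1.0)
        _, k, crit = cluster_areas(s, 2, 5)
        assert k == 2
        assert len(set(np.round(list(crit.values()), 12))) == 1

    def test_labels_invariant_to_area_reordering(self, rng):
        x, _ = self._block_profiles(rng, 3, 7)
        s = similarity_affinity(_pm(x))
        perm = rng.permutation(len(x))
        labels1, _, _ = cluster_areas(s, 2, 6)
        labels2, _, _ = cluster_areas(s[np.ix_(perm, perm)], 2, 6)
        assert adjusted_rand_score(labels1[perm], labels2) == 1.0
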