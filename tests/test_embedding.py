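import numpy as np
import pytest
from scipy import linalg

from gradmosaic import (
    AffinityMatrix,
    Connectome,
    GradientSet,
    diffusion_map,
    group_template,
    normalize_and_stack,
    procrustes_align,
)


def dense_diffusion_oracle(w, n_components, alpha):
    """Full nonsymmetric eigendecomposition of the diffusion operator —
    an independent route to the same embedding."""
    d = w.sum(axis=1)
    w1 = w / np.outer(d**alpha, d**alpha)
    m = w1 / w1.sum(axis=1, keepdims=True)
    evals, evecs = linalg.eig(m)
    evals, evecs = evals.real, evecs.real
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    lam = np.clip(evals[1 : n_components + 1], None, 1 - 1e-9)
    comps = evecs[:, 1 : n_components + 1]
    comps = comps / np.linalg.norm(comps, axis=0, keepdims=True)
    return comps * (lam / (1 - lam))


def random_affinity(rng, n):
    w = rng.uniform(0, 1, (n, n))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 1.0)
    return AffinityMatrix(values=w, source_modality="FC")


class TestDiffusionMap:
    def test_matches_dense_oracle(self, rng):
        for _ in range(3):
            aff = random_affinity(rng, 100)
            got = diffusion_map(aff, n_components=6, alpha=0.5)
            want = dense_diffusion_oracle(aff.values, 6, 0.5)
            for j in range(6):
                r = np.corrcoef(got.components[:, j], want[:, j])[0, 1]
                assert abs(r) > 0.999

    def test_two_block_affinity_separated_by_sign(self):
        n = 40
        w = np.full((n, n), 0.01)
        w[:20, :20] = 1.0
        w[20:, 20:] = 1.0
        aff = AffinityMatrix(values=w, source_modality="SC")
        g1 = diffusion_map(aff, n_components=3).components[:, 0]
        assert len(np.unique(np.sign(g1[:20]))) == 1
        assert len(np.unique(np.sign(g1[20:]))) == 1
        assert np.sign(g1[0]) != np.sign(g1[-1])

    def test_disconnected_graph_reports_component_sizes(self):
        w = np.zeros((10, 10))
        w[:6, :6] = 1.0
        w[6:, 6:] = 1.0
        aff = AffinityMatrix(values=w, source_modality="FC")
        with pytest.raises(ValueError, match=r"\[6, 4\]"):
            diffusion_map(aff, n_components=2)

    def test_deterministic_sign_convention(self, rng):
        aff = random_affinity(rng, 60)
        a = diffusion_map(aff, n_components=4)
        b = diffusion_map(aff, n_components=4)
        assert np.array_equal(a.components, b.components)
        for j in range(4):
            i = np.argmax(np.abs(a.components[:, j]))
            assert a.components[i, j] > 0

    def test_eigenvalues_nonincreasing(self, rng):
        g = diffusion_map(random_affinity(rng, 80), n_components=5)
        assert np.all(np.diff(g.eigenvalues) <= 1e-12)


class TestProcrustes:
    def _gs(self, comps):
        k = comps.shape[1]
        return GradientSet(components=comps, eigenvalues=np.linspace(1, 0.5, k),
                           modality="FC", alpha=0.5)

    def test_self_alignment_residual_zero(self, rng):
        g = self._gs(rng.standard_normal((30, 4)))
        out = procrustes_align(g, g)
        assert np.abs(out.components - g.components).max() < 1e-9

    def test_planted_rotation_recovered(self, rng):
        ref = rng.standard_normal((25, 5))
        q, _ = np.linalg.qr(rng.standard_normal((5, 5)))
        src = (ref - ref.mean(axis=0)) @ q + ref.mean(axis=0)
        out = procrustes_align(self._gs(src), self._gs(ref))
        assert np.abs(out.components - ref).max() < 1e-9

    def test_never_increases_distance(self, rng):
        for _ in range(20):
            ref = rng.standard_normal((20, 3))
            src = rng.standard_normal((20, 3))
            aligned = procrustes_align(self._gs(src), self._gs(ref)).components
            ref_c = ref - ref.mean(axis=0)
            src_c = src - src.mean(axis=0)
            before = np.linalg.norm(src_c - ref_c)
            after = np.linalg.norm((aligned - ref.mean(axis=0)) - ref_c)
            assert after <= before + 1e-9

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            procrustes_align(
                self._gs(rng.standard_normal((10, 3))),
                self._gs(rng.standard_normal((10, 4))),
            )


class TestNormalizeAndStack:
    def _sets(self, rng, n=20, k=6):
        return [
            GradientSet(components=rng.standard_normal((n, k)),
                        eigenvalues=np.linspace(1, 0.1, k), modality=m,
                        alpha=0.5)
            for m in ("MPC", "SC", "FC")
        ]

    def test_column_normalization_rule(self, rng):
        sets = self._sets(rng)
        sets[0].components[:, 0] = 0.0
        sets[0].components[0, 0] = -2.0
        sets[0].components[1, 0] = 1.0
        mm = normalize_and_stack(sets, k_per_modality=3)
        assert mm.values[0, 0] == -1.0
        assert mm.values[1, 0] == 0.5

    def test_default_k_gives_15_columns(self, rng):
        mm = normalize_and_stack(self._sets(rng))
        assert mm.values.shape[1] == 15
        assert mm.column_names[:2] == ["MPC_G1", "MPC_G2"]
        assert mm.column_names[-1] == "FC_G5"

    def test_every_column_max_abs_is_one(self, rng):
        mm = normalize_and_stack(self._sets(rng), k_per_modality=4)
        assert np.allclose(np.abs(mm.values).max(axis=0), 1.0, atol=1e-9)

    def test_k_out_of_range(self, rng):
        with pytest.raises(ValueError):
            normalize_and_stack(self._sets(rng), k_per_modality=2)
        with pytest.raises(ValueError):
            normalize_and_stack(self._sets(rng), k_per_modality=8)


class TestSplitHemisphereEmbedding:
    def test_split_mode_recovers_planted_axis(self, mesh, dataset_high_snr):
        from scipy.stats import spearmanr
        from gradmosaic import build_mpc, split_hemisphere_embedding

        conn = build_mpc(dataset_high_snr.profiles)
        g = split_hemisphere_embedding(conn, mesh.hemisphere)
        # the planted fields of the two hemispheres are independent, so the
        # Procrustes alignment may rotate the right hemisphere's axis within
        # the leading components; the axis must survive in that subspace
        for h in ("left", "right"):
            idx = mesh.hemi_indices(h)
            idx = idx[mesh.cortex_mask[idx]]
            rhos = [
                abs(
                    spearmanr(
                        g.components[idx, j], dataset_high_snr.planted[idx, 0]
                    ).statistic
                )
                for j in range(3)
            ]
            assert max(rhos) > 0.8, (h, rhos)

    def test_rejects_single_hemisphere(self, rng):
        from gradmosaic import Connectome, split_hemisphere_embedding

        w = np.abs(rng.standard_normal((20, 20)))
        with pytest.raises(ValueError, match="two hemisphere"):
            split_hemisphere_embedding(
                Connectome(weights=w, modality="FC"), np.full(20, "left")
            )


class TestGroupTemplate:
    def test_single_subject_equals_own_embedding(self, rng):
        w = np.abs(rng.standard_normal((50, 50)))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        conn = Connectome(weights=w, modality="FC")
        t = group_template([conn], n_components=4)
        from gradmosaic.pipeline import embed_modality
        own = embed_modality(conn, 0.10, 4, 0.5)
        assert np.allclose(t.components, own.components, atol=1e-9)

    def test_identical_subjects_match_single(self, rng):
        w = np.abs(rng.standard_normal((40, 40)))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        conns = [Connectome(weights=w.copy(), modality="SC") for _ in range(3)]
        t3 = group_template(conns, n_components=3)
        t1 = group_template(conns[:1], n_components=3)
        assert np.allclose(t3.components, t1.components, atol=1e-9)
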