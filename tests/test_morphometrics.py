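import numpy as np
import pytest

from shellprint import morphometrics as mm


def _random_landmarks(n, seed, scale=100.0):
    rng = np.random.default_rng(seed)
    return rng.uniform(0, scale, size=(n, 2))


class TestTPSWarp:
    def test_identity_when_landmarks_match(self):
        lm = _random_landmarks(8, 0)
        pts = _random_landmarks(30, 1)
        out = mm.tps_warp(lm, lm, pts)
        assert np.allclose(out, pts, atol=1e-8)

    def test_affine_landmarks_give_affine_warp(self):
        lm = _random_landmarks(10, 2)
        A = np.array([[1.2, 0.3], [-0.1, 0.9]])
        t = np.array([4.0, -2.0])
        pts = _random_landmarks(25, 3)
        out = mm.tps_warp(lm, lm @ A.T + t, pts)
        assert np.allclose(out, pts @ A.T + t, atol=1e-6)

    def test_exact_at_landmarks_under_nonlinear_deformation(self):
        lm = _random_landmarks(20, 4)
        rng = np.random.default_rng(5)
        target = lm + rng.normal(0, 3.0, size=lm.shape)
        out = mm.tps_warp(lm, target, lm)
        assert np.allclose(out, target, atol=1e-9)

    def test_collinear_landmarks_rejected(self):
        lm = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        with pytest.raises(ValueError):
            mm.tps_warp(lm, lm, lm)


class TestCorrespondSurfaceSemis:
    def test_self_correspondence(self):
        anchors = _random_landmarks(10, 6)
        surface = _random_landmarks(40, 7)
        snapped, idx = mm.correspond_surface_semis(anchors, surface, anchors, surface)
        assert np.allclose(snapped, surface)
        assert list(idx) == list(range(40))

    def test_affine_target_recovers_true_correspondence(self):
        anchors = _random_landmarks(10, 8)
        surface = _random_landmarks(50, 9)
        A = np.array([[1.1, 0.1], [-0.2, 0.95]])
        t = np.array([3.0, 8.0])
        snapped, idx = mm.correspond_surface_semis(
            anchors, surface, anchors @ A.T + t, surface @ A.T + t
        )
        assert list(idx) == list(range(50))

    def test_single_point(self):
        anchors = _random_landmarks(5, 10)
        surface = anchors[:1] + 0.5
        targets = np.array([[0.0, 0.0], [50.0, 50.0]])
        snapped, idx = mm.correspond_surface_semis(anchors, surface, anchors, targets)
        assert snapped.shape == (1, 2)

    def test_no_structures_rejected(self):
        anchors = _random_landmarks(5, 11)
        with pytest.raises(ValueError):
            mm.correspond_surface_semis(anchors, anchors, anchors, np.zeros((0, 2)))


def _rigid(points, angle, scale, trans):
    a = np.radians(angle)
    R = scale * np.array([[np.cos(a), np.sin(a)], [-np.sin(a), np.cos(a)]])
    return points @ R.T + trans


class TestProcrustes:
    def test_identical_shapes_under_similarity_transforms(self):
        base = _random_landmarks(12, 12)
        specs = [
            base,
            _rigid(base, 30.0, 2.0, [5.0, 5.0]),
            _rigid(base, -70.0, 0.5, [-3.0, 10.0]),
        ]
        coords = mm.procrustes_align(specs)
        for i in range(1, 3):
            assert np.allclose(coords.aligned[i], coords.aligned[0], atol=1e-6)

    def test_unit_centroid_size_and_zero_centroid(self):
        specs = [_random_landmarks(10, s) for s in range(5)]
        coords = mm.procrustes_align(specs)
        for cfg in coords.aligned:
            assert np.allclose(cfg.mean(axis=0), 0.0, atol=1e-9)
            assert np.isclose(np.sqrt((cfg**2).sum()), 1.0, atol=1e-9)

    def test_consensus_converges_to_base_shape(self):
        # shapes perturbed isotropically around one base: the consensus
        # approaches the (normalized) base at the Monte Carlo rate
        base = _random_landmarks(20, 13)
        eps = 0.5
        rng = np.random.default_rng(14)
        specs = [base + rng.normal(0, eps, base.shape) for _ in range(40)]
        coords = mm.procrustes_align(specs)
        base_n = (base - base.mean(0)) / np.sqrt(((base - base.mean(0)) ** 2).sum())
        # align the consensus onto the normalized base before comparing
        from scipy.linalg import orthogonal_procrustes

        R, _ = orthogonal_procrustes(coords.consensus, base_n)
        err = np.linalg.norm(coords.consensus @ R - base_n)
        base_size = np.sqrt(((base - base.mean(0)) ** 2).sum())
        assert err <= 3 * eps / base_size

    def test_order_invariance(self):
        specs = [_random_landmarks(8, s) for s in range(6)]
        c1 = mm.procrustes_align(specs)
        c2 = mm.procrustes_align(specs[::-1])
        # consensus agrees up to rotation
        from scipy.linalg import orthogonal_procrustes

        R, _ = orthogonal_procrustes(c2.consensus, c1.consensus)
        assert np.allclose(c2.consensus @ R, c1.consensus, atol=1e-6)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            mm.procrustes_align([np.zeros((5, 2)), np.zeros((5, 2))])


class TestShapePCA:
    def test_explained_fractions_sum_to_one(self):
        specs = [_random_landmarks(10, s) for s in range(8)]
        coords = mm.procrustes_align(specs)
        _, evr, scores = mm.shape_pca(coords)
        assert np.isclose(evr.sum(), 1.0, atol=1e-9)
        assert scores.shape[0] == 8

    def test_single_deformation_axis_dominates_pc1(self):
        base = _random_landmarks(15, 15)
        direction = _random_landmarks(15, 16) - 50.0
        direction /= np.linalg.norm(direction)
        specs = [base + t * direction for t in np.linspace(-5, 5, 12)]
        coords = mm.procrustes_align(specs)
        _, evr, _ = mm.shape_pca(coords)
        assert evr[0] >= 0.99


class TestSpeciesDistance:
    def test_identical_groups_zero(self):
        specs = [_random_landmarks(10, s) for s in range(4)]
        coords = mm.procrustes_align(specs)
        assert mm.species_distance(coords.aligned, coords.aligned) == 0.0

    def test_symmetry(self):
        specs = [_random_landmarks(10, s) for s in range(6)]
        coords = mm.procrustes_align(specs)
        a, b = coords.aligned[:3], coords.aligned[3:]
        assert mm.species_distance(a, b) == mm.species_distance(b, a)


def test_species_experiment_sorts_species():
    """Three synthetic species separate in PC1-PC2 and between-species
    distances exceed the within-species spread."""
    res = mm.species_experiment(n_specimens=8, seed=3)
    assert res["accuracy_pc12"] >= 0.9
    assert np.isclose(res["explained_variance_ratio"].sum(), 1.0, atol=1e-9)
    coords = res["coords"]
    labels = res["labels"]
    for (a, b), d in res["species_distances"].items():
        within = mm.species_distance(
            coords.aligned[labels == a][: len(labels[labels == a]) // 2],
            coords.aligned[labels == a][len(labels[labels == a]) // 2 :],
        )
        assert d > within
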