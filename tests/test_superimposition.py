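"""Procrustes machinery: oracles, invariants and metric properties."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from skatemorph import (
    LandmarkConfiguration,
    align_pair,
    centroid_size,
    gpa,
    procrustes_distance,
    shape_at_pc_extreme,
    shape_pca,
    slide_semilandmarks,
    template_outline,
)
from skatemorph.io_formats import default_outline_sliders
from skatemorph.superimposition import _center_scale, pca_of_rows


def rotation(theta):
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s], [s, c]])


class TestCentroidSize:
    def test_unit_square(self):
        # four corners each sqrt(1/2) from the centre: CS = sqrt(4 * 1/2)
        square = np.array([(0, 0), (1, 0), (1, 1), (0, 1)], dtype=float)
        assert centroid_size(square) == pytest.approx(math.sqrt(2.0), abs=1e-12)

    @given(st.floats(min_value=0.01, max_value=100.0))
    @settings(deadline=None, max_examples=25)
    def test_homogeneous_in_scale(self, factor):
        coords = template_outline(12).coords
        assert centroid_size(coords * factor) == pytest.approx(
            factor * centroid_size(coords), rel=1e-9
        )

    def test_matches_loop_oracle(self, random_config):
        coords = random_config(k=35)
        centroid = coords.mean(axis=0)
        oracle = math.sqrt(
            sum((x - centroid[0]) ** 2 + (y - centroid[1]) ** 2 for x, y in coords)
        )
        assert centroid_size(coords) == pytest.approx(oracle, abs=1e-12)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            centroid_size(np.ones((5, 2)))


def grid_search_residual(reference, target, n=62832):
    """Brute-force rotation-only Procrustes residual over a fine angle grid."""
    ref = _center_scale(np.asarray(reference, float))
    tgt = _center_scale(np.asarray(target, float))
    thetas = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    c, s = np.cos(thetas), np.sin(thetas)
    rots = np.stack([np.stack([c, -s], -1), np.stack([s, c], -1)], -2)
    residuals = np.sqrt(
        ((np.einsum("ki,nij->nkj", tgt, rots) - ref) ** 2).sum(axis=(1, 2))
    )
    return float(residuals.min())


class TestAlignPair:
    def test_exact_recovery_of_similarity_transform(self, random_config):
        ref = random_config(k=20)
        target = 3.0 * (ref @ rotation(math.pi / 6).T) + np.array([5.0, -2.0])
        _, dist = align_pair(ref, target)
        assert dist < 1e-10

    def test_mirrored_triangle_matches_rotation_grid_oracle(self):
        triangle = np.array([(0, 0), (3, 0), (1, 2)], dtype=float)
        mirrored = triangle * [-1, 1]
        _, dist = align_pair(triangle, mirrored, allow_reflection=False)
        assert dist == pytest.approx(grid_search_residual(triangle, mirrored), abs=1e-6)
        _, dist_refl = align_pair(triangle, mirrored, allow_reflection=True)
        assert dist_refl < 1e-10

    def test_matches_grid_oracle_on_random_pairs(self, random_config):
        for _ in range(10):
            ref, tgt = random_config(k=12), random_config(k=12)
            _, dist = align_pair(ref, tgt)
            oracle = grid_search_residual(ref, tgt, n=62832)
            assert dist <= oracle + 1e-12
            assert dist == pytest.approx(oracle, abs=1e-6)

    def test_k_mismatch(self, random_config):
        with pytest.raises(ValueError, match="mismatch"):
            align_pair(random_config(k=10), random_config(k=11))


class TestSliding:
    def test_tangential_displacement_fully_removed(self, template35, sliders35):
        ref = template35.coords
        config = ref.copy()
        trip = sliders35.zero_based()
        b, m, a = trip[10]
        tangent = ref[a] - ref[b]
        tangent /= np.linalg.norm(tangent)
        config[m] = ref[m] + 0.005 * tangent
        slid = slide_semilandmarks(config, ref, sliders35)
        np.testing.assert_allclose(slid[m], ref[m], atol=1e-12)

    def test_orthogonal_displacement_untouched(self, template35, sliders35):
        ref = template35.coords
        config = ref.copy()
        trip = sliders35.zero_based()
        b, m, a = trip[20]
        tangent = ref[a] - ref[b]
        tangent /= np.linalg.norm(tangent)
        normal = np.array([-tangent[1], tangent[0]])
        config[m] = ref[m] + 0.004 * normal
        slid = slide_semilandmarks(config, ref, sliders35)
        np.testing.assert_allclose(slid[m], config[m], atol=1e-12)

    def test_matches_1d_grid_oracle(self, template35, sliders35, rng):
        """Each slid point achieves the 2000-point grid minimum on its tangent."""
        ref = template35.coords
        for _ in range(20):
            config = ref + 0.004 * rng.standard_normal(ref.shape)
            slid = slide_semilandmarks(config, ref, sliders35)
            for b, m, a in sliders35.zero_based():
                tangent = config[a] - config[b]
                tangent /= np.linalg.norm(tangent)
                steps = np.linspace(-0.05, 0.05, 2000)
                candidates = config[m] + steps[:, None] * tangent
                grid_best = np.linalg.norm(candidates - ref[m], axis=1).min()
                assert np.linalg.norm(slid[m] - ref[m]) <= grid_best + 1e-6

    def test_never_increases_distance_to_reference(self, template35, sliders35, rng):
        ref = template35.coords
        for _ in range(10):
            config = ref + 0.004 * rng.standard_normal(ref.shape)
            slid = slide_semilandmarks(config, ref, sliders35)
            assert procrustes_distance(slid, ref) <= procrustes_distance(config, ref) + 1e-12

    def test_zero_length_tangent_named(self, sliders35, template35):
        config = template35.coords.copy()
        config[4] = config[6]  # slider 6's chord (landmarks 5..7) collapses
        with pytest.raises(ValueError, match="slider 6"):
            slide_semilandmarks(config, template35.coords, sliders35)


class TestGpa:
    def test_copies_of_one_shape_collapse(self, random_config, rng):
        base = random_config(k=15)
        configs = []
        for _ in range(6):
            theta = rng.uniform(0, 2 * np.pi)
            configs.append(
                rng.uniform(0.5, 2.0) * (base @ rotation(theta).T)
                + rng.uniform(-5, 5, 2)
            )
        aligned = gpa(configs)
        assert aligned.converged
        for shape in aligned.shapes:
            assert procrustes_distance(shape, aligned.consensus) < 1e-9

    def test_two_shapes_equidistant_from_consensus(self, random_config):
        a, b = random_config(k=18), random_config(k=18)
        aligned = gpa([a, b])
        d1 = procrustes_distance(aligned.shapes[0], aligned.consensus)
        d2 = procrustes_distance(aligned.shapes[1], aligned.consensus)
        assert d1 == pytest.approx(d2, abs=1e-9)

    def test_aligned_sample_invariants(self, random_config):
        configs = [random_config(k=25) for _ in range(12)]
        aligned = gpa(configs)
        assert np.abs(aligned.shapes.mean(axis=1)).max() < 1e-9
        sizes = np.sqrt((aligned.shapes**2).sum(axis=(1, 2)))
        assert np.abs(sizes - 1.0).max() < 1e-9
        mean = aligned.shapes.mean(axis=0)
        np.testing.assert_allclose(
            aligned.consensus, _center_scale(mean), atol=1e-12
        )

    def test_input_order_stability(self, random_config, rng):
        configs = [random_config(k=20) for _ in range(20)]
        sliders = default_outline_sliders(20)
        ref = gpa(configs, sliders=sliders)
        perm = rng.permutation(20)
        permuted = gpa([configs[i] for i in perm], sliders=sliders)
        assert procrustes_distance(ref.consensus, permuted.consensus) < 1e-6

    def test_centroid_sizes_preserved(self, random_config):
        configs = [random_config(k=10, scale=s) for s in (1.0, 2.5, 7.0)]
        aligned = gpa(configs)
        expected = [centroid_size(c) for c in configs]
        np.testing.assert_allclose(aligned.centroid_sizes, expected, rtol=1e-12)


class TestProcrustesDistance:
    def test_examples(self):
        a = np.array([(0, 0), (1, 0)], dtype=float)
        b = np.array([(0, 0), (1, 1)], dtype=float)
        assert procrustes_distance(a, a) == 0.0
        assert procrustes_distance(a, b) == pytest.approx(1.0, abs=1e-15)

    def test_matches_loop_oracle(self, random_config):
        a, b = random_config(k=35), random_config(k=35)
        oracle = math.sqrt(
            sum(
                (a[i, 0] - b[i, 0]) ** 2 + (a[i, 1] - b[i, 1]) ** 2
                for i in range(35)
            )
        )
        assert procrustes_distance(a, b) == pytest.approx(oracle, abs=1e-12)

    def test_metric_axioms_on_random_triples(self, random_config):
        for _ in range(20):
            a, b, c = (random_config(k=9) for _ in range(3))
            dab = procrustes_distance(a, b)
            assert dab == pytest.approx(procrustes_distance(b, a), abs=1e-12)
            assert dab >= 0
            assert dab <= procrustes_distance(a, c) + procrustes_distance(c, b) + 1e-12


class TestShapePca:
    def test_identical_shapes_have_zero_variance(self, random_config):
        coords = random_config(k=10)
        aligned = gpa([coords.copy() for _ in range(5)])
        pca = shape_pca(aligned)
        assert np.all(pca.eigenvalues < 1e-20)
        assert np.all(np.abs(pca.scores) < 1e-9)

    def test_collinear_shapes_give_single_axis(self):
        base = template_outline(10).coords
        direction = np.zeros_like(base)
        direction[3, 1] = 1.0
        rows = np.stack(
            [(base + t * 0.01 * direction).ravel() for t in (-1.0, 0.0, 1.0)]
        )
        pca = pca_of_rows(rows)
        assert pca.proportion_variance[0] == pytest.approx(1.0, abs=1e-9)
        assert np.all(pca.eigenvalues[1:] < 1e-12 * pca.eigenvalues[0])

    def test_matches_covariance_eigendecomposition_oracle(self, random_config):
        configs = [random_config(k=12) for _ in range(40)]
        aligned = gpa(configs)
        pca = shape_pca(aligned)
        flat = aligned.flattened()
        cov = np.cov(flat, rowvar=False)
        oracle = np.sort(np.linalg.eigvalsh(cov))[::-1]
        m = pca.n_axes
        np.testing.assert_allclose(pca.eigenvalues, oracle[:m], atol=1e-12)
        np.testing.assert_allclose(
            pca.proportion_variance, oracle[:m] / oracle.sum(), atol=1e-9
        )

    def test_structural_invariants(self, random_config):
        configs = [random_config(k=14) for _ in range(15)]
        aligned = gpa(configs)
        pca = shape_pca(aligned)
        assert pca.proportion_variance.sum() == pytest.approx(1.0, abs=1e-9)
        gram = pca.loadings @ pca.loadings.T
        np.testing.assert_allclose(gram, np.eye(pca.n_axes), atol=1e-9)
        assert np.abs(pca.scores.mean(axis=0)).max() < 1e-9
        recon = pca.mean + pca.scores @ pca.loadings
        np.testing.assert_allclose(recon, aligned.flattened(), atol=1e-8)
        # total variance equals mean squared distance to the mean * n/(n-1)
        flat = aligned.flattened()
        msd = ((flat - flat.mean(axis=0)) ** 2).sum(axis=1).mean()
        n = flat.shape[0]
        assert pca.eigenvalues.sum() == pytest.approx(msd * n / (n - 1), rel=1e-9)

    def test_too_few_shapes_rejected(self, random_config):
        aligned = gpa([random_config(k=8), random_config(k=8)])
        with pytest.raises(ValueError, match="at least 3"):
            shape_pca(aligned)


class TestPcExtremes:
    def test_linearity_and_round_trip(self, random_config):
        configs = [random_config(k=16) for _ in range(12)]
        pca = shape_pca(gpa(configs))
        lo = shape_at_pc_extreme(pca, 2, "min")
        hi = shape_at_pc_extreme(pca, 2, "max")
        scores = pca.scores[:, 1]
        expected_diff = (scores.max() - scores.min()) * pca.loadings[1]
        np.testing.assert_allclose((hi - lo).ravel(), expected_diff, atol=1e-12)
        # projecting the extreme shape back recovers the extreme score
        back = (hi.ravel() - pca.mean) @ pca.loadings[1]
        assert back == pytest.approx(scores.max(), abs=1e-10)

    def test_null_axis_rejected(self, random_config):
        coords = random_config(k=10)
        aligned = gpa([coords.copy() for _ in range(4)])
        pca = shape_pca(aligned)
        with pytest.raises(ValueError, match="zero variance"):
            shape_at_pc_extreme(pca, 1, "max")
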