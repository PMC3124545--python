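import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wingshape.superimposition import (DegenerateConfigurationError,
                                       LandmarkConfiguration, center_and_scale,
                                       gpa_align, optimal_rotation,
                                       procrustes_distance,
                                       tangent_adequacy_check, tangent_project)


def rot(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def similarity(coords, rng):
    theta = rng.uniform(0, 2 * np.pi)
    scale = rng.uniform(0.3, 3.0)
    shift = rng.normal(0, 5, 2)
    return scale * coords @ rot(theta).T + shift


class TestCenterAndScale:
    def test_square_hand_computation(self):
        sq = LandmarkConfiguration("sq", [(0, 0), (2, 0), (2, 2), (0, 2)])
        # centroid (1,1); root summed squared distances = sqrt(4*2) = 2*sqrt(2)
        assert sq.centroid_size == pytest.approx(2 * np.sqrt(2))
        out = center_and_scale(sq)
        np.testing.assert_allclose(out.coords.mean(axis=0), 0, atol=1e-15)
        assert out.centroid_size == pytest.approx(1.0)
        np.testing.assert_allclose(out.coords[0], [-1, -1] / (2 * np.sqrt(2)))

    def test_idempotent(self, template):
        once = center_and_scale(template)
        twice = center_and_scale(once)
        np.testing.assert_allclose(twice.coords, once.coords, atol=1e-15)

    def test_coincident_landmarks_error(self):
        cfg = LandmarkConfiguration("bad", np.ones((19, 2)))
        with pytest.raises(DegenerateConfigurationError):
            center_and_scale(cfg)


class TestOptimalRotation:
    def test_recovers_known_angle(self, template):
        ref = center_and_scale(template)
        rotated = LandmarkConfiguration("r", ref.coords @ rot(np.pi / 6).T)
        angle, back = optimal_rotation(rotated, ref)
        assert angle == pytest.approx(-np.pi / 6)
        np.testing.assert_allclose(back, ref.coords, atol=1e-10)

    def test_identity_for_same_config(self, template):
        ref = center_and_scale(template)
        angle, back = optimal_rotation(ref, ref)
        assert angle == pytest.approx(0.0)

    def test_reflection_not_applied(self, template):
        """A reflected shape keeps a nonzero residual: the best PROPER
        rotation matches a brute-force search over angles."""
        ref = center_and_scale(template)
        reflected = LandmarkConfiguration("m", ref.coords * [-1, 1])
        reflected = center_and_scale(reflected)
        _, fitted = optimal_rotation(reflected, ref)
        residual = ((fitted - ref.coords) ** 2).sum()
        assert residual > 1e-3
        grid = np.linspace(0, 2 * np.pi, 20000)
        best = min(((reflected.coords @ rot(t).T - ref.coords) ** 2).sum()
                   for t in grid)
        assert residual == pytest.approx(best, rel=1e-5)

    def test_mismatched_k_error(self, template):
        small = LandmarkConfiguration("s", template.coords[:5])
        with pytest.raises(ValueError, match="mismatch"):
            optimal_rotation(small, center_and_scale(template))


class TestGpaAlign:
    def test_recovers_single_shape_under_similarity(self, template):
        rng = np.random.default_rng(0)
        configs = [LandmarkConfiguration(f"c{i}", similarity(template.coords, rng))
                   for i in range(5)]
        res = gpa_align(configs)
        assert res.converged
        for cfg in res.aligned:
            np.testing.assert_allclose(cfg.coords, res.aligned[0].coords,
                                       atol=1e-8)
        assert procrustes_distance(res.aligned[0],
                                   center_and_scale(template)) < 1e-8

    def test_invariant_to_ordering_and_similarity(self, low_noise_wings):
        rng = np.random.default_rng(3)
        res1 = gpa_align(low_noise_wings)
        shuffled = list(low_noise_wings)
        rng.shuffle(shuffled)
        transformed = [LandmarkConfiguration(c.label,
                                             similarity(c.coords, rng))
                       for c in shuffled]
        res2 = gpa_align(transformed)
        by_label_1 = {c.label: c.coords for c in res1.aligned}
        by_label_2 = {c.label: c.coords for c in res2.aligned}
        for label in by_label_1:
            np.testing.assert_allclose(by_label_2[label], by_label_1[label],
                                       atol=1e-8)

    def test_aligned_configs_normalized(self, aligned_low_noise):
        for cfg in aligned_low_noise.aligned:
            np.testing.assert_allclose(cfg.coords.mean(axis=0), 0, atol=1e-9)
            assert cfg.centroid_size == pytest.approx(1.0, abs=1e-9)
        cons = aligned_low_noise.consensus
        assert np.sqrt((cons ** 2).sum()) == pytest.approx(1.0, abs=1e-9)

    def test_two_triangles_matches_brute_force(self):
        a = LandmarkConfiguration("a", [(0, 0), (1, 0), (0.5, 1.0)])
        b = LandmarkConfiguration("b", [(0, 0), (1, 0), (0.2, 0.6)])
        res = gpa_align([a, b])
        resid = sum(((c.coords - res.consensus) ** 2).sum()
                    for c in res.aligned)
        # oracle: consensus must be the normalized mean and the summed
        # residual the minimum over relative rotation angles
        an, bn = center_and_scale(a).coords, center_and_scale(b).coords
        grid = np.linspace(0, 2 * np.pi, 100000)
        best = np.inf
        for t in grid:
            bt = bn @ rot(t).T
            mean = (an + bt) / 2
            mean /= np.sqrt((mean ** 2).sum())
            best = min(best, ((an - mean) ** 2).sum() + ((bt - mean) ** 2).sum())
        assert resid == pytest.approx(best, abs=1e-6)

    def test_converges_quickly_on_synthetic_wings(self, aligned_low_noise):
        assert aligned_low_noise.converged
        assert aligned_low_noise.iterations < 10


class TestProcrustesDistance:
    def test_zero_under_similarity(self, template):
        rng = np.random.default_rng(2)
        other = LandmarkConfiguration("t", similarity(template.coords, rng))
        assert procrustes_distance(template, other) == pytest.approx(0, abs=1e-10)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_symmetry_and_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c = (LandmarkConfiguration(n, rng.normal(0, 1, (8, 2)))
                   for n in "abc")
        dab = procrustes_distance(a, b)
        dba = procrustes_distance(b, a)
        assert dab == pytest.approx(dba, abs=1e-10)
        dac = procrustes_distance(a, c)
        dbc = procrustes_distance(b, c)
        assert dab <= dac + dbc + 1e-10

    def test_matches_rotation_grid_oracle(self):
        eq = LandmarkConfiguration("eq", [(0, 0), (1, 0), (0.5, np.sqrt(3) / 2)])
        ri = LandmarkConfiguration("ri", [(0, 0), (1, 0), (0, 1)])
        d = procrustes_distance(eq, ri)
        an, bn = center_and_scale(eq).coords, center_and_scale(ri).coords
        grid = np.linspace(0, 2 * np.pi, 200000)
        best = min(np.sqrt(((bn @ rot(t).T - an) ** 2).sum()) for t in grid)
        assert d == pytest.approx(best, abs=1e-8)


class TestTangent:
    def test_consensus_maps_to_zero(self, aligned_low_noise):
        from wingshape.superimposition import tangent_coords_at
        cons_cfg = LandmarkConfiguration("cons", aligned_low_noise.consensus)
        row = tangent_coords_at(aligned_low_noise.consensus, [cons_cfg])
        np.testing.assert_allclose(row, 0, atol=1e-12)

    def test_projection_is_linear(self, aligned_low_noise):
        t = tangent_project(aligned_low_noise)
        a = aligned_low_noise.aligned[0].flat()
        b = aligned_low_noise.aligned[1].flat()
        c = aligned_low_noise.consensus.reshape(-1)
        mid = (a + b) / 2
        proj_mid = mid - (mid @ c) * c
        np.testing.assert_allclose(proj_mid, (t[0] + t[1]) / 2, atol=1e-12)

    def test_tangent_distances_close_to_procrustes(self, aligned_low_noise):
        t = tangent_project(aligned_low_noise)
        n = aligned_low_noise.n
        rng = np.random.default_rng(0)
        for _ in range(50):
            i, j = rng.choice(n, 2, replace=False)
            pd = procrustes_distance(aligned_low_noise.aligned[i],
                                     aligned_low_noise.aligned[j])
            td = np.linalg.norm(t[i] - t[j])
            assert td == pytest.approx(pd, rel=1e-3)

    def test_adequacy_near_one_for_low_variation(self, aligned_low_noise):
        res = tangent_adequacy_check(aligned_low_noise)
        assert res.n_pairs == 50 * 49 // 2
        assert res.correlation_through_origin >= 0.999
        assert res.slope == pytest.approx(1.0, abs=0.01)

    def test_identical_shapes_flagged(self, template):
        configs = [LandmarkConfiguration(f"c{i}", template.coords.copy())
                   for i in range(4)]
        aligned = gpa_align(configs)
        with pytest.raises(ValueError, match="identical"):
            tangent_adequacy_check(aligned)


def test_gpa_residual_monotone(low_noise_wings):
    """The summed squared residual to the consensus never increases across
    GPA iterations (monotone objective)."""
    from wingshape.superimposition import (_normalize, optimal_rotation,
                                           procrustes_distance_coords)
    scaled = [center_and_scale(c).coords for c in low_noise_wings]
    consensus = _normalize(np.mean(scaled, axis=0))
    aligned = scaled
    prev = np.inf
    for _ in range(6):
        aligned = [optimal_rotation(a, consensus)[1] for a in aligned]
        resid = sum(((a - consensus) ** 2).sum() for a in aligned)
        assert resid <= prev + 1e-12
        prev = resid
        consensus = _normalize(np.mean(aligned, axis=0))
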