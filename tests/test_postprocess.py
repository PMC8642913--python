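import numpy as np
import pytest

from volpiv.core import PHYSICAL, VectorFieldResult
from volpiv.grid import grid_dimensions
from volpiv.postprocess import (
    Replacement,
    average_similarity_selective,
    average_spatial,
    average_spatiotemporal,
    collectiveness_map,
    divergence_map,
    filter_magnitude,
    filter_ppr,
    pseudo_trajectories,
    replace_vectors,
    to_physical_units,
    velocity_map,
)


def make_field(u, v, w=None, sn=None):
    comps = [np.asarray(u, dtype=float), np.asarray(v, dtype=float)]
    if w is not None:
        comps.append(np.asarray(w, dtype=float))
    vectors = np.stack(comps)
    shape = vectors.shape[1:]
    inter = (4,) * len(shape)
    vol = tuple(4 * s for s in shape)
    grid = grid_dimensions(vol, inter, 0)
    sn_arr = None if sn is None else np.asarray(sn, dtype=float)
    return VectorFieldResult(vectors=vectors, sn=sn_arr, grid=grid)


def uniform_field(shape, vec, sn=None):
    comps = [np.full(shape, c) for c in vec]
    return make_field(*comps, sn=sn)


class TestFiltering:
    def test_ppr_threshold_one_keeps_everything(self):
        f = uniform_field((3, 3), (1.0, 0.0), sn=np.full((3, 3), 2.0))
        out, mask = filter_ppr(f, 1.0)
        assert not mask.any()
        assert np.array_equal(out.vectors, f.vectors)

    def test_ppr_zero_replacement(self):
        sn = np.array([[2.0, 1.1]])
        f = make_field([[1.0, 1.0]], [[0.5, 0.5]], sn=sn)
        out, mask = filter_ppr(f, 1.5, Replacement.ZERO)
        assert mask.tolist() == [[False, True]]
        assert out.vectors[:, 0, 1].tolist() == [0.0, 0.0]
        assert out.vectors[:, 0, 0].tolist() == [1.0, 0.5]

    def test_ppr_requires_sn(self):
        f = uniform_field((2, 2), (1.0, 0.0))
        with pytest.raises(ValueError):
            filter_ppr(f, 1.5)

    def test_mean_replacement_uniform_neighbors(self):
        u = np.ones((3, 3)); u[1, 1] = 50.0
        f = make_field(u, np.zeros((3, 3)))
        mask = np.zeros((3, 3), dtype=bool); mask[1, 1] = True
        out = replace_vectors(f, mask, Replacement.MEAN, radius=1)
        assert out.vectors[0, 1, 1] == pytest.approx(1.0)

    def test_mean_replacement_arithmetic(self):
        u = np.array([[1.0, 0.0, 3.0]])
        f = make_field(u, np.zeros((1, 3)))
        mask = np.array([[False, True, False]])
        out = replace_vectors(f, mask, Replacement.MEAN, radius=1)
        assert out.vectors[0, 0, 1] == pytest.approx(2.0)

    def test_median_robust_to_outlier(self):
        u = np.array([[1.0, 1.0, 0.0, 1.0, 99.0]])
        f = make_field(u, np.zeros((1, 5)))
        mask = np.array([[False, False, True, False, False]])
        out = replace_vectors(f, mask, Replacement.MEDIAN, radius=2)
        assert out.vectors[0, 0, 2] == pytest.approx(1.0)

    def test_no_valid_neighbor_becomes_zero(self):
        f = uniform_field((2, 2), (3.0, 4.0))
        mask = np.ones((2, 2), dtype=bool)
        out = replace_vectors(f, mask, Replacement.MEAN, radius=1)
        assert np.all(out.vectors == 0.0)
        assert np.all(np.isfinite(out.vectors))

    def test_magnitude_rules(self):
        u = np.array([[1.0, 1.0, 10.0]])
        f = make_field(u, np.zeros((1, 3)))
        _, mask = filter_magnitude(f, high=5.0)
        assert mask.tolist() == [[False, False, True]]
        _, mask_none = filter_magnitude(uniform_field((1, 3), (1.0, 0.0)),
                                        nsigma_global=2.0)
        assert not mask_none.any()
        with pytest.raises(ValueError):
            filter_magnitude(f)

    def test_band_pass_equals_combined_mask(self):
        u = np.array([[0.1, 1.0, 10.0, 2.0]])
        f = make_field(u, np.zeros((1, 4)))
        _, m_low = filter_magnitude(f, low=0.5)
        _, m_high = filter_magnitude(f, high=5.0)
        _, m_band = filter_magnitude(f, low=0.5, high=5.0)
        assert np.array_equal(m_band, m_low | m_high)


class TestAveraging:
    def test_constant_field_unchanged(self):
        f = uniform_field((4, 4), (2.0, -1.0))
        out = average_spatial(f, radius=1)
        assert np.allclose(out.vectors, f.vectors)

    def test_impulse_spreads_to_ninth(self):
        u = np.zeros((5, 5)); u[2, 2] = 9.0
        f = make_field(u, np.zeros((5, 5)))
        out = average_spatial(f, radius=1)
        assert out.vectors[0, 2, 2] == pytest.approx(1.0)
        assert out.vectors[0, 1, 1] == pytest.approx(1.0)
        assert out.vectors[0, 0, 0] == pytest.approx(0.0)

    def test_radius_zero_identity(self, rng):
        f = make_field(rng.random((4, 4)), rng.random((4, 4)))
        out = average_spatial(f, radius=0)
        assert np.allclose(out.vectors, f.vectors)

    def test_border_clipped_counts(self):
        u = np.ones((3, 3))
        f = make_field(u, np.zeros((3, 3)))
        out = average_spatial(f, radius=1)
        # corner mean over a 2x2 clipped window of ones is still 1
        assert out.vectors[0, 0, 0] == pytest.approx(1.0)

    def test_spatiotemporal_time_constant_unchanged(self):
        fields = [uniform_field((3, 3), (1.0, 2.0)) for _ in range(4)]
        out = average_spatiotemporal(fields, radius=1, n_t=1)
        for f in out:
            assert np.allclose(f.vectors[0], 1.0) and np.allclose(f.vectors[1], 2.0)

    def test_spatiotemporal_alternating_sequence(self):
        plus = uniform_field((3, 3), (1.0, 0.0))
        minus = uniform_field((3, 3), (-1.0, 0.0))
        out = average_spatiotemporal([plus, minus, plus, minus], radius=0, n_t=1)
        # interior frame 1 averages frames 0..2 -> (+1 -1 +1)/3
        assert np.allclose(out[1].vectors[0], 1.0 / 3.0)
        # end frame 0 averages frames 0..1 -> 0
        assert np.allclose(out[0].vectors[0], 0.0)

    def test_nt_zero_equals_spatial(self, rng):
        fields = [make_field(rng.random((4, 4)), rng.random((4, 4))) for _ in range(2)]
        out = average_spatiotemporal(fields, radius=1, n_t=0)
        for f_in, f_out in zip(fields, out):
            assert np.allclose(f_out.vectors, average_spatial(f_in, 1).vectors)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            average_spatiotemporal(
                [uniform_field((3, 3), (1, 0)), uniform_field((4, 4), (1, 0))], 1, 1
            )


class TestSimilaritySelective:
    def test_uniform_unit_field_unchanged(self):
        f = uniform_field((5, 5), (0.0, 1.0))
        out = average_similarity_selective(f, radius=1, sim_threshold=0.5)
        assert np.allclose(out.vectors[1], 1.0)
        assert np.allclose(out.vectors[0], 0.0)

    def test_opposing_neighbors_dissolve_vector(self):
        u = -np.ones((3, 3)); u[1, 1] = 1.0
        f = make_field(u, np.zeros((3, 3)))
        out = average_similarity_selective(f, radius=1, sim_threshold=0.5)
        assert np.allclose(out.vectors[:, 1, 1], 0.0)

    def test_background_edge_keeps_half_magnitude(self):
        """A coherent vector with half its neighbors zero keeps magnitude
        ~ the similar fraction instead of being dissolved."""
        u = np.zeros((3, 3)); u[:, :2] = 1.0  # left 2 columns move, right is background
        f = make_field(u, np.zeros((3, 3)))
        out = average_similarity_selective(f, radius=1, sim_threshold=0.5)
        # center of the moving region: col 0, row 1 -> neighbors: 3 in col 1 similar...
        mag = np.sqrt(np.sum(out.vectors**2, axis=0))
        assert mag[1, 1] == pytest.approx(5 / 8)  # 5 similar of 8 neighbors
        assert mag[1, 0] == pytest.approx(1.0)  # clipped window, all 5 similar

    def test_magnitude_matches_collectiveness(self, rng):
        f = make_field(rng.normal(size=(4, 4)), rng.normal(size=(4, 4)))
        out = average_similarity_selective(f, radius=1, sim_threshold=0.3)
        mag = np.sqrt(np.sum(out.vectors**2, axis=0))
        coll = collectiveness_map(f, radius=1, sim_threshold=0.3)
        assert np.allclose(mag, coll, atol=1e-12)


class TestMaps:
    def test_velocity_map_values(self):
        f = make_field([[3.0, 0.0]], [[4.0, 0.0]])
        assert velocity_map(f).tolist() == [[5.0, 0.0]]

    def test_velocity_scales_with_unit_conversion(self):
        f = uniform_field((2, 2), (2.0, 0.0))
        phys = to_physical_units(f, 1.0, 0.5)  # isotropic pitch -> global factor 2
        assert np.allclose(velocity_map(phys), 2.0 * velocity_map(f))

    def test_divergence_source_detected(self):
        shape = (7, 7)
        idx = np.indices(shape).astype(float) - 3.0
        f = make_field(idx[0], idx[1])
        dmap = divergence_map(f, cube_size=3)
        assert np.unravel_index(np.argmax(dmap), shape) == (3, 3)
        assert dmap[3, 3] > 0

    def test_divergence_uniform_interior_zero(self):
        f = uniform_field((6, 6), (1.0, 1.0))
        dmap = divergence_map(f, cube_size=3)
        assert np.allclose(dmap[1:-1, 1:-1], 0.0, atol=1e-12)

    def test_divergence_antisymmetric_under_negation(self, rng):
        f = make_field(rng.normal(size=(5, 5)), rng.normal(size=(5, 5)))
        neg = make_field(-f.vectors[0], -f.vectors[1])
        assert np.allclose(divergence_map(f, 3), -divergence_map(neg, 3))

    def test_divergence_matches_sliding_oracle(self, rng):
        from volpiv.postprocess import _unit_vectors, divergence_template

        f = make_field(rng.normal(size=(5, 6)), rng.normal(size=(5, 6)))
        k = 3
        t = divergence_template(k, 2)
        unit, _ = _unit_vectors(f.vectors)
        dmap = divergence_map(f, k)
        r = k // 2
        for c0 in range(5):
            for c1 in range(6):
                total = 0.0
                for o0 in range(-r, r + 1):
                    for o1 in range(-r, r + 1):
                        p0, p1 = c0 + o0, c1 + o1
                        if 0 <= p0 < 5 and 0 <= p1 < 6:
                            total += (t[0, o0 + r, o1 + r] * unit[0, p0, p1]
                                      + t[1, o0 + r, o1 + r] * unit[1, p0, p1])
                assert dmap[c0, c1] == pytest.approx(total, abs=1e-10)

    def test_even_cube_rejected(self):
        with pytest.raises(ValueError):
            divergence_map(uniform_field((3, 3), (1.0, 0.0)), cube_size=4)

    def test_collectiveness_uniform_is_one(self):
        f = uniform_field((4, 4), (1.0, 1.0))
        assert np.allclose(collectiveness_map(f, 1, 0.5), 1.0)

    def test_collectiveness_checkerboard_orthogonal(self):
        u = np.zeros((4, 4)); v = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                if (i + j) % 2:
                    u[i, j] = 1.0
                else:
                    v[i, j] = 1.0
        f = make_field(u, v)
        coll = collectiveness_map(f, 1, 0.5)
        # 4-connected neighbors are orthogonal (dot 0); diagonal ones parallel
        interior = coll[1:-1, 1:-1]
        assert np.allclose(interior, 4 / 8)  # 4 similar diagonals of 8 neighbors


class TestTrajectories:
    def test_uniform_field_straight_path(self):
        fields = [uniform_field((8, 8), (1.0, 0.0)) for _ in range(5)]
        trajs = pseudo_trajectories(fields, n_particles=3, seed=2,
                                    region=[(1, 2), (1, 2)])
        for tr in trajs:
            net = tr.positions[-1] - tr.positions[0]
            assert net[0] == pytest.approx(5.0)
            assert net[1] == pytest.approx(0.0)

    def test_zero_field_stationary(self):
        fields = [uniform_field((6, 6), (0.0, 0.0)) for _ in range(4)]
        trajs = pseudo_trajectories(fields, 5, seed=1)
        for tr in trajs:
            assert np.allclose(tr.positions, tr.positions[0])

    def test_rotational_field_matches_hand_stepping(self):
        shape = (9, 9)
        idx = np.indices(shape).astype(float) - 4.0
        f = make_field(-0.3 * idx[1], 0.3 * idx[0])  # solid rotation
        fields = [f] * 6
        trajs = pseudo_trajectories(fields, 4, seed=7)
        for tr in trajs:
            p = tr.positions[0].copy()
            for t in range(6):
                cell = np.rint(p).astype(int)
                if np.any(cell < 0) or np.any(cell >= np.array(shape)):
                    break
                p = p + f.vectors[(slice(None),) + tuple(cell)]
            assert np.allclose(tr.positions[len(tr.positions) - 1], p, atol=1e-12) or not tr.alive

    def test_exiting_particle_frozen(self):
        fields = [uniform_field((4, 4), (5.0, 0.0)) for _ in range(4)]
        trajs = pseudo_trajectories(fields, 2, seed=0)
        for tr in trajs:
            assert not tr.alive
            assert np.array_equal(tr.positions[-1], tr.positions[-2])

    def test_bad_region_rejected(self):
        fields = [uniform_field((4, 4), (0.0, 0.0))] * 2
        with pytest.raises(ValueError):
            pseudo_trajectories(fields, 2, region=[(3, 1), (0, 1)])
        with pytest.raises(ValueError):
            pseudo_trajectories(fields, 2, t_start=2, t_end=1)


class TestUnitConversion:
    def test_basic_conversion(self):
        f = uniform_field((2, 2), (2.0, 0.0))
        out = to_physical_units(f, 0.5, 0.5)  # 0.5 um pitch, 0.5 h interval
        assert np.allclose(out.vectors[0], 2.0)
        assert out.units == PHYSICAL

    def test_anisotropic_pitch(self):
        f = uniform_field((2, 2, 2), (1.0, 1.0, 1.0))
        out = to_physical_units(f, (1.0, 2.0, 4.0), 1.0)
        assert np.allclose(out.vectors[0], 1.0)
        assert np.allclose(out.vectors[1], 2.0)
        assert np.allclose(out.vectors[2], 4.0)

    def test_double_conversion_rejected(self):
        f = uniform_field((2, 2), (1.0, 0.0))
        out = to_physical_units(f, 1.0, 1.0)
        with pytest.raises(ValueError):
            to_physical_units(out, 1.0, 1.0)

    def test_zero_vector_stays_zero(self):
        f = uniform_field((2, 2), (0.0, 0.0))
        out = to_physical_units(f, 3.0, 0.1)
        assert np.all(out.vectors == 0.0)
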