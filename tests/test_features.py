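"""Conformational features: partitioning, reported index map, geometry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from shearfold import SimParams, partition_chain, extract_features
from shearfold.features import (
    FEATURE_SYMBOLS,
    com_velocity,
    end_to_end,
    feature_index_map,
    feature_names,
    featurize_frames,
    flow_induced_displacement,
    gyration,
    local_chain_concentration,
    max_axis_extent,
    n_reported_indices,
    pca_flow_projections,
    variation_fraction_flow,
)
from shearfold.fixtures import FixtureSpec, generate_fixture
from shearfold.simulation import Frame

finite_clouds = arrays(
    np.float64, (20, 3),
    elements=st.floats(-1e3, 1e3, allow_nan=False, allow_infinity=False),
)


class TestPartitioning:
    @pytest.mark.parametrize("n_seg,size", [(1, 100), (5, 20), (10, 10)])
    def test_equal_contiguous_ranges(self, n_seg, size):
        part = partition_chain(100, n_seg)
        assert len(part.ranges) == n_seg
        assert all(b - a == size for a, b in part.ranges)
        flat = [i for a, b in part.ranges for i in range(a, b)]
        assert flat == list(range(100))

    def test_non_divisible_rejected(self):
        with pytest.raises(ValueError):
            partition_chain(100, 7)

    def test_spring_to_segment_assignment(self):
        part = partition_chain(100, 5)
        assert part.segment_of_spring(0) == 0
        assert part.segment_of_spring(9) == 0
        assert part.segment_of_spring(10) == 1
        assert part.segment_of_spring(49) == 4


class TestGeometryOps:
    def test_max_axis_extent_single_bead_zero(self):
        assert max_axis_extent(np.array([[1.0, 2.0, 3.0]]), 0) == 0.0

    def test_max_axis_extent_two_beads(self):
        pos = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        assert max_axis_extent(pos, 0) == 5.0

    def test_max_axis_extent_matches_pairwise_oracle(self, rng):
        pos = rng.standard_normal((20, 3)) * 40
        for ax in range(3):
            brute = max(
                abs(pos[i, ax] - pos[j, ax])
                for i in range(20) for j in range(20)
            )
            assert max_axis_extent(pos, ax) == pytest.approx(brute)

    def test_end_to_end_examples(self):
        assert end_to_end(np.array([[0.0, 0, 0], [9, 9, 9], [0, 0, 0]])) == 0.0
        path = np.array([[0.0, 0, 0], [7, -2, 11], [3.0, 4.0, 0.0]])
        assert end_to_end(path) == pytest.approx(5.0)
        with pytest.raises(ValueError):
            end_to_end(np.array([[1.0, 2, 3]]))

    def test_gyration_identity_and_degenerate_axes(self, rng):
        pos = rng.standard_normal((30, 3)) * 25
        gx, gy, gz, gt = gyration(pos)
        assert gt**2 == pytest.approx(gx**2 + gy**2 + gz**2, rel=1e-12)
        dev = pos - pos.mean(axis=0)
        assert gt == pytest.approx(np.sqrt(np.mean(np.sum(dev**2, axis=1))))
        on_axis = np.zeros((5, 3))
        on_axis[:, 0] = [0, 1, 2, 3, 4]
        gx, gy, gz, gt = gyration(on_axis)
        assert gy == 0 and gz == 0 and gt == pytest.approx(gx)

    def test_vff_examples(self):
        assert variation_fraction_flow(2.0, 2.0, 2.0) == pytest.approx(1 / 3)
        assert variation_fraction_flow(4.0, 0.0, 0.0) == 1.0
        assert variation_fraction_flow(3.0, 2.0, 1.0) == pytest.approx(0.5)
        with pytest.warns(UserWarning):
            assert variation_fraction_flow(0.0, 0.0, 0.0) == 0.0

    def test_lcc_counts_all_beads_within_threshold(self):
        # 20-bead segment isolated far from the other 80 beads
        pos = np.zeros((100, 3))
        pos[20:] = [1e5, 0.0, 0.0]
        val = local_chain_concentration(pos, (0, 20), 5, bead_radius=12.0)
        assert val == pytest.approx(0.2)
        with pytest.raises(ValueError):
            local_chain_concentration(pos, (0, 20), 7, bead_radius=12.0)

    def test_lcc_threshold_scales_with_resolution(self):
        # bead at 30 radii: inside the chain-level threshold (50a) only
        pos = np.zeros((10, 3))
        pos[-1] = [30 * 12.0, 0, 0]
        pos[:-1, 0] = np.linspace(-1, 1, 9)
        chain = local_chain_concentration(pos, (0, 10), 1, 12.0)
        ten = local_chain_concentration(pos, (0, 10), 10, 12.0)
        assert chain > ten


class TestPca:
    def test_rod_along_flow_axis(self):
        pos = np.zeros((10, 3))
        pos[:, 0] = np.arange(10)
        p1, p2, p3 = pca_flow_projections(pos)
        assert p1 == pytest.approx(1.0)

    def test_rod_perpendicular_to_flow(self):
        pos = np.zeros((10, 3))
        pos[:, 1] = np.arange(10)
        p1, _, _ = pca_flow_projections(pos)
        assert p1 == pytest.approx(0.0, abs=1e-12)

    def test_matches_svd_oracle(self, rng):
        pos = rng.standard_normal((25, 3)) * [5, 2, 9]
        dev = pos - pos.mean(axis=0)
        _, s, vt = np.linalg.svd(dev, full_matrices=False)
        expected = np.abs(vt[:, 0])
        got = pca_flow_projections(pos)
        assert np.allclose(sorted(got), sorted(expected), atol=1e-8)
        assert all(0 <= g <= 1 for g in got)
        # eigenvalue ordering: projections follow descending variance
        assert got[0] == pytest.approx(expected[0], abs=1e-8)


class TestKinematicFeatures:
    def test_com_velocity_identical_frames_zero(self):
        pos = np.random.default_rng(0).standard_normal((10, 3))
        f0 = Frame(0.0, pos, np.zeros(5))
        f1 = Frame(1e-6, pos, np.zeros(5))
        assert com_velocity(f1, f0, (0, 10)) == (0.0, 0.0, 0.0)

    def test_com_velocity_uniform_translation(self):
        pos = np.zeros((4, 3))
        f0 = Frame(0.0, pos, np.zeros(2))
        f1 = Frame(2e-6, pos + [1.0, -2.0, 0.5], np.zeros(2))
        v = com_velocity(f1, f0, (0, 4))
        assert np.allclose(v, np.array([1.0, -2.0, 0.5]) / 2e-6)

    def test_com_velocity_equals_mean_bead_velocity(self, rng):
        p0 = rng.standard_normal((10, 3))
        p1 = p0 + rng.standard_normal((10, 3))
        f0, f1 = Frame(0.0, p0, np.zeros(5)), Frame(1e-6, p1, np.zeros(5))
        v = np.array(com_velocity(f1, f0, (2, 8)))
        per_bead = (p1[2:8] - p0[2:8]) / 1e-6
        assert np.allclose(v, per_bead.mean(axis=0))

    def test_com_velocity_rejects_bad_ordering(self):
        pos = np.zeros((4, 3))
        f0 = Frame(0.0, pos, np.zeros(2))
        f1 = Frame(1e-6, pos, np.zeros(2))
        with pytest.raises(ValueError):
            com_velocity(f0, f1, (0, 4))
        with pytest.raises(ValueError):
            com_velocity(f1, f0, (0, 4), sample_interval=5e-6)

    @pytest.mark.parametrize(
        "rate,z,dt,expected",
        [(0.0, 3.0, 0.5, 0.0), (2.0, 0.0, 0.5, 0.0), (2.0, 3.0, 0.5, 3.0)],
    )
    def test_flow_induced_displacement(self, rate, z, dt, expected):
        pos = np.zeros((2, 3))
        pos[:, 2] = z
        frame = Frame(0.0, pos, np.zeros(1))
        assert flow_induced_displacement(frame, (0, 2), rate, dt) == pytest.approx(expected)


class TestIndexMap:
    @pytest.mark.parametrize("res,count", [(1, 20), (5, 88), (10, 173)])
    def test_reported_index_counts(self, res, count):
        assert n_reported_indices(res) == count
        assert feature_index_map(100, res).max() == count

    def test_raw_position_features_number_three_hundred(self):
        idx = feature_index_map(100, 5)
        assert np.count_nonzero(np.isin(idx, (1, 2, 3))) == 300
        assert len(idx) == 300 + 17 * 5

    def test_five_segment_layout_matches_printed_ranges(self):
        idx = feature_index_map(100, 5)
        names = feature_names(100, 5)
        # per-axis maximum span in x occupies indices 24-28
        got = sorted(idx[i] for i, n in enumerate(names) if n.startswith("MAX_X"))
        assert got == [24, 25, 26, 27, 28]
        got = sorted(idx[i] for i, n in enumerate(names) if n.startswith("PCA_3"))
        assert got == [84, 85, 86, 87, 88]

    def test_ten_segment_last_index_is_173(self):
        idx = feature_index_map(100, 10)
        names = feature_names(100, 10)
        pca3 = sorted(idx[i] for i, n in enumerate(names) if n.startswith("PCA_3"))
        assert pca3 == list(range(164, 174))

    def test_bijective_onto_reported_indices(self):
        for res in (1, 5, 10):
            idx = feature_index_map(100, res)
            assert set(idx) == set(range(1, n_reported_indices(res) + 1))


class TestExtractFeatures:
    def test_rod_fixture_closed_form_values(self, rod_pair):
        prev, cur = rod_pair
        p = SimParams()
        fv = extract_features(cur, prev, p, 5)
        for s in range(1, 6):
            assert fv[f"VFF_s{s}"] == pytest.approx(1.0)
            assert fv[f"PCA_1_s{s}"] == pytest.approx(1.0)
            assert fv[f"RG_Y_s{s}"] == 0.0
            assert fv[f"EE_s{s}"] == pytest.approx(19 * 30.0)
            assert fv[f"MAX_X_s{s}"] == pytest.approx(19 * 30.0)
        # lattice variance of 20 equally spaced beads, spacing 30
        expected_rg = 30.0 * np.sqrt((20**2 - 1) / 12.0)
        assert fv["RG_X_s1"] == pytest.approx(expected_rg)

    def test_globule_fixture_chain_level_lcc_is_one(self, globule_pair):
        prev, cur = globule_pair
        fv = extract_features(cur, prev, SimParams(), 1)
        assert fv["LCC_s1"] == 1.0

    def test_uniform_velocity_recovered(self):
        prev, cur = generate_fixture(
            FixtureSpec("rod", n_beads=100, velocity=(1e6, -5e5, 0.0),
                        sample_interval=SimParams().sample_interval)
        )
        fv = extract_features(cur, prev, SimParams(), 1)
        assert fv["v_X_s1"] == pytest.approx(1e6, rel=1e-6)
        assert fv["v_Y_s1"] == pytest.approx(-5e5, rel=1e-6)
        assert fv["v_Z_s1"] == pytest.approx(0.0, abs=1e-3)

    def test_model_input_length(self, rod_pair):
        prev, cur = rod_pair
        for res, n in ((1, 317), (5, 385), (10, 470)):
            fv = extract_features(cur, prev, SimParams(), res)
            assert len(fv.values) == n
            assert fv.n_reported == n_reported_indices(res)

    def test_mismatched_frame_spacing_rejected(self, rod_pair):
        prev, cur = rod_pair
        bad_prev = Frame(cur.time - 1.0, prev.positions, prev.a2_tensions)
        with pytest.raises(ValueError):
            extract_features(cur, bad_prev, SimParams(), 5)


class TestInvariances:
    @settings(max_examples=25, deadline=None)
    @given(cloud=finite_clouds, shift=st.tuples(
        st.floats(-500, 500), st.floats(-500, 500), st.floats(-500, 500)))
    def test_shape_features_are_translation_invariant(self, cloud, shift):
        moved = cloud + np.asarray(shift)
        for ax in range(3):
            assert max_axis_extent(moved, ax) == pytest.approx(
                max_axis_extent(cloud, ax), abs=1e-6)
        assert end_to_end(moved) == pytest.approx(end_to_end(cloud), abs=1e-6)
        g0, g1 = gyration(cloud), gyration(moved)
        assert np.allclose(g0, g1, atol=1e-6)

    def test_gyration_invariant_to_bead_ordering(self, rng):
        pos = rng.standard_normal((20, 3)) * 10
        perm = rng.permutation(20)
        assert np.allclose(gyration(pos), gyration(pos[perm]))
        assert np.allclose(
            sorted(pca_flow_projections(pos)), sorted(pca_flow_projections(pos[perm])),
            atol=1e-9,
        )

    def test_batch_matches_single_frame_path(self, rng):
        p = SimParams()
        pos_t = rng.standard_normal((3, 100, 3)) * 50
        pos_p = pos_t + rng.standard_normal((3, 100, 3))
        batch = featurize_frames(pos_t, pos_p, p, 5)
        for f in range(3):
            cur = Frame(p.sample_interval, pos_t[f], np.zeros(50))
            prev = Frame(0.0, pos_p[f], np.zeros(50))
            single = extract_features(cur, prev, p, 5)
            assert np.allclose(batch[f], single.values, rtol=1e-12)
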