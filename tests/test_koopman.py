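"""EDMD/Ulam contracts: grid, pairs, matrix identity, spectra, clustering."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import badgermove as bm
from badgermove.koopman import (
    MetastablePartition,
    SnapshotPairs,
    build_grid,
    build_pairs,
    cluster_metastable,
    estimate_koopman,
    filter_sparse_pairs,
    prune_spurious_absorbing,
    spectral_decompose,
    spectral_gap,
    transition_count_oracle,
)
from badgermove.preprocessing import RegularTrack, Track, interpolate_uniform
from badgermove.synthetic import simulate_ou_1d

from conftest import fix_table


def regular_track(xy, dt=20.0, period="p", animal="A1"):
    df = fix_table(np.arange(len(xy)) * dt, xy)
    df["interpolated"] = False
    return RegularTrack(period, animal, dt, df)


class TestBuildGrid:
    def test_exact_spans(self):
        pts = [[0, 0], [1000, 500]]
        g = build_grid(pts, 100.0)
        assert (g.nx, g.ny) == (10, 5)
        assert g.edge_x == 100.0 and g.edge_y == 100.0

    def test_rounding_keeps_integer_counts(self):
        g = build_grid([[0, 0], [1050, 100]], 100.0)
        assert g.nx in (10, 11)
        assert g.edge_x == pytest.approx(1050 / g.nx)

    def test_single_point(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            g = build_grid([[5, 5]], 100.0)
        assert (g.nx, g.ny) == (1, 1)
        assert list(g.occupied) == [0]

    def test_degenerate_cloud_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            build_grid([[0, 0], [0, 100]], 10.0)

    def test_every_point_maps_to_one_box(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 1000, (500, 2))
        g = build_grid(pts, 100.0)
        idx = g.box_index(pts)
        assert idx.shape == (500,)
        assert ((idx >= 0) & (idx < g.n_boxes)).all()

    def test_outside_point_rejected(self):
        g = build_grid([[0, 0], [100, 100]], 50.0)
        with pytest.raises(ValueError):
            g.box_index([[500, 0]])


class TestBuildPairs:
    def test_pair_counts(self):
        t1 = regular_track(np.zeros((5, 2)))
        t2 = regular_track(np.ones((3, 2)), animal="A2")
        t3 = regular_track(np.ones((4, 2)), animal="A3")
        assert len(build_pairs([t1])) == 4
        pairs = build_pairs([t2, t3])
        assert len(pairs) == 5

    def test_no_pair_bridges_tracks(self):
        t1 = regular_track([[0, 0], [1, 0], [2, 0]])
        t2 = regular_track([[100, 0], [101, 0]], animal="A2")
        pairs = build_pairs([t1, t2])
        gaps = np.linalg.norm(pairs.destinations - pairs.sources, axis=1)
        assert gaps.max() < 10  # never the 98 m track-to-track jump

    def test_length_one_track_contributes_nothing(self):
        t1 = regular_track([[0, 0], [1, 0]])
        t2 = regular_track([[9, 9]], animal="A2")
        assert len(build_pairs([t1, t2])) == 1

    def test_mixed_dt_rejected(self):
        t1 = regular_track(np.zeros((3, 2)), dt=20.0)
        t2 = regular_track(np.zeros((3, 2)), dt=35.0, animal="A2")
        with pytest.raises(ValueError):
            build_pairs([t1, t2])


class TestEstimateKoopman:
    def test_deterministic_alternation(self):
        pts = np.array([[0.0, 0.0], [300.0, 0.0]] * 10)
        pairs = SnapshotPairs(pts[:-1], pts[1:], 20.0)
        g = build_grid(pts, 150.0)
        km = estimate_koopman(pairs, g)
        np.testing.assert_allclose(sorted(map(tuple, km.K)),
                                   [(0, 1), (1, 0)], atol=1e-12)
        eig = np.sort(spectral_decompose(km).eigenvalues.real)
        np.testing.assert_allclose(eig, [-1.0, 1.0], atol=1e-10)

    def test_single_box(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 0.0]])
        pairs = SnapshotPairs(pts[:-1], pts[1:], 20.0)
        g = build_grid(pts, 100.0)
        km = estimate_koopman(pairs, g)
        np.testing.assert_allclose(km.K, [[1.0]])

    def test_oracle_hand_count(self):
        # 3 pairs box0 -> box1 and 1 pair box0 -> box0
        src = np.array([[0, 0]] * 4, dtype=float)
        dst = np.array([[300, 0], [300, 0], [300, 0], [0, 0]], dtype=float)
        g = build_grid(np.vstack([src, dst]), 150.0)
        km = transition_count_oracle(SnapshotPairs(src, dst, 20.0), g)
        row0 = km.K[list(km.box_indices).index(g.box_index([[0, 0]])[0])]
        assert sorted(row0) == [0.25, 0.75]

    @settings(max_examples=120, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_edmd_equals_ulam_on_random_pair_sets(self, seed):
        """Central oracle: the least-squares EDMD solution with indicator
        basis functions equals the row-normalised transition-count matrix
        entrywise, on arbitrary random pair sets."""
        rng = np.random.default_rng(seed)
        n_pairs = int(rng.integers(1, 200))
        src = rng.uniform(0, 900, (n_pairs, 2))
        dst = src + rng.normal(0, 120, (n_pairs, 2))
        pairs = SnapshotPairs(src, dst, 20.0)
        grid = build_grid(pairs.all_points, 100.0)
        edmd = estimate_koopman(pairs, grid)
        ulam = transition_count_oracle(pairs, grid)
        np.testing.assert_array_equal(edmd.box_indices, ulam.box_indices)
        assert np.max(np.abs(edmd.K - ulam.K)) < 1e-8

    def test_rows_stochastic_spectrum_in_unit_disk(self, four_well_clean):
        tracks, sched = four_well_clean["tracks"], four_well_clean["schedule"]
        regular = [seg for t in tracks for seg in bm.regularise(t, sched, 20.0)]
        pairs = build_pairs(regular)
        grid = build_grid(pairs.all_points, 100.0)
        km = estimate_koopman(pairs, grid)
        sums = km.K[km.source_counts > 0].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-8)
        assert (km.K > -1e-12).all()
        spec = spectral_decompose(km)
        assert np.all(np.abs(spec.eigenvalues) <= 1 + 1e-6)
        assert abs(spec.eigenvalues[0] - 1.0) < 1e-6

    def test_leading_eigenfunction_constant(self):
        rng = np.random.default_rng(5)
        src = rng.uniform(0, 500, (2000, 2))
        dst = np.clip(src + rng.normal(0, 150, (2000, 2)), 0, 500)
        pairs = SnapshotPairs(src, dst, 20.0)
        grid = build_grid(pairs.all_points, 100.0)
        spec = spectral_decompose(estimate_koopman(pairs, grid))
        lead = np.real(spec.eigenvectors[:, 0])
        assert np.std(lead) / np.abs(np.mean(lead)) < 1e-6

    def test_empty_pairs_rejected(self):
        g = build_grid([[0, 0], [100, 100]], 50.0)
        with pytest.raises(ValueError):
            estimate_koopman(SnapshotPairs(np.empty((0, 2)),
                                           np.empty((0, 2)), 20.0), g)


class TestSpectralGap:
    @pytest.mark.parametrize("eigs,delta,expected", [
        ((1.0, 0.2, 0.1), 0.5, 1),
        ((1.0, 0.98, 0.95, 0.30, 0.20), 0.5, 3),
    ])
    def test_threshold_rule(self, eigs, delta, expected):
        assert spectral_gap(eigs, delta=delta) == expected

    def test_fallback_to_largest_difference(self):
        with pytest.warns(UserWarning, match="falling back"):
            n = spectral_gap((1.0, 0.9, 0.8, 0.7), delta=0.5)
        assert n == 1

    def test_too_few_eigenvalues(self):
        with pytest.raises(ValueError):
            spectral_gap((1.0,), delta=0.1)


class TestOrnsteinUhlenbeck:
    def test_second_eigenvalue_matches_closed_form(self):
        """For a 1-D OU process with rate theta the Koopman operator at
        lag tau has second eigenvalue exp(-theta tau); the Ulam estimate
        from a long exactly-sampled trajectory must be within 5%."""
        theta, sigma, tau = 0.05, 1.0, 5.0
        x = simulate_ou_1d(theta, sigma, 0.0, tau, 120_000, seed=11)
        pts = np.column_stack([x, np.zeros_like(x)])
        pairs = SnapshotPairs(pts[:-1], pts[1:], tau)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            grid = build_grid(pairs.all_points, 0.5)
        spec = spectral_decompose(estimate_koopman(pairs, grid))
        lam2 = spec.eigenvalues[1].real
        assert abs(lam2 - np.exp(-theta * tau)) / np.exp(-theta * tau) < 0.05


class TestClustering:
    def _two_block_spectral(self):
        # two spatially separated box groups, mixing only within groups
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 290, (300, 2))
        b = rng.uniform(1000, 1290, (300, 2))
        src = np.vstack([a[:-1], b[:-1]])
        dst = np.vstack([a[1:], b[1:]])
        pairs = SnapshotPairs(src, dst, 20.0)
        grid = build_grid(pairs.all_points, 100.0)
        km = estimate_koopman(pairs, grid)
        return spectral_decompose(km), grid

    def test_block_diagonal_recovers_blocks_exactly(self):
        spec, grid = self._two_block_spectral()
        ones = np.sum(np.abs(spec.eigenvalues.real - 1.0) < 1e-8)
        assert ones == 2
        part = cluster_metastable(spec, 2, seed=0)
        centres = grid.box_centres(part.box_indices)
        truth = (centres[:, 0] > 500).astype(int)
        same = part.box_labels[truth == 0]
        other = part.box_labels[truth == 1]
        assert len(set(same)) == 1 and len(set(other)) == 1
        assert set(same) != set(other)

    def test_single_cluster(self):
        spec, _ = self._two_block_spectral()
        part = cluster_metastable(spec, 1, seed=0)
        assert set(part.box_labels) == {1}

    def test_n_exceeding_boxes_rejected(self):
        spec, _ = self._two_block_spectral()
        with pytest.raises(ValueError):
            cluster_metastable(spec, spec.matrix.n_states + 1, seed=0)

    def test_permutation_invariance(self):
        """Relabelling box indices permutes cluster labels consistently."""
        spec, grid = self._two_block_spectral()
        part = cluster_metastable(spec, 2, seed=0)
        km = spec.matrix
        perm = np.random.default_rng(3).permutation(km.n_states)
        km2 = bm.KoopmanMatrix(km.K[np.ix_(perm, perm)], grid,
                               km.box_indices[perm], km.source_counts[perm])
        part2 = cluster_metastable(spectral_decompose(km2), 2, seed=0)
        lab1 = dict(zip(part.box_indices, part.box_labels))
        lab2 = dict(zip(part2.box_indices, part2.box_labels))
        agreement = {}
        consistent = True
        for box in lab1:
            pair = (lab1[box], lab2[box])
            if lab1[box] in agreement and agreement[lab1[box]] != pair[1]:
                consistent = False
            agreement[lab1[box]] = pair[1]
        assert consistent

    def test_prune_drops_singleton_absorbing_box(self):
        # box 2 is only ever entered and self-looped once: spurious
        src = np.array([[0, 0], [300, 0], [0, 0], [900, 0]], dtype=float)
        dst = np.array([[300, 0], [0, 0], [300, 0], [900, 0]], dtype=float)
        pairs = SnapshotPairs(src, dst, 20.0)
        grid = build_grid(pairs.all_points, 150.0)
        km = estimate_koopman(pairs, grid)
        pruned = prune_spurious_absorbing(km, min_class_size=2)
        assert pruned.n_states == km.n_states - 1
        spec = spectral_decompose(pruned)
        assert np.sum(np.abs(spec.eigenvalues.real - 1) < 1e-8) == 1


class TestFullRecovery:
    def test_four_well_study_recovers_groups(self, four_well_clean):
        """End-to-end slow-scale analysis on the four-group study: the
        spectral gap finds four metastable states and the box partition
        agrees with the generating wells on >= 95% of boxes."""
        tracks = four_well_clean["tracks"]
        sched = four_well_clean["schedule"]
        regular = [seg for t in tracks for seg in bm.regularise(t, sched, 20.0)]
        pairs = build_pairs(regular)
        grid = build_grid(pairs.all_points, 100.0)
        pairs = filter_sparse_pairs(pairs, grid, min_count=5)
        km = prune_spurious_absorbing(estimate_koopman(pairs, grid))
        spec = spectral_decompose(km)
        n = spectral_gap(spec.eigenvalues, delta=0.05, n_max=20)
        assert n == 4
        part = cluster_metastable(spec, n, seed=0)

        # box-level truth: the nearest generating well
        wells = four_well_clean["field"].centres
        centres = grid.box_centres(part.box_indices)
        nearest = np.argmin(
            np.linalg.norm(centres[:, None, :] - wells[None, :, :], axis=2),
            axis=1)
        conf = np.zeros((n, len(wells)))
        for lab, w in zip(part.box_labels, nearest):
            conf[lab - 1, w] += 1
        from scipy.optimize import linear_sum_assignment
        r, c = linear_sum_assignment(-conf)
        assert conf[r, c].sum() / conf.sum() >= 0.95
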