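"""KDE density, mode hunting, two-step clustering and distance diagnostics."""

import numpy as np
import pytest

from svmotif.cluster import (
    BreakpointVector,
    Cluster,
    ClusteringConfig,
    assign_breakpoints,
    bandwidth_sweep,
    cluster_chromosome,
    cluster_distances,
    filter_intra_cluster_adjacencies,
    find_density_peaks,
    gaussian_kde_density,
    two_step_clustering,
)
from svmotif.model import Side

from .conftest import dataset_from_pairs, make_adjacency

R, L = Side.EXTENDS_RIGHT, Side.EXTENDS_LEFT


def bv(positions, sample="s1", chrom="chr1"):
    positions = list(positions)
    return BreakpointVector(
        sample_id=sample,
        chrom=chrom,
        positions=np.asarray(positions, dtype=float),
        refs=[(f"a{i}", 0) for i in range(len(positions))],
    )


class TestKdeDensity:
    def test_single_point_closed_form(self):
        profile = gaussian_kde_density([0.0], 1.0, [0.0])
        assert profile.density[0] == pytest.approx(1 / np.sqrt(2 * np.pi), rel=1e-12)
        # and scales as 1/h at the kernel centre
        profile_h = gaussian_kde_density([0.0], 250.0, [0.0])
        assert profile_h.density[0] == pytest.approx(
            1 / (np.sqrt(2 * np.pi) * 250.0), rel=1e-12
        )

    def test_symmetric_input_symmetric_profile(self):
        grid = np.linspace(-10, 10, 401)
        profile = gaussian_kde_density([-5.0, 5.0], 1.0, grid)
        np.testing.assert_allclose(profile.density, profile.density[::-1], rtol=1e-10)

    def test_normalization_integral(self, rng):
        positions = rng.uniform(0, 1000, size=30)
        h = 40.0
        grid = np.linspace(positions.min() - 8 * h, positions.max() + 8 * h, 4000)
        profile = gaussian_kde_density(positions, h, grid)
        assert np.trapezoid(profile.density, grid) == pytest.approx(1.0, abs=1e-3)

    def test_empty_positions_rejected(self):
        with pytest.raises(ValueError):
            gaussian_kde_density([], 1.0, [0.0])


class TestPeaks:
    def test_unimodal_single_peak(self):
        grid = np.linspace(-5, 5, 501)
        profile = gaussian_kde_density([0.0], 1.0, grid)
        assert len(find_density_peaks(profile)) == 1

    @pytest.mark.parametrize(
        "separation_h, n_modes", [(10.0, 2), (3.0, 2), (0.5, 1), (1.5, 1)]
    )
    def test_two_point_critical_separation(self, separation_h, n_modes):
        """Two equal Gaussians merge into one mode below separation 2h."""
        h = 1.0
        pts = [0.0, separation_h * h]
        grid = np.linspace(-5, separation_h + 5, 2000)
        peaks = find_density_peaks(gaussian_kde_density(pts, h, grid))
        assert len(peaks) == n_modes
        # brute-force oracle: count sign changes of the discrete derivative
        dens = gaussian_kde_density(pts, h, grid).density
        rising = np.diff(dens) > 0
        assert int(np.sum(rising[:-1] & ~rising[1:])) == n_modes

    def test_no_peaks_in_flat_zero_tails(self):
        grid = np.linspace(-40, 40, 4001)
        peaks = find_density_peaks(gaussian_kde_density([0.0], 1.0, grid))
        assert len(peaks) == 1
        assert abs(peaks[0]) < 0.1


class TestAssignment:
    def test_nearest_peak(self):
        assert assign_breakpoints([200.0], [100.0, 900.0])[0] == 0

    def test_equidistant_ties_to_lower_peak(self):
        assert assign_breakpoints([200.0], [100.0, 300.0])[0] == 0

    def test_single_peak_takes_all(self):
        labels = assign_breakpoints([1.0, 50.0, 99.0], [40.0])
        assert (labels == 0).all()

    def test_empty_peaks_rejected(self):
        with pytest.raises(ValueError):
            assign_breakpoints([1.0], [])


class TestClusterChromosome:
    def test_planted_groups_recovered_vs_nearest_centre_oracle(self, rng):
        centers = np.array([1_000_000.0, 1_100_000.0, 2_500_000.0])
        positions = np.concatenate(
            [c + rng.uniform(-100, 100, size=7) for c in centers]
        )
        vector = bv(positions)
        clusters = cluster_chromosome(vector, 1000.0, ClusteringConfig())
        assert len(clusters) == 3
        nearest = np.abs(vector.positions[:, None] - centers).argmin(axis=1)
        oracle = {
            frozenset(vector.positions[nearest == k].tolist()) for k in range(3)
        }
        got = {frozenset(c.positions.tolist()) for c in clusters}
        assert got == oracle

    def test_singleton(self):
        (cluster,) = cluster_chromosome(bv([12345.0]), 1000.0, ClusteringConfig())
        assert cluster.peak_pos == 12345.0
        assert cluster.n == 1

    def test_all_identical_positions(self):
        (cluster,) = cluster_chromosome(bv([500.0] * 6), 1000.0, ClusteringConfig())
        assert cluster.peak_pos == 500.0
        assert cluster.n == 6

    def test_mode_count_non_increasing_in_bandwidth(self, rng):
        positions = np.sort(rng.uniform(0, 200_000, size=40))
        counts = [
            len(cluster_chromosome(bv(positions), h, ClusteringConfig()))
            for h in [100, 300, 1000, 3000, 10000, 30000]
        ]
        assert counts == sorted(counts, reverse=True)

    def test_tiny_bandwidth_one_cluster_per_distinct_coordinate(self):
        positions = [100.0, 100.0, 5000.0, 9000.0]
        clusters = cluster_chromosome(bv(positions), 5.0, ClusteringConfig())
        assert len(clusters) == 3
        assert sorted(c.n for c in clusters) == [1, 1, 2]

    def test_peak_within_member_span(self, rng):
        positions = rng.uniform(0, 50_000, size=25)
        config = ClusteringConfig()
        for c in cluster_chromosome(bv(positions), 800.0, config):
            lo, hi = c.span
            step = config.grid_step_factor * 800.0
            assert lo - step <= c.peak_pos <= hi + step


class TestLoopFilterAndTwoStep:
    def test_intra_cluster_loops_discarded(self):
        adjacencies = [
            make_adjacency("loop", "s1", ("chr1", 1000, R), ("chr1", 1200, L)),
            make_adjacency("inter", "s1", ("chr1", 1050, R), ("chr2", 900_000, L)),
        ]
        assignment = {
            ("loop", 0): "C7",
            ("loop", 1): "C7",
            ("inter", 0): "C7",
            ("inter", 1): "C9",
        }
        kept, discarded = filter_intra_cluster_adjacencies(adjacencies, assignment)
        assert [a.id for a in discarded] == ["loop"]
        assert [a.id for a in kept] == ["inter"]

    def test_empty_input(self):
        assert filter_intra_cluster_adjacencies([], {}) == ([], [])

    def test_unassigned_breakend_raises(self):
        adj = make_adjacency("x", "s1", ("chr1", 10, R), ("chr1", 20, L))
        with pytest.raises(ValueError):
            filter_intra_cluster_adjacencies([adj], {})

    def test_subgroups_merge_round1_split_round2(self):
        """Sub-groups 1.8 kb apart merge at h1=1000 but split at h2=400."""
        group_a = [1_000_000 + d for d in (-60, -20, 30, 70)]
        group_b = [1_001_800 + d for d in (-50, 0, 55)]
        pairs = [("s1", "chr1", p, "chr2", 5_000_000 + 10_000 * i) for i, p in enumerate(group_a)]
        pairs += [("s1", "chr1", p, "chr3", 5_000_000 + 10_000 * i) for i, p in enumerate(group_b)]
        dataset = dataset_from_pairs(pairs)
        result = two_step_clustering(dataset)
        chr1_r1 = [c for c in result.round1_clusters if c.chrom == "chr1"]
        assert len(chr1_r1) == 1
        chr1_final = [c for c in result.clusters if c.chrom == "chr1"]
        assert len(chr1_final) == 2
        sizes = sorted(c.n for c in chr1_final)
        assert sizes == [3, 4]

    def test_only_loops_leaves_nothing(self):
        pairs = [("s1", "chr1", 1000, "chr1", 1100)]
        result = two_step_clustering(dataset_from_pairs(pairs))
        assert result.kept_adjacencies == []
        assert result.clusters == []
        assert len(result.discarded_adjacencies) == 1

    def test_partition_every_breakend_in_exactly_one_final_cluster(self, planted_clustered):
        dataset, result, _graphs = planted_clustered
        refs = {(adj.id, i) for adj in result.kept_adjacencies for i in (0, 1)}
        assigned = set(result.assignment)
        assert assigned == refs
        member_refs = [ref for c in result.clusters for ref in c.members]
        assert len(member_refs) == len(set(member_refs)) == len(refs)

    def test_single_breakpoint_round1_cluster_gives_singleton(self):
        pairs = [("s1", "chr1", 1_000_000, "chr2", 2_000_000)]
        result = two_step_clustering(dataset_from_pairs(pairs))
        assert len(result.clusters) == 2
        assert all(c.n == 1 and c.round == 2 for c in result.clusters)


class TestDistances:
    def _cluster(self, cid, positions):
        positions = np.asarray(positions, dtype=float)
        return Cluster(
            id=cid,
            sample_id="s1",
            chrom="chr1",
            peak_pos=float(np.median(positions)),
            members=[(f"{cid}m{i}", 0) for i in range(len(positions))],
            positions=positions,
            round=2,
        )

    def test_intra_is_span(self):
        intra, _ = cluster_distances([self._cluster("a", [10, 40, 100])])
        assert intra == [90.0]

    def test_inter_is_gap_between_adjacent_spans(self):
        intra, inter = cluster_distances(
            [self._cluster("a", [10, 100]), self._cluster("b", [500, 600])]
        )
        assert inter == [400.0]

    def test_singleton_intra_zero(self):
        intra, _ = cluster_distances([self._cluster("a", [42])])
        assert intra == [0.0]

    def test_overlapping_spans_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            cluster_distances(
                [self._cluster("a", [10, 300]), self._cluster("b", [200, 500])]
            )


class TestBandwidthSweep:
    def test_single_candidate_single_row(self, planted):
        dataset, *_ = planted
        table = bandwidth_sweep(dataset, [400.0])
        assert len(table) == 1
        assert table.loc[0, "h2"] == 400.0

    def test_total_intra_non_decreasing_in_h2(self, planted):
        dataset, *_ = planted
        table = bandwidth_sweep(dataset, [100.0, 400.0, 1000.0])
        intra = table["total_intra"].to_numpy()
        assert (np.diff(intra) >= 0).all()

    def test_empty_candidates_rejected(self, planted):
        dataset, *_ = planted
        with pytest.raises(ValueError):
            bandwidth_sweep(dataset, [])
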