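"""Triangle subclassification: junction orientation, CN states, decision rules."""

import numpy as np
import pytest

from svmotif.graph import enumerate_cycles
from svmotif.model import CopyNumberSegment, Side
from svmotif.simulate import (
    PlantedCycleSpec,
    SimulationConfig,
    generate_dataset,
)
from svmotif.triangles import (
    CNState,
    ClassifierConfig,
    TriangleType,
    breakpoint_cn_state,
    classify_triangle,
    classify_triangles,
    cn_profile_oscillates,
    junction_inversion_flag,
    triangle_overlap_matrix,
    triangle_type_cancer_summary,
)
from svmotif.cluster import two_step_clustering
from svmotif.pipeline import build_graphs

from .conftest import make_adjacency

R, L = Side.EXTENDS_RIGHT, Side.EXTENDS_LEFT


class TestInversionFlag:
    @pytest.mark.parametrize(
        "s1, s2, inverted",
        [(R, L, False), (L, R, False), (R, R, True), (L, L, True)],
    )
    def test_same_side_means_inverted(self, s1, s2, inverted):
        adj = make_adjacency("a", "s", ("chr1", 100, s1), ("chr2", 200, s2))
        assert junction_inversion_flag(adj) is inverted


def segs(sample, chrom, triples):
    return [CopyNumberSegment(sample, chrom, a, b, cn) for a, b, cn in triples]


class TestCnState:
    def test_gain_loss_neutral_vs_flank_median(self):
        base = segs("s", "chr1", [(1, 900_000, 2), (900_001, 1_100_000, 3), (1_100_001, 3_000_000, 2)])
        state, covered = breakpoint_cn_state("s", "chr1", 1_000_000, base)
        assert (state, covered) == (CNState.GAIN, True)
        low = segs("s", "chr1", [(1, 900_000, 2), (900_001, 1_100_000, 1), (1_100_001, 3_000_000, 2)])
        assert breakpoint_cn_state("s", "chr1", 1_000_000, low)[0] == CNState.LOSS
        flat = segs("s", "chr1", [(1, 3_000_000, 2)])
        assert breakpoint_cn_state("s", "chr1", 1_000_000, flat)[0] == CNState.NEUTRAL

    def test_uncovered_peak_neutral_with_flag(self):
        state, covered = breakpoint_cn_state("s", "chr1", 999, segs("s", "chr2", [(1, 10, 2)]))
        assert (state, covered) == (CNState.NEUTRAL, False)


class TestOscillation:
    @pytest.mark.parametrize(
        "states, expected",
        [
            ((CNState.NEUTRAL, CNState.GAIN, CNState.NEUTRAL), True),
            ((CNState.GAIN, CNState.NEUTRAL, CNState.GAIN), True),
            ((CNState.NEUTRAL, CNState.NEUTRAL, CNState.GAIN), False),
            ((CNState.NEUTRAL, CNState.NEUTRAL, CNState.NEUTRAL), False),
            ((CNState.GAIN, CNState.LOSS, CNState.NEUTRAL), False),
        ],
    )
    def test_alternation_between_exactly_two_states(self, states, expected):
        assert cn_profile_oscillates(states) is expected


def triangle_fixture(inverted_pattern, cn_deltas, sample="s1"):
    """One planted triangle; returns (cycle, sample graph, lookup, cn segments)."""
    centers = [("chr1", 5_000_000), ("chr2", 5_000_000), ("chr3", 5_000_000)]
    spec = PlantedCycleSpec(
        sample_id="S000", size=3, inverted_pattern=inverted_pattern, centers=centers
    )
    config = SimulationConfig(
        n_samples=1, planted_cycles=[spec], jitter_sd=0.0, seed=1
    )
    dataset, _cn, _map, _manifest = generate_dataset(config)
    result = two_step_clustering(dataset)
    graphs = build_graphs(dataset.sample_ids, result)
    (cycle,) = enumerate_cycles(graphs["S000"])
    cn_segments = []
    for (chrom, pos), delta in zip(centers, cn_deltas):
        cn_segments += segs(
            "S000",
            chrom,
            [(1, pos - 50_000, 2), (pos - 49_999, pos + 50_000, 2 + delta), (pos + 50_001, 10_000_000, 2)],
        )
    lookup = {a.id: a for a in dataset.iter_adjacencies()}
    return cycle, graphs["S000"], lookup, cn_segments


class TestDecisionRules:
    def test_no_inversion_all_neutral_is_chromoplexy(self):
        cycle, sg, lookup, cn = triangle_fixture([False] * 3, [0, 0, 0])
        call = classify_triangle(cycle, sg, lookup, cn)
        assert call.label is TriangleType.CHROMOPLEXY
        assert call.n_inverted == 0

    def test_inverted_with_gain_is_templated_insertion(self):
        cycle, sg, lookup, cn = triangle_fixture([True, True, False], [1, 1, 1])
        call = classify_triangle(cycle, sg, lookup, cn)
        assert call.label is TriangleType.TEMPLATED_INSERTION_CYCLE

    def test_all_inverted_all_neutral_is_chromotrikona(self):
        cycle, sg, lookup, cn = triangle_fixture([True] * 3, [0, 0, 0])
        call = classify_triangle(cycle, sg, lookup, cn)
        assert call.label is TriangleType.CHROMOTRIKONA
        assert call.n_inverted == 3

    def test_inverted_oscillating_is_noncanonical_chromothripsis(self):
        """CN alternating 2-3-2 across the ordered clusters."""
        cycle, sg, lookup, cn = triangle_fixture([True, True, False], [0, 1, 0])
        call = classify_triangle(cycle, sg, lookup, cn)
        assert call.oscillating
        assert call.label is TriangleType.NONCANONICAL_CHROMOTHRIPSIS

    def test_minimal_loss_still_chromoplexy(self):
        cycle, sg, lookup, cn = triangle_fixture([False] * 3, [0, -1, 0])
        call = classify_triangle(cycle, sg, lookup, cn)
        assert call.label is TriangleType.CHROMOPLEXY

    def test_gain_without_enough_inversions_unclassified(self):
        cycle, sg, lookup, cn = triangle_fixture([False] * 3, [1, 1, 1])
        call = classify_triangle(cycle, sg, lookup, cn)
        assert call.label is TriangleType.UNCLASSIFIED

    def test_without_cn_data_restricted_labels_and_flag(self):
        cycle, sg, lookup, _cn = triangle_fixture([True] * 3, [0, 0, 0])
        call = classify_triangle(cycle, sg, lookup, None)
        assert call.label is TriangleType.CHROMOTRIKONA
        assert "no-CN" in call.flags
        cycle, sg, lookup, _cn = triangle_fixture([False] * 3, [0, 0, 0])
        call = classify_triangle(cycle, sg, lookup, None)
        assert call.label is TriangleType.CHROMOPLEXY

    def test_label_invariant_to_junction_ordering(self):
        cycle, sg, lookup, cn = triangle_fixture([True, False, True], [0, 1, 0])
        reference = classify_triangle(cycle, sg, lookup, cn).label
        # same edge set presented in shuffled order must classify identically
        from svmotif.graph import CycleOccurrence, canonical_cycle_key

        for rotation in range(3):
            vertices = cycle.vertices[rotation:] + cycle.vertices[:rotation]
            rotated = CycleOccurrence(
                sample_id=cycle.sample_id,
                size=3,
                edge_set=cycle.edge_set,
                canonical_key=cycle.canonical_key,
                vertices=vertices,
            )
            assert classify_triangle(rotated, sg, lookup, cn).label is reference

    def test_every_triangle_gets_exactly_one_label(self, planted_clustered):
        dataset, result, graphs = planted_clustered
        occurrences = [
            o for sg in graphs.values() for o in enumerate_cycles(sg) if o.size == 3
        ]
        lookup = {a.id: a for a in dataset.iter_adjacencies()}
        calls = classify_triangles(occurrences, graphs, lookup, None)
        assert len(calls) == len(occurrences)
        assert all(isinstance(c.label, TriangleType) for c in calls)


class TestOverlapMatrix:
    def _call(self, label, clusters, sample="s1"):
        from svmotif.triangles import TriangleCall

        return TriangleCall(
            cycle=None,
            inverted_flags=(False, False, False),
            cn_states=(CNState.NEUTRAL,) * 3,
            oscillating=False,
            label=label,
            cluster_ids=tuple(clusters),
        )

    def test_shared_cluster_counted_once(self):
        calls = [
            self._call(TriangleType.CHROMOPLEXY, ["c1", "c2", "c3"]),
            self._call(TriangleType.CHROMOTRIKONA, ["c3", "c4", "c5"]),
        ]
        matrix = triangle_overlap_matrix(calls)
        assert matrix.loc["chromoplexy", "chromotrikona"] == 1
        assert matrix.loc["chromotrikona", "chromoplexy"] == 1

    def test_disjoint_triangles_zero_off_diagonal(self):
        calls = [
            self._call(TriangleType.CHROMOPLEXY, ["c1", "c2", "c3"]),
            self._call(TriangleType.CHROMOTRIKONA, ["c4", "c5", "c6"]),
        ]
        matrix = triangle_overlap_matrix(calls)
        off = matrix.to_numpy().copy()
        np.fill_diagonal(off, 0)
        assert (off == 0).all()

    def test_symmetric_nonnegative(self):
        calls = [
            self._call(TriangleType.CHROMOPLEXY, ["c1", "c2", "c3"]),
            self._call(TriangleType.TEMPLATED_INSERTION_CYCLE, ["c2", "c3", "c7"]),
            self._call(TriangleType.CHROMOTRIKONA, ["c3", "c8", "c9"]),
        ]
        matrix = triangle_overlap_matrix(calls).to_numpy()
        assert (matrix == matrix.T).all()
        assert (matrix >= 0).all()


class TestCancerSummary:
    def test_small_cancer_types_excluded_and_ci_closed_form(self):
        from svmotif.graph import CycleOccurrence
        from svmotif.triangles import TriangleCall

        def call(sample, label):
            cycle = CycleOccurrence(
                sample_id=sample,
                size=3,
                edge_set=frozenset(
                    {frozenset((f"{sample}a", f"{sample}b")),
                     frozenset((f"{sample}b", f"{sample}c")),
                     frozenset((f"{sample}c", f"{sample}a"))}
                ),
                canonical_key=sample,
                vertices=(f"{sample}a", f"{sample}b", f"{sample}c"),
            )
            return TriangleCall(
                cycle=cycle,
                inverted_flags=(False,) * 3,
                cn_states=(CNState.NEUTRAL,) * 3,
                oscillating=False,
                label=label,
                cluster_ids=tuple(cycle.vertices),
            )

        calls = []
        cancer_map = {}
        # 12 samples of "Big": alternating 1 and 3 chromoplexy triangles
        for i in range(12):
            sample = f"B{i}"
            cancer_map[sample] = "Big"
            for _ in range(1 if i % 2 == 0 else 3):
                calls.append(call(sample, TriangleType.CHROMOPLEXY))
        # 9 samples of "Small" -> excluded
        for i in range(9):
            sample = f"M{i}"
            cancer_map[sample] = "Small"
            calls.append(call(sample, TriangleType.CHROMOPLEXY))
        summary = triangle_type_cancer_summary(calls, cancer_map, min_samples=10)
        assert set(summary["cancer_type"]) == {"Big"}
        row = summary[
            (summary["cancer_type"] == "Big")
            & (summary["triangle_type"] == "chromoplexy")
        ].iloc[0]
        values = np.array([1, 3] * 6, dtype=float)
        assert row["mean_frequency"] == pytest.approx(values.mean())
        assert row["ci95_half_width"] == pytest.approx(
            1.96 * values.std(ddof=1) / np.sqrt(12)
        )
        assert row["n_samples"] == 12

    def test_constant_counts_zero_halfwidth(self):
        from svmotif.graph import CycleOccurrence
        from svmotif.triangles import TriangleCall

        calls = []
        cancer_map = {}
        for i in range(10):
            sample = f"X{i}"
            cancer_map[sample] = "T"
            for j in range(2):
                cycle = CycleOccurrence(
                    sample_id=sample,
                    size=3,
                    edge_set=frozenset(
                        {frozenset((f"{sample}{j}a", f"{sample}{j}b")),
                         frozenset((f"{sample}{j}b", f"{sample}{j}c")),
                         frozenset((f"{sample}{j}c", f"{sample}{j}a"))}
                    ),
                    canonical_key=f"{sample}{j}",
                    vertices=(f"{sample}{j}a", f"{sample}{j}b", f"{sample}{j}c"),
                )
                calls.append(
                    TriangleCall(
                        cycle=cycle,
                        inverted_flags=(False,) * 3,
                        cn_states=(CNState.NEUTRAL,) * 3,
                        oscillating=False,
                        label=TriangleType.CHROMOPLEXY,
                        cluster_ids=tuple(cycle.vertices),
                    )
                )
        summary = triangle_type_cancer_summary(calls, cancer_map)
        row = summary[summary["triangle_type"] == "chromoplexy"].iloc[0]
        assert row["mean_frequency"] == 2.0
        assert row["ci95_half_width"] == 0.0
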