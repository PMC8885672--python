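"""Subclassification of triangle (size-3 cycle) patterns.

A triangle is described by the orientation of its three junctions and the
copy-number (CN) state at its three breakpoint clusters:

* a junction is *inverted* when both breakends retain the same flank
  (head-to-head or tail-to-tail);
* a cluster's CN state compares the segment containing the cluster peak
  against the median CN of flanking segments within a window (default
  1 Mb): gain at >= +1 copy, loss at <= -1 copy, else neutral;
* the CN profile *oscillates* when the states of the three clusters (in
  chromosome/position order) alternate between exactly two states.

With I = number of inverted junctions, the four classes are:

* **non-canonical chromothripsis** — I >= 2 with an oscillating CN profile;
* **templated-insertion cycle** — I >= 2 with at least one CN gain (and no
  oscillation, which takes precedence);
* **chromotrikona** — I >= 2 with an entirely neutral CN profile;
* **chromoplexy** — I <= 1 with no CN gain (neutral or minimal loss: a
  balanced closed chain of translocations).

Anything else is left unclassified.  Without CN data only the
orientation-driven labels (chromoplexy for I <= 1, chromotrikona for
I >= 2) are available and calls are flagged "no-CN".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .graph import CycleOccurrence, SampleGraph
from .model import Adjacency, CancerTypeMap, CopyNumberSegment

logger = logging.getLogger(__name__)


class CNState(str, Enum):
    GAIN = "gain"
    LOSS = "loss"
    NEUTRAL = "neutral"


class TriangleType(str, Enum):
    CHROMOPLEXY = "chromoplexy"
    TEMPLATED_INSERTION_CYCLE = "templated_insertion_cycle"
    NONCANONICAL_CHROMOTHRIPSIS = "noncanonical_chromothripsis"
    CHROMOTRIKONA = "chromotrikona"
    UNCLASSIFIED = "unclassified"


CANONICAL_TYPES = [
    TriangleType.CHROMOPLEXY,
    TriangleType.TEMPLATED_INSERTION_CYCLE,
    TriangleType.NONCANONICAL_CHROMOTHRIPSIS,
    TriangleType.CHROMOTRIKONA,
]


@dataclass
class ClassifierConfig:
    """Crisp thresholds for the qualitative class descriptions."""

    min_inverted: int = 2  # "frequent inverted rearrangements" = I >= 2
    cn_window: float = 1_000_000.0  # flank window around the cluster peak, bp
    gain_delta: float = 1.0  # gain if local - flank median >= +gain_delta
    loss_delta: float = 1.0  # loss if local - flank median <= -loss_delta


def junction_inversion_flag(adjacency: Adjacency) -> bool:
    """True iff both breakends retain the same flank (inverted junction)."""
    return adjacency.end_a.side == adjacency.end_b.side


def breakpoint_cn_state(
    sample_id: str,
    chrom: str,
    peak_pos: float,
    cn_segments: Sequence[CopyNumberSegment],
    window: float = 1_000_000.0,
    gain_delta: float = 1.0,
    loss_delta: float = 1.0,
) -> tuple[CNState, bool]:
    """CN state at a cluster peak: local segment vs. flank median.

    Returns ``(state, covered)``; an uncovered peak is neutral with
    ``covered=False``.
    """
    local = [
        s
        for s in cn_segments
        if s.sample_id == sample_id and s.chrom == chrom and s.contains(int(peak_pos))
    ]
    if not local:
        return CNState.NEUTRAL, False
    local_seg = local[0]
    lo, hi = int(peak_pos - window), int(peak_pos + window)
    flank = [
        s.total_cn
        for s in cn_segments
        if s.sample_id == sample_id
        and s.chrom == chrom
        and s.overlaps(lo, hi)
        and s is not local_seg
    ]
    if not flank:
        return CNState.NEUTRAL, True
    diff = local_seg.total_cn - float(np.median(flank))
    if diff >= gain_delta:
        return CNState.GAIN, True
    if diff <= -loss_delta:
        return CNState.LOSS, True
    return CNState.NEUTRAL, True


def cn_profile_oscillates(states: Sequence[CNState]) -> bool:
    """True iff the ordered states alternate between exactly two states
    (pattern A-B-A for a triangle)."""
    if len(set(states)) != 2:
        return False
    return all(a != b for a, b in zip(states, states[1:]))


@dataclass
class TriangleCall:
    cycle: CycleOccurrence
    inverted_flags: tuple[bool, bool, bool]
    cn_states: tuple[CNState, ...]
    oscillating: bool
    label: TriangleType
    cluster_ids: tuple[str, str, str]  # in (chrom, peak_pos) order
    flags: list[str] = field(default_factory=list)

    @property
    def n_inverted(self) -> int:
        return sum(self.inverted_flags)

    @property
    def sample_id(self) -> str:
        return self.cycle.sample_id


def classify_triangle(
    cycle: CycleOccurrence,
    sample_graph: SampleGraph,
    adjacency_lookup: Mapping[str, Adjacency],
    cn_segments: Sequence[CopyNumberSegment] | None,
    config: ClassifierConfig | None = None,
) -> TriangleCall:
    """Classify one size-3 cycle.

    Junction orientations come from each edge's first contributing
    adjacency; CN states are evaluated at the three cluster peaks.  The
    decision rules depend only on the edge set, so the label is invariant to
    any rotation/reflection of the cycle.
    """
    if cycle.size != 3:
        raise ValueError("triangle classification needs a size-3 cycle")
    config = config or ClassifierConfig()
    g = sample_graph.graph
    flags: list[str] = []

    edges = sorted(tuple(sorted(e)) for e in cycle.edge_set)
    inverted = []
    for u, v in edges:
        adj_ids = g.edges[u, v]["adjacencies"]
        inverted.append(junction_inversion_flag(adjacency_lookup[adj_ids[0]]))
    inverted_flags = tuple(inverted)
    n_inverted = sum(inverted_flags)

    vertices = sorted(
        {v for e in cycle.edge_set for v in e}, key=sample_graph.vertex_sort_key
    )
    if cn_segments is None:
        cn_states = tuple(CNState.NEUTRAL for _ in vertices)
        oscillating = False
        flags.append("no-CN")
        label = (
            TriangleType.CHROMOTRIKONA
            if n_inverted >= config.min_inverted
            else TriangleType.CHROMOPLEXY
        )
        return TriangleCall(
            cycle=cycle,
            inverted_flags=inverted_flags,
            cn_states=cn_states,
            oscillating=oscillating,
            label=label,
            cluster_ids=tuple(vertices),
            flags=flags,
        )

    states = []
    for v in vertices:
        data = g.nodes[v]
        state, covered = breakpoint_cn_state(
            cycle.sample_id,
            data["chrom"],
            data["peak_pos"],
            cn_segments,
            window=config.cn_window,
            gain_delta=config.gain_delta,
            loss_delta=config.loss_delta,
        )
        if not covered:
            flags.append(f"uncovered:{v}")
        states.append(state)
    cn_states = tuple(states)
    oscillating = cn_profile_oscillates(cn_states)

    if n_inverted >= config.min_inverted and oscillating:
        label = TriangleType.NONCANONICAL_CHROMOTHRIPSIS
    elif n_inverted >= config.min_inverted and CNState.GAIN in cn_states:
        label = TriangleType.TEMPLATED_INSERTION_CYCLE
    elif n_inverted >= config.min_inverted and all(
        s is CNState.NEUTRAL for s in cn_states
    ):
        label = TriangleType.CHROMOTRIKONA
    elif n_inverted < config.min_inverted and CNState.GAIN not in cn_states:
        label = TriangleType.CHROMOPLEXY
    else:
        label = TriangleType.UNCLASSIFIED
    return TriangleCall(
        cycle=cycle,
        inverted_flags=inverted_flags,
        cn_states=cn_states,
        oscillating=oscillating,
        label=label,
        cluster_ids=tuple(vertices),
        flags=flags,
    )


def classify_triangles(
    occurrences: Sequence[CycleOccurrence],
    graphs: Mapping[str, SampleGraph],
    adjacency_lookup: Mapping[str, Adjacency],
    cn_segments: Sequence[CopyNumberSegment] | None,
    config: ClassifierConfig | None = None,
) -> list[TriangleCall]:
    """Classify every size-3 occurrence in the mined set."""
    return [
        classify_triangle(
            occ, graphs[occ.sample_id], adjacency_lookup, cn_segments, config
        )
        for occ in occurrences
        if occ.size == 3
    ]


def triangle_overlap_matrix(
    calls: Sequence[TriangleCall],
    types: Sequence[TriangleType] = tuple(CANONICAL_TYPES),
) -> pd.DataFrame:
    """Symmetric matrix of clusters shared between every pair of triangle types.

    Entry (X, Y) counts clusters that appear in at least one triangle of
    type X and at least one of type Y; the diagonal counts each type's
    distinct clusters.
    """
    clusters_by_type: dict[TriangleType, set[str]] = {t: set() for t in types}
    for call in calls:
        if call.label in clusters_by_type:
            clusters_by_type[call.label].update(call.cluster_ids)
    labels = [t.value for t in types]
    matrix = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for x in types:
        for y in types:
            matrix.loc[x.value, y.value] = len(
                clusters_by_type[x] & clusters_by_type[y]
            )
    return matrix


def triangle_type_cancer_summary(
    calls: Sequence[TriangleCall],
    cancer_map: CancerTypeMap,
    min_samples: int = 10,
    types: Sequence[TriangleType] = tuple(CANONICAL_TYPES),
) -> pd.DataFrame:
    """Per cancer type x triangle type: mean per-sample frequency with 95% CI.

    Only cancer types with at least *min_samples* triangle-bearing samples
    are included; the CI is the normal approximation
    mean +/- 1.96 * SD / sqrt(n) over the type's triangle-bearing samples.
    """
    missing = {c.sample_id for c in calls} - set(cancer_map)
    if missing:
        raise ValueError(f"cancer map does not cover samples: {sorted(missing)}")
    counts: dict[str, dict[TriangleType, int]] = {}
    for call in calls:
        counts.setdefault(call.sample_id, {t: 0 for t in types})
        if call.label in counts[call.sample_id]:
            counts[call.sample_id][call.label] += 1
    by_cancer: dict[str, list[str]] = {}
    for sample_id in counts:
        by_cancer.setdefault(cancer_map[sample_id], []).append(sample_id)
    rows = []
    for cancer_type in sorted(by_cancer):
        samples = by_cancer[cancer_type]
        if len(samples) < min_samples:
            logger.info(
                "excluding cancer type %s: only %d triangle-bearing samples",
                cancer_type,
                len(samples),
            )
            continue
        n = len(samples)
        for t in types:
            values = np.array([counts[s][t] for s in samples], dtype=float)
            mean = float(values.mean())
            sd = float(values.std(ddof=1)) if n > 1 else 0.0
            rows.append(
                {
                    "cancer_type": cancer_type,
                    "triangle_type": t.value,
                    "mean_frequency": mean,
                    "ci95_half_width": 1.96 * sd / np.sqrt(n),
                    "n_samples": n,
                }
            )
    return pd.DataFrame(rows)


def calls_to_frame(calls: Sequence[TriangleCall]) -> pd.DataFrame:
    """TSV-ready triangle-call table."""
    return pd.DataFrame(
        [
            {
                "sample": c.sample_id,
                "cluster_1": c.cluster_ids[0],
                "cluster_2": c.cluster_ids[1],
                "cluster_3": c.cluster_ids[2],
                "n_inverted": c.n_inverted,
                "cn_states": ",".join(s.value for s in c.cn_states),
                "oscillating": c.oscillating,
                "label": c.label.value,
                "flags": ";".join(c.flags),
            }
            for c in calls
        ]
    )
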