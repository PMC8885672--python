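"""Degree-preserving edge-switching null model and the Abundance statistic.

The null keeps every sample's vertex set, per-sample edge count and the
pooled degree multiset fixed, and randomizes which clusters are joined:
repeatedly pick two random edges A-B and C-D from the pooled, sample-tagged
edge list and exchange their ends to form A-D and C-B.  A move that would
create a self-loop or duplicate an existing edge within an affected sample
is rejected (but still counts toward the attempt budget).  After
``multiplier x E`` attempted switches (E = total edges across all samples)
the edge set is considered randomized; N independent such datasets form the
ensemble.

A pattern's over/under-representation is the Abundance

    delta = (f_input - mean(f_random)) / (f_input + mean(f_random) + epsilon)

where f_input is the pattern frequency in the real data, f_random its
frequency in each randomized dataset and epsilon a Laplace pseudo-count
keeping the ratio defined when frequencies are small.  delta ranges from -1
(underrepresented) to +1 (overrepresented); the single-edge pattern is an
exact control at 0 because edge counts are conserved by the null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .graph import SampleGraph, enumerate_cycles
from .model import CancerTypeMap

logger = logging.getLogger(__name__)

#: One pooled edge: (sample_id, u, v).
TaggedEdge = tuple[str, str, str]


@dataclass
class SwitchingConfig:
    n_datasets: int = 100
    multiplier: int = 100  # switches per dataset = multiplier x E
    epsilon: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_datasets < 1:
            raise ValueError("n_datasets must be >= 1")
        if self.multiplier < 1:
            raise ValueError("multiplier must be >= 1")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")


def pooled_edges(graphs: Iterable[SampleGraph]) -> list[TaggedEdge]:
    """Sample-tagged pooled edge list across all sample graphs (sorted)."""
    edges: list[TaggedEdge] = []
    for sg in graphs:
        for u, v in sg.graph.edges:
            a, b = sorted((u, v))
            edges.append((sg.sample_id, a, b))
    edges.sort()
    return edges


def switch_edges(
    edges: Sequence[TaggedEdge], n_switches: int, rng: np.random.Generator
) -> list[TaggedEdge]:
    """Attempt *n_switches* degree-preserving switches on the pooled edge list.

    Each attempt draws two distinct edges A-B (sample s1) and C-D (sample
    s2), flips each stored endpoint order uniformly, and proposes replacing
    them with A-D (in s1) and C-B (in s2).  The proposal is rejected — but
    still consumes an attempt — if either new edge would be a self-loop or
    duplicate an existing edge of its sample.  Degrees, per-sample edge
    counts and the total edge count are conserved by construction.
    """
    if len(edges) < 2:
        logger.warning("fewer than 2 edges: nothing to switch")
        return list(edges)
    out: list[list] = [list(e) for e in edges]
    per_sample: dict[str, set[frozenset]] = {}
    for s, u, v in out:
        per_sample.setdefault(s, set()).add(frozenset((u, v)))
    n = len(out)
    accepted = 0
    for _ in range(n_switches):
        i = int(rng.integers(n))
        j = int(rng.integers(n - 1))
        if j >= i:
            j += 1
        s1, a, b = out[i]
        s2, c, d = out[j]
        if rng.integers(2):
            a, b = b, a
        if rng.integers(2):
            c, d = d, c
        new1, new2 = frozenset((a, d)), frozenset((c, b))
        if a == d or c == b:
            continue
        old1, old2 = frozenset((a, b)), frozenset((c, d))
        set1, set2 = per_sample[s1], per_sample[s2]
        set1.discard(old1)
        set2.discard(old2)
        ok = new1 not in set1 and new2 not in set2 and not (s1 == s2 and new1 == new2)
        if ok:
            set1.add(new1)
            set2.add(new2)
            out[i] = [s1, *sorted((a, d))]
            out[j] = [s2, *sorted((c, b))]
            accepted += 1
        else:
            set1.add(old1)
            set2.add(old2)
    logger.debug("switching: %d/%d moves accepted", accepted, n_switches)
    return [tuple(e) for e in out]


def _graphs_from_edges(
    edges: Sequence[TaggedEdge],
    sample_ids: Sequence[str],
    vertex_attrs: Mapping[str, dict],
) -> dict[str, SampleGraph]:
    """Rebuild per-sample graphs from a (possibly switched) pooled edge list.

    Cluster vertices are loci reusable across samples, so a switched edge
    may join vertices that originated in different samples' clusterings.
    """
    graphs: dict[str, nx.Graph] = {s: nx.Graph() for s in sample_ids}
    for s, u, v in edges:
        g = graphs.setdefault(s, nx.Graph())
        for w in (u, v):
            if w not in g:
                g.add_node(w, **vertex_attrs.get(w, {}))
        g.add_edge(u, v)
    return {s: SampleGraph(sample_id=s, graph=g) for s, g in graphs.items()}


def global_vertex_attrs(graphs: Iterable[SampleGraph]) -> dict[str, dict]:
    attrs: dict[str, dict] = {}
    for sg in graphs:
        for v, data in sg.graph.nodes(data=True):
            attrs.setdefault(v, dict(data))
    return attrs


def randomized_dataset_ensemble(
    graphs: Sequence[SampleGraph], config: SwitchingConfig | None = None
) -> list[dict[str, SampleGraph]]:
    """N independently edge-switched copies of the real sample graphs.

    Every dataset is switched from the original with multiplier x E
    attempts; per-sample edge counts equal the originals in every dataset.
    """
    config = config or SwitchingConfig()
    edges = pooled_edges(graphs)
    e_total = len(edges)
    sample_ids = [sg.sample_id for sg in graphs]
    attrs = global_vertex_attrs(graphs)
    rng = np.random.default_rng(config.seed)
    ensemble = []
    for _ in range(config.n_datasets):
        switched = switch_edges(edges, config.multiplier * e_total, rng)
        ensemble.append(_graphs_from_edges(switched, sample_ids, attrs))
    return ensemble


def abundance(
    f_input: float, f_random_values: Sequence[float], epsilon: float = 1.0
) -> float:
    """Abundance delta of a pattern versus the randomized ensemble."""
    if f_input < 0 or any(v < 0 for v in f_random_values):
        raise ValueError("frequencies must be non-negative")
    f_random_mean = float(np.mean(f_random_values)) if len(f_random_values) else 0.0
    denominator = f_input + f_random_mean + epsilon
    if denominator == 0:
        raise ValueError("abundance undefined: f_input = f_random = epsilon = 0")
    return (f_input - f_random_mean) / denominator


@dataclass
class AbundanceResult:
    pattern: str  # "edge" or the cycle size as a string
    f_input: float
    f_random_values: list[float] = field(repr=False, default_factory=list)
    f_random_mean: float = 0.0
    delta: float = 0.0


def _frequencies(
    graphs: Mapping[str, SampleGraph] | Sequence[SampleGraph],
    sizes: Sequence[int],
    samples: set[str] | None,
) -> dict[str, float]:
    """Pattern frequencies (total deduplicated edges, and cycles per size)."""
    if isinstance(graphs, Mapping):
        graphs = list(graphs.values())
    freq: dict[str, float] = {"edge": 0.0, **{str(k): 0.0 for k in sizes}}
    for sg in graphs:
        if samples is not None and sg.sample_id not in samples:
            continue
        freq["edge"] += sg.n_edges
        for occ in enumerate_cycles(sg, k_min=min(sizes), k_max=max(sizes)):
            if occ.size in sizes:
                freq[str(occ.size)] += 1
    return freq


def motif_abundance_report(
    real_graphs: Sequence[SampleGraph],
    ensemble: Sequence[Mapping[str, SampleGraph]],
    sizes: Sequence[int] = (3, 4, 5, 6),
    epsilon: float = 1.0,
    cancer_map: CancerTypeMap | None = None,
    cancer_filter: str | None = None,
) -> list[AbundanceResult]:
    """Abundance per cycle size plus the single-edge control row.

    With *cancer_filter*, frequencies on both sides are restricted to that
    type's samples before the delta is computed (the ensemble itself is the
    global one).
    """
    samples: set[str] | None = None
    if cancer_filter is not None:
        if cancer_map is None:
            raise ValueError("cancer_filter requires a cancer_map")
        samples = {s for s, t in cancer_map.items() if t == cancer_filter}
        if not samples:
            logger.warning("cancer type %r has no samples; skipping", cancer_filter)
            return []
    f_real = _frequencies(real_graphs, sizes, samples)
    f_rand = [_frequencies(d, sizes, samples) for d in ensemble]
    results = []
    for pattern in ["edge", *[str(k) for k in sizes]]:
        values = [fr[pattern] for fr in f_rand]
        results.append(
            AbundanceResult(
                pattern=pattern,
                f_input=f_real[pattern],
                f_random_values=values,
                f_random_mean=float(np.mean(values)) if values else 0.0,
                delta=abundance(f_real[pattern], values, epsilon),
            )
        )
    return results


def abundance_frame(
    results: Sequence[AbundanceResult],
    n_datasets: int,
    epsilon: float,
    cancer_type: str | None = None,
) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "pattern": r.pattern,
            "f_input": r.f_input,
            "f_random_mean": r.f_random_mean,
            "delta": r.delta,
            "n_datasets": n_datasets,
            "epsilon": epsilon,
        }
        if cancer_type is not None:
            row["cancer_type"] = cancer_type
        rows.append(row)
    return pd.DataFrame(rows)
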