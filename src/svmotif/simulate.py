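"""Synthetic SV datasets with known ground truth.

The generator emulates the features of tumor SV call sets that the pipeline
exploits: breakpoints concentrated at recurrent genomic loci (tight clusters
with small jitter), per-sample junction sets that close into cycles of 3-6
clusters, junction orientation patterns, and step-wise copy-number profiles
around planted cycles.  Everything else (background noise) is uniform random
pairing.  Alongside the dataset a manifest records the planted truth so that
cluster recovery, cycle recovery and triangle labels can be scored exactly.

Defaults: breakend jitter SD 50 bp (well under the round-2 bandwidth of
400 bp, so planted clusters survive both clustering rounds), planted cluster
centers at least 1 Mb apart, CN baseline 2 with +/-1 integer steps over
100 kb windows to realize gain/loss archetypes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .graph import CycleOccurrence, SampleGraph
from .model import (
    Adjacency,
    Breakend,
    CancerTypeMap,
    CopyNumberSegment,
    SVDataset,
    Side,
)
from .triangles import TriangleType

logger = logging.getLogger(__name__)

DEFAULT_GENOME = {
    "chr1": 60_000_000,
    "chr2": 55_000_000,
    "chr3": 50_000_000,
    "chr4": 45_000_000,
    "chr5": 40_000_000,
}

#: archetype -> (inverted pattern for 3 junctions, CN deltas per sorted vertex)
TRIANGLE_ARCHETYPES: dict[str, tuple[list[bool], list[float]]] = {
    TriangleType.CHROMOPLEXY.value: ([False, False, False], [0, 0, 0]),
    TriangleType.TEMPLATED_INSERTION_CYCLE.value: ([True, True, True], [1, 1, 1]),
    TriangleType.NONCANONICAL_CHROMOTHRIPSIS.value: ([True, True, True], [0, 1, 0]),
    TriangleType.CHROMOTRIKONA.value: ([True, True, True], [0, 0, 0]),
}


@dataclass
class PlantedCycleSpec:
    """One cycle to plant: k cluster centers chained into a closed ring."""

    sample_id: str
    size: int
    archetype: str | None = None  # triangle archetype name, or None
    inverted_pattern: list[bool] | None = None  # per junction; default per archetype
    centers: list[tuple[str, int]] | None = None  # auto-drawn if None

    def __post_init__(self) -> None:
        if not 3 <= self.size <= 6:
            raise ValueError(f"cycle size {self.size} outside [3, 6]")
        if self.archetype is not None:
            if self.size != 3:
                raise ValueError("triangle archetypes require size 3")
            if self.archetype not in TRIANGLE_ARCHETYPES:
                raise ValueError(f"unknown archetype {self.archetype!r}")


@dataclass
class SimulationConfig:
    genome: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GENOME))
    n_samples: int = 10
    background_adjacencies: int | Sequence[int] = 0  # per sample (scalar or per-sample list)
    planted_cycles: list[PlantedCycleSpec] = field(default_factory=list)
    jitter_sd: float = 50.0
    cn_baseline: float = 2.0
    cn_halfwidth: int = 50_000  # half-width of CN step windows around centers
    center_min_separation: int = 1_000_000
    cancer_types: list[str] = field(default_factory=lambda: ["SimCA"])
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.jitter_sd < 0:
            problems.append("jitter_sd must be >= 0")
        if any(length <= 0 for length in self.genome.values()):
            problems.append("chromosome lengths must be positive")
        if self.n_samples < 1:
            problems.append("n_samples must be >= 1")
        counts = self.background_counts
        if len(counts) != self.n_samples or any(c < 0 for c in counts):
            problems.append(
                "background_adjacencies must be a non-negative int or one per sample"
            )
        sample_ids = set(self.sample_ids)
        for spec in self.planted_cycles:
            if spec.sample_id not in sample_ids:
                problems.append(f"planted cycle in unknown sample {spec.sample_id!r}")
            if spec.centers is not None:
                if len(spec.centers) != spec.size:
                    problems.append(
                        f"cycle in {spec.sample_id}: {len(spec.centers)} centers "
                        f"for size {spec.size}"
                    )
                for chrom, _pos in spec.centers:
                    if chrom not in self.genome:
                        problems.append(f"center on unknown chromosome {chrom!r}")
        if problems:
            raise ValueError("invalid simulation config: " + "; ".join(problems))

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i:03d}" for i in range(self.n_samples)]

    @property
    def background_counts(self) -> list[int]:
        if isinstance(self.background_adjacencies, int):
            return [self.background_adjacencies] * self.n_samples
        return list(self.background_adjacencies)


@dataclass
class GroundTruthManifest:
    """Planted truth: cluster centers, cycle edge sets and triangle labels."""

    centers: list[dict]  # {id, chrom, pos}
    cycles: list[dict]  # {sample, size, center_ids, archetype, label}
    per_sample_counts: dict[str, dict[str, int]]
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "centers": self.centers,
                    "cycles": self.cycles,
                    "per_sample_counts": self.per_sample_counts,
                    "seed": self.seed,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthManifest":
        data = json.loads(Path(path).read_text())
        return cls(
            centers=data["centers"],
            cycles=data["cycles"],
            per_sample_counts=data["per_sample_counts"],
            seed=data["seed"],
        )


def _draw_center(
    genome: Mapping[str, int],
    existing: list[tuple[str, int]],
    min_separation: int,
    rng: np.random.Generator,
) -> tuple[str, int]:
    chroms = sorted(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    margin = min_separation
    for _ in range(10_000):
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        pos = int(rng.integers(margin, genome[chrom] - margin))
        if all(
            c != chrom or abs(pos - p) >= min_separation for c, p in existing
        ):
            return chrom, pos
    raise RuntimeError("could not place a cluster center; genome too crowded")


def plant_cycle(
    spec: PlantedCycleSpec,
    centers: Sequence[tuple[str, int]],
    jitter_sd: float,
    rng: np.random.Generator,
    id_prefix: str,
) -> tuple[list[Adjacency], list[tuple[str, int, float]]]:
    """Materialize one planted cycle.

    Returns the k junction adjacencies chaining the k centers into a closed
    ring (each breakend jittered N(0, jitter_sd^2)) and the CN deviations
    ``(chrom, center_pos, delta)`` realizing the archetype.
    """
    k = spec.size
    if len(centers) < k:
        raise ValueError(f"need {k} centers, got {len(centers)}")
    centers = list(centers)[:k]
    if spec.inverted_pattern is not None:
        pattern = list(spec.inverted_pattern)
    elif spec.archetype is not None:
        pattern = list(TRIANGLE_ARCHETYPES[spec.archetype][0])
    else:
        pattern = [False] * k
    if len(pattern) != k:
        raise ValueError("inverted pattern length must equal cycle size")

    def jittered(center: tuple[str, int]) -> tuple[str, int]:
        chrom, pos = center
        if jitter_sd > 0:
            pos = max(1, int(round(pos + rng.normal(0.0, jitter_sd))))
        return chrom, pos

    adjacencies = []
    for m in range(k):
        (c1, p1) = jittered(centers[m])
        (c2, p2) = jittered(centers[(m + 1) % k])
        if pattern[m]:
            s1 = s2 = Side.EXTENDS_LEFT
        else:
            s1, s2 = Side.EXTENDS_RIGHT, Side.EXTENDS_LEFT
        adjacencies.append(
            Adjacency(
                id=f"{id_prefix}j{m}",
                sample_id=spec.sample_id,
                end_a=Breakend(spec.sample_id, c1, p1, s1),
                end_b=Breakend(spec.sample_id, c2, p2, s2),
            )
        )

    cn_deviations: list[tuple[str, int, float]] = []
    if spec.archetype is not None:
        deltas = TRIANGLE_ARCHETYPES[spec.archetype][1]
        # deltas are indexed by (chrom, pos)-sorted vertex order
        order = sorted(range(k), key=lambda i: centers[i])
        for rank, idx in enumerate(order):
            delta = deltas[rank]
            if delta != 0:
                chrom, pos = centers[idx]
                cn_deviations.append((chrom, pos, float(delta)))
    return adjacencies, cn_deviations


def _cn_segments_for_sample(
    sample_id: str,
    genome: Mapping[str, int],
    deviations: Sequence[tuple[str, int, float]],
    baseline: float,
    halfwidth: int,
) -> list[CopyNumberSegment]:
    """Step-wise CN profile: baseline everywhere, steps around deviations."""
    by_chrom: dict[str, list[tuple[int, float]]] = {}
    for chrom, pos, delta in deviations:
        by_chrom.setdefault(chrom, []).append((pos, delta))
    segments: list[CopyNumberSegment] = []
    for chrom in sorted(genome):
        length = genome[chrom]
        cursor = 1
        for pos, delta in sorted(by_chrom.get(chrom, [])):
            lo = max(1, pos - halfwidth)
            hi = min(length, pos + halfwidth)
            if lo > cursor:
                segments.append(
                    CopyNumberSegment(sample_id, chrom, cursor, lo - 1, baseline)
                )
            segments.append(
                CopyNumberSegment(sample_id, chrom, lo, hi, baseline + delta)
            )
            cursor = hi + 1
        if cursor <= length:
            segments.append(
                CopyNumberSegment(sample_id, chrom, cursor, length, baseline)
            )
    return segments


def generate_dataset(
    config: SimulationConfig,
) -> tuple[SVDataset, list[CopyNumberSegment], CancerTypeMap, GroundTruthManifest]:
    """Generate a synthetic dataset, its CN profile and its truth manifest."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    sample_ids = config.sample_ids
    samples: dict[str, list[Adjacency]] = {s: [] for s in sample_ids}
    all_centers: list[tuple[str, int]] = []
    center_ids: dict[tuple[str, int], str] = {}
    manifest_cycles: list[dict] = []
    cn_dev_by_sample: dict[str, list[tuple[str, int, float]]] = {
        s: [] for s in sample_ids
    }

    def register_center(center: tuple[str, int]) -> str:
        if center not in center_ids:
            center_ids[center] = f"L{len(center_ids):03d}"
            all_centers.append(center)
        return center_ids[center]

    for i, spec in enumerate(config.planted_cycles):
        if spec.centers is not None:
            centers = [(c, int(p)) for c, p in spec.centers]
            for center in centers:
                register_center(center)
        else:
            centers = []
            for _ in range(spec.size):
                center = _draw_center(
                    config.genome, all_centers, config.center_min_separation, rng
                )
                register_center(center)
                centers.append(center)
        adjacencies, deviations = plant_cycle(
            spec, centers, config.jitter_sd, rng, id_prefix=f"{spec.sample_id}.c{i}."
        )
        samples[spec.sample_id].extend(adjacencies)
        cn_dev_by_sample[spec.sample_id].extend(deviations)
        manifest_cycles.append(
            {
                "sample": spec.sample_id,
                "size": spec.size,
                "center_ids": [center_ids[c] for c in centers],
                "centers": [[c, p] for c, p in centers],
                "archetype": spec.archetype,
                "label": spec.archetype,
            }
        )

    chroms = sorted(config.genome)
    lengths = np.array([config.genome[c] for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    for sample_id, n_background in zip(sample_ids, config.background_counts):
        for b in range(n_background):
            ends = []
            for _ in range(2):
                chrom = chroms[int(rng.choice(len(chroms), p=weights))]
                pos = int(rng.integers(1, config.genome[chrom] + 1))
                side = Side.EXTENDS_LEFT if rng.integers(2) else Side.EXTENDS_RIGHT
                ends.append(Breakend(sample_id, chrom, pos, side))
            samples[sample_id].append(
                Adjacency(
                    id=f"{sample_id}.bg{b}",
                    sample_id=sample_id,
                    end_a=ends[0],
                    end_b=ends[1],
                )
            )

    dataset = SVDataset(samples=samples, genome=dict(config.genome))
    cn_segments: list[CopyNumberSegment] = []
    for sample_id in sample_ids:
        cn_segments.extend(
            _cn_segments_for_sample(
                sample_id,
                config.genome,
                cn_dev_by_sample[sample_id],
                config.cn_baseline,
                config.cn_halfwidth,
            )
        )
    cancer_map: CancerTypeMap = {
        s: config.cancer_types[i % len(config.cancer_types)]
        for i, s in enumerate(sample_ids)
    }
    per_sample_counts = {
        s: {
            "adjacencies": len(samples[s]),
            "planted_cycles": sum(1 for c in manifest_cycles if c["sample"] == s),
        }
        for s in sample_ids
    }
    manifest = GroundTruthManifest(
        centers=[
            {"id": center_ids[c], "chrom": c[0], "pos": c[1]} for c in all_centers
        ],
        cycles=manifest_cycles,
        per_sample_counts=per_sample_counts,
        seed=config.seed,
    )
    return dataset, cn_segments, cancer_map, manifest


def verify_manifest(
    dataset: SVDataset, manifest: GroundTruthManifest, jitter_tol: float = 500.0
) -> None:
    """Independent consistency check of manifest against the emitted dataset.

    Verifies per-sample adjacency counts and that every planted cycle's
    centers are hit by breakends of the right sample within *jitter_tol* bp.
    Raises ``AssertionError`` on any inconsistency.
    """
    for sample_id, expected in manifest.per_sample_counts.items():
        actual = len(dataset.samples.get(sample_id, []))
        assert actual == expected["adjacencies"], (
            f"sample {sample_id}: {actual} adjacencies, "
            f"manifest says {expected['adjacencies']}"
        )
    for cycle in manifest.cycles:
        sample_id = cycle["sample"]
        ends = [
            end
            for adj in dataset.samples.get(sample_id, [])
            for end in adj.ends
        ]
        for chrom, pos in cycle["centers"]:
            hits = [
                e for e in ends if e.chrom == chrom and abs(e.pos - pos) <= jitter_tol
            ]
            assert len(hits) >= 2, (
                f"center {chrom}:{pos} of a planted cycle in {sample_id} "
                f"is hit by {len(hits)} breakends (expected >= 2)"
            )


def match_planted_cycles(
    manifest: GroundTruthManifest,
    occurrences: Sequence[CycleOccurrence],
    graphs: Mapping[str, SampleGraph],
    tol: float = 1000.0,
) -> tuple[int, int]:
    """Score recovery: (number of planted cycles recovered, number planted).

    A planted cycle is recovered when a mined cycle of the same size in the
    same sample has every vertex peak within *tol* bp of a distinct planted
    center.
    """
    recovered = 0
    for cycle in manifest.cycles:
        sample_id = cycle["sample"]
        centers = [(c, int(p)) for c, p in cycle["centers"]]
        if sample_id not in graphs:
            continue
        nodes = graphs[sample_id].graph.nodes
        hit = False
        for occ in occurrences:
            if occ.sample_id != sample_id or occ.size != cycle["size"]:
                continue
            remaining = list(centers)
            for v in set(occ.vertices):
                data = nodes[v]
                match = next(
                    (
                        c
                        for c in remaining
                        if c[0] == data["chrom"] and abs(c[1] - data["peak_pos"]) <= tol
                    ),
                    None,
                )
                if match is None:
                    break
                remaining.remove(match)
            else:
                if not remaining:
                    hit = True
                    break
        recovered += hit
    return recovered, len(manifest.cycles)


def expected_triangle_labels(manifest: GroundTruthManifest) -> dict[str, list[str]]:
    """Planted triangle labels per sample (archetype cycles of size 3 only)."""
    labels: dict[str, list[str]] = {}
    for cycle in manifest.cycles:
        if cycle["size"] == 3 and cycle["archetype"] is not None:
            labels.setdefault(cycle["sample"], []).append(cycle["archetype"])
    return labels


def background_split(total: int, n_samples: int) -> list[int]:
    """Split a dataset-total background count into per-sample counts."""
    base, extra = divmod(total, n_samples)
    return [base + (i < extra) for i in range(n_samples)]


def simple_config(
    n_samples: int = 10,
    n_triangles: int = 0,
    background_adjacencies: int | Sequence[int] = 0,
    archetypes: Sequence[str] = tuple(TRIANGLE_ARCHETYPES),
    seed: int = 0,
    **kwargs,
) -> SimulationConfig:
    """Convenience config: *n_triangles* planted across samples round-robin,
    cycling through the given archetypes."""
    sample_ids = [f"S{i:03d}" for i in range(n_samples)]
    planted = [
        PlantedCycleSpec(
            sample_id=sample_ids[i % n_samples],
            size=3,
            archetype=archetypes[i % len(archetypes)],
        )
        for i in range(n_triangles)
    ]
    return SimulationConfig(
        n_samples=n_samples,
        background_adjacencies=background_adjacencies,
        planted_cycles=planted,
        seed=seed,
        **kwargs,
    )
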