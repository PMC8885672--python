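"""Core data model for structural-variant junction analysis.

A structural variant (SV) is recorded as a novel *adjacency*: a junction
joining two *breakends*, each of which is a genomic position plus an
orientation saying which flank of the position is retained in the derived
chromosome.  A dataset is a collection of per-sample adjacency lists over a
declared genome (chromosome name -> length).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping

logger = logging.getLogger(__name__)


class Side(str, Enum):
    """Which flank of the breakend position is retained/joined onward."""

    EXTENDS_RIGHT = "extends_right"
    EXTENDS_LEFT = "extends_left"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class Breakend:
    """One side of a chromosomal break."""

    sample_id: str
    chrom: str
    pos: int  # 1-based
    side: Side

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"breakend position must be >= 1, got {self.pos}")
        if not isinstance(self.side, Side):
            object.__setattr__(self, "side", Side(self.side))

    @property
    def sort_key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.side.value)


@dataclass(frozen=True)
class Adjacency:
    """An SV junction tying two breakends of one sample.

    The pair is unordered: ends are stored in canonical (chrom, pos, side)
    order so that swapping the ends yields an identical object apart from
    the id.
    """

    id: str
    sample_id: str
    end_a: Breakend
    end_b: Breakend

    def __post_init__(self) -> None:
        if not (self.end_a.sample_id == self.end_b.sample_id == self.sample_id):
            raise ValueError(f"adjacency {self.id}: sample ids disagree")
        if self.end_b.sort_key < self.end_a.sort_key:
            a, b = self.end_a, self.end_b
            object.__setattr__(self, "end_a", b)
            object.__setattr__(self, "end_b", a)

    @property
    def ends(self) -> tuple[Breakend, Breakend]:
        return (self.end_a, self.end_b)

    def end(self, index: int) -> Breakend:
        return self.ends[index]

    @property
    def is_intra_chromosomal(self) -> bool:
        return self.end_a.chrom == self.end_b.chrom


#: Reference to one breakend: (adjacency id, end index 0|1).
BreakendRef = tuple[str, int]


@dataclass
class SVDataset:
    """Per-sample adjacency lists over a declared genome."""

    samples: dict[str, list[Adjacency]]
    genome: dict[str, int]
    _index: dict[str, Adjacency] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {}
        seen: set[str] = set()
        for sample_id, adjacencies in self.samples.items():
            for adj in adjacencies:
                if adj.sample_id != sample_id:
                    raise ValueError(
                        f"adjacency {adj.id} filed under sample {sample_id!r} "
                        f"but carries sample {adj.sample_id!r}"
                    )
                if adj.id in seen:
                    raise ValueError(f"duplicate adjacency id {adj.id!r}")
                seen.add(adj.id)
                for end in adj.ends:
                    if end.chrom not in self.genome:
                        raise ValueError(
                            f"adjacency {adj.id}: chromosome {end.chrom!r} "
                            "not in declared genome"
                        )
                self._index[adj.id] = adj

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.samples)

    @property
    def n_adjacencies(self) -> int:
        return sum(len(v) for v in self.samples.values())

    def adjacency(self, adjacency_id: str) -> Adjacency:
        return self._index[adjacency_id]

    def breakend(self, ref: BreakendRef) -> Breakend:
        adjacency_id, end_index = ref
        return self._index[adjacency_id].end(end_index)

    def iter_adjacencies(self) -> Iterator[Adjacency]:
        for sample_id in self.sample_ids:
            yield from self.samples[sample_id]

    def iter_breakends(self) -> Iterator[tuple[BreakendRef, Breakend]]:
        for adj in self.iter_adjacencies():
            yield (adj.id, 0), adj.end_a
            yield (adj.id, 1), adj.end_b


def make_dataset(
    adjacencies: Iterable[Adjacency],
    genome: Mapping[str, int],
) -> SVDataset:
    """Assemble an :class:`SVDataset`, dropping junctions on undeclared contigs.

    Breakends on unplaced/alt contigs (anything absent from *genome*) are
    dropped with a logged count, keeping the declared chromosome model.
    """
    genome = dict(genome)
    samples: dict[str, list[Adjacency]] = {}
    n_dropped = 0
    for adj in adjacencies:
        if adj.end_a.chrom not in genome or adj.end_b.chrom not in genome:
            n_dropped += 1
            continue
        samples.setdefault(adj.sample_id, []).append(adj)
    if n_dropped:
        logger.warning(
            "dropped %d adjacencies on contigs outside the declared genome",
            n_dropped,
        )
    return SVDataset(samples=samples, genome=genome)


@dataclass(frozen=True)
class CopyNumberSegment:
    """Total copy number over a 1-based inclusive genomic interval."""

    sample_id: str
    chrom: str
    start: int
    end: int
    total_cn: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"segment start {self.start} > end {self.end} "
                f"({self.sample_id}:{self.chrom})"
            )
        if self.total_cn < 0:
            raise ValueError(f"negative total copy number {self.total_cn}")

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def overlaps(self, start: int, end: int) -> bool:
        return self.start <= end and start <= self.end


#: sample id -> cancer-type label
CancerTypeMap = dict[str, str]


def validate_cancer_map(mapping: Mapping[str, str]) -> CancerTypeMap:
    for sample_id, label in mapping.items():
        if not label:
            raise ValueError(f"empty cancer-type label for sample {sample_id!r}")
    return dict(mapping)
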