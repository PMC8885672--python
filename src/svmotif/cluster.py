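"""Recursive two-step KDE mode-hunting clustering of SV breakpoints.

Breakpoints of one sample on one chromosome are clustered by estimating a
fixed-bandwidth Gaussian kernel density, locating its local maxima (modes)
and assigning every breakpoint to the nearest mode — so every SV always ends
up in a cluster.  A first round at a coarse bandwidth (default 1000 bp)
defines regions; junctions looping inside a single round-1 cluster are
discarded; a second, finer round (default 400 bp) is then run independently
inside each surviving round-1 cluster and only the round-2 clusters are kept.

The bandwidth pair is a global choice across all samples; the diagnostics
(intra-cluster distance = largest within-cluster breakpoint gap,
inter-cluster distance = smallest gap between consecutive clusters) support
sweeping candidate bandwidths over the whole dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .model import Adjacency, BreakendRef, SVDataset

logger = logging.getLogger(__name__)


@dataclass
class ClusteringConfig:
    """Bandwidths (bp) and density-grid resolution for the two rounds."""

    h1: float = 1000.0
    h2: float = 400.0
    grid_step_factor: float = 0.1  # grid spacing as a fraction of the bandwidth
    grid_pad: float = 4.0  # evaluation window half-width, in bandwidth units

    def __post_init__(self) -> None:
        if self.h1 <= 0 or self.h2 <= 0:
            raise ValueError("bandwidths must be positive")
        if not 0 < self.grid_step_factor <= 0.5:
            raise ValueError("grid_step_factor must lie in (0, 0.5]")


@dataclass
class BreakpointVector:
    """Sorted breakpoint positions of one sample on one chromosome."""

    sample_id: str
    chrom: str
    positions: np.ndarray  # sorted ascending, 1-based
    refs: list[BreakendRef]  # parallel to positions

    def __post_init__(self) -> None:
        order = np.argsort(np.asarray(self.positions, dtype=float), kind="stable")
        self.positions = np.asarray(self.positions, dtype=float)[order]
        self.refs = [self.refs[i] for i in order]

    @property
    def n(self) -> int:
        return len(self.positions)


@dataclass
class DensityProfile:
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def __post_init__(self) -> None:
        if len(self.grid) != len(self.density):
            raise ValueError("grid and density lengths differ")


@dataclass
class Cluster:
    """A peak-centred group of breakpoints on one chromosome of one sample."""

    id: str
    sample_id: str
    chrom: str
    peak_pos: float
    members: list[BreakendRef]
    positions: np.ndarray  # parallel to members
    round: int

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def span(self) -> tuple[float, float]:
        return float(np.min(self.positions)), float(np.max(self.positions))


def gaussian_kde_density(
    positions: Sequence[float], bandwidth: float, query_points: Sequence[float]
) -> DensityProfile:
    """Fixed-bandwidth Gaussian KDE evaluated at *query_points*.

    density(x) = (1 / (n h sqrt(2 pi))) * sum_i exp(-(x - x_i)^2 / (2 h^2))
    """
    positions = np.asarray(positions, dtype=float)
    if positions.size == 0:
        raise ValueError("positions must be non-empty")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    query = np.asarray(query_points, dtype=float)
    norm = 1.0 / (positions.size * bandwidth * np.sqrt(2.0 * np.pi))
    density = np.empty_like(query)
    # chunk the grid so the (points x grid) kernel matrix stays small
    chunk = max(1, 4_000_000 // max(positions.size, 1))
    for start in range(0, query.size, chunk):
        block = query[start : start + chunk]
        z = (block[None, :] - positions[:, None]) / bandwidth
        density[start : start + chunk] = norm * np.exp(-0.5 * z * z).sum(axis=0)
    return DensityProfile(grid=query, density=density, bandwidth=bandwidth)


def find_density_peaks(profile: DensityProfile) -> np.ndarray:
    """Strict local maxima of the density over the grid, ascending.

    Plateaus collapse to their leftmost grid point.  Grid boundary points are
    not peaks (the evaluation window always pads beyond the data).
    """
    if len(profile.grid) < 3:
        raise ValueError("profile needs at least 3 grid points")
    idx, props = find_peaks(profile.density, plateau_size=1)
    left = props["left_edges"] if len(idx) else idx
    return profile.grid[left]


def assign_breakpoints(
    positions: Sequence[float], peaks: Sequence[float]
) -> np.ndarray:
    """Map every position to the index of its nearest peak.

    Equidistant positions break ties toward the lower-coordinate peak.
    """
    peaks = np.asarray(peaks, dtype=float)
    if peaks.size == 0:
        raise ValueError("no peaks to assign to")
    positions = np.asarray(positions, dtype=float)
    right = np.searchsorted(peaks, positions)
    right = np.clip(right, 0, peaks.size - 1)
    left = np.clip(right - 1, 0, peaks.size - 1)
    d_left = np.abs(positions - peaks[left])
    d_right = np.abs(positions - peaks[right])
    # ties (d_left == d_right) go to the lower-coordinate peak
    return np.where(d_left <= d_right, left, right)


def _grid_windows(
    positions: np.ndarray, bandwidth: float, config: ClusteringConfig
) -> list[np.ndarray]:
    """Evaluation grids over the union of windows data +/- grid_pad * h."""
    pad = config.grid_pad * bandwidth
    step = config.grid_step_factor * bandwidth
    lo = positions - pad
    hi = positions + pad
    order = np.argsort(lo)
    windows: list[tuple[float, float]] = []
    for a, b in zip(lo[order], hi[order]):
        if windows and a <= windows[-1][1]:
            windows[-1] = (windows[-1][0], max(windows[-1][1], b))
        else:
            windows.append((a, b))
    grids = []
    for a, b in windows:
        n_pts = max(int(np.ceil((b - a) / step)) + 1, 5)
        grids.append(np.linspace(a, b, n_pts))
    return grids


def cluster_chromosome(
    bv: BreakpointVector,
    bandwidth: float,
    config: ClusteringConfig,
    round_no: int = 1,
    id_prefix: str = "",
) -> list[Cluster]:
    """Mode-hunting clustering of one breakpoint vector at a fixed bandwidth.

    The density is evaluated on a grid of step ``grid_step_factor * h``
    restricted to the union of windows data +/- ``grid_pad * h``; breakpoints
    are assigned to the nearest density peak.  The clusters partition the
    breakpoints and their spans are disjoint.
    """
    if bv.n == 0:
        raise ValueError("empty breakpoint vector")
    positions = bv.positions
    unique = np.unique(positions)
    if unique.size == 1:
        peaks = unique
    else:
        peaks_parts = []
        for grid in _grid_windows(unique, bandwidth, config):
            profile = gaussian_kde_density(positions, bandwidth, grid)
            window_peaks = find_density_peaks(profile)
            if window_peaks.size == 0:
                # degenerate window (monotone density): fall back to its argmax
                window_peaks = np.array([grid[int(np.argmax(profile.density))]])
            peaks_parts.append(window_peaks)
        peaks = np.sort(np.concatenate(peaks_parts))
    labels = assign_breakpoints(positions, peaks)
    clusters: list[Cluster] = []
    for j, peak in enumerate(peaks):
        mask = labels == j
        if not mask.any():
            continue
        member_positions = positions[mask]
        # the cluster centre stays within the member span: a breakpoint on the
        # shoulder of a neighbouring mode must not carry the peak outside
        peak = float(np.clip(peak, member_positions.min(), member_positions.max()))
        clusters.append(
            Cluster(
                id=f"{id_prefix}{bv.sample_id}:{bv.chrom}:r{round_no}:{len(clusters)}",
                sample_id=bv.sample_id,
                chrom=bv.chrom,
                peak_pos=peak,
                members=[bv.refs[i] for i in np.flatnonzero(mask)],
                positions=member_positions,
                round=round_no,
            )
        )
    return clusters


def _breakpoint_vectors(
    adjacencies: Iterable[Adjacency],
) -> dict[tuple[str, str], BreakpointVector]:
    """Group breakends of the given adjacencies by (sample, chromosome)."""
    acc: dict[tuple[str, str], tuple[list[float], list[BreakendRef]]] = {}
    for adj in adjacencies:
        for i, end in enumerate(adj.ends):
            key = (adj.sample_id, end.chrom)
            pos_list, ref_list = acc.setdefault(key, ([], []))
            pos_list.append(float(end.pos))
            ref_list.append((adj.id, i))
    return {
        key: BreakpointVector(
            sample_id=key[0], chrom=key[1], positions=np.array(pos), refs=refs
        )
        for key, (pos, refs) in sorted(acc.items())
    }


def filter_intra_cluster_adjacencies(
    adjacencies: Sequence[Adjacency],
    assignment: dict[BreakendRef, str],
) -> tuple[list[Adjacency], list[Adjacency]]:
    """Discard junctions looping inside a single round-1 cluster.

    An adjacency is discarded iff both its breakends were assigned to the
    same round-1 cluster; *assignment* maps breakend refs to cluster ids.
    """
    kept: list[Adjacency] = []
    discarded: list[Adjacency] = []
    for adj in adjacencies:
        try:
            ca = assignment[(adj.id, 0)]
            cb = assignment[(adj.id, 1)]
        except KeyError as exc:
            raise ValueError(f"breakend {exc} not assigned to a round-1 cluster")
        (discarded if ca == cb else kept).append(adj)
    if discarded:
        logger.info(
            "loop filter: discarded %d intra-cluster adjacencies, kept %d",
            len(discarded),
            len(kept),
        )
    return kept, discarded


@dataclass
class TwoStepResult:
    """Output of the recursive two-step clustering."""

    clusters: list[Cluster]  # round-2 only
    assignment: dict[BreakendRef, str]  # breakend -> final cluster id
    kept_adjacencies: list[Adjacency]
    discarded_adjacencies: list[Adjacency]
    round1_clusters: list[Cluster] = field(default_factory=list)

    def cluster(self, cluster_id: str) -> Cluster:
        if not hasattr(self, "_by_id"):
            self._by_id = {c.id: c for c in self.clusters}
        return self._by_id[cluster_id]


def two_step_clustering(
    dataset: SVDataset, config: ClusteringConfig | None = None
) -> TwoStepResult:
    """Round-1 clustering at h1, loop filtering, round-2 at h2 inside each
    surviving round-1 cluster; round-1 clusters are then discarded and only
    the round-2 clusters remain."""
    config = config or ClusteringConfig()
    round1: list[Cluster] = []
    for bv in _breakpoint_vectors(dataset.iter_adjacencies()).values():
        round1.extend(cluster_chromosome(bv, config.h1, config, round_no=1))
    r1_assignment = {ref: c.id for c in round1 for ref in c.members}

    all_adjacencies = list(dataset.iter_adjacencies())
    kept, discarded = filter_intra_cluster_adjacencies(all_adjacencies, r1_assignment)

    # round 2: independent clustering inside every surviving round-1 cluster
    surviving_refs = {(adj.id, i) for adj in kept for i in (0, 1)}
    final: list[Cluster] = []
    assignment: dict[BreakendRef, str] = {}
    for c1 in round1:
        mask = [ref in surviving_refs for ref in c1.members]
        if not any(mask):
            continue
        refs = [ref for ref, keep in zip(c1.members, mask) if keep]
        positions = c1.positions[np.asarray(mask)]
        bv = BreakpointVector(
            sample_id=c1.sample_id, chrom=c1.chrom, positions=positions, refs=refs
        )
        for c2 in cluster_chromosome(
            bv, config.h2, config, round_no=2, id_prefix=f"{c1.id}|"
        ):
            final.append(c2)
            for ref in c2.members:
                assignment[ref] = c2.id
    return TwoStepResult(
        clusters=final,
        assignment=assignment,
        kept_adjacencies=kept,
        discarded_adjacencies=discarded,
        round1_clusters=round1,
    )


def cluster_distances(
    clusters: Sequence[Cluster],
) -> tuple[list[float], list[float]]:
    """Distance diagnostics for the clusters of one sample/chromosome.

    Returns ``(intra, inter)``: intra(C) = max(members) - min(members) per
    cluster; inter(C_k, C_{k+1}) = min(C_{k+1}) - max(C_k) per consecutive
    pair ordered by peak position.  Overlapping cluster spans (inter <= 0)
    violate the partition invariant and raise.
    """
    ordered = sorted(clusters, key=lambda c: c.peak_pos)
    intra = [c.span[1] - c.span[0] for c in ordered]
    inter: list[float] = []
    for a, b in zip(ordered, ordered[1:]):
        gap = b.span[0] - a.span[1]
        if gap <= 0:
            raise ValueError(
                f"clusters {a.id} and {b.id} have overlapping spans"
            )
        inter.append(gap)
    return intra, inter


def bandwidth_sweep(
    dataset: SVDataset,
    h2_values: Sequence[float],
    config: ClusteringConfig | None = None,
) -> pd.DataFrame:
    """Total intra- and inter-cluster distance over the dataset per candidate h2.

    For each candidate, runs the full two-step clustering and sums the
    diagnostics across every sample/chromosome.
    """
    if len(h2_values) == 0:
        raise ValueError("need at least one candidate bandwidth")
    base = config or ClusteringConfig()
    rows = []
    for h2 in h2_values:
        cfg = ClusteringConfig(
            h1=base.h1,
            h2=float(h2),
            grid_step_factor=base.grid_step_factor,
            grid_pad=base.grid_pad,
        )
        result = two_step_clustering(dataset, cfg)
        total_intra = total_inter = 0.0
        groups: dict[tuple[str, str], list[Cluster]] = {}
        for c in result.clusters:
            groups.setdefault((c.sample_id, c.chrom), []).append(c)
        for group in groups.values():
            intra, inter = cluster_distances(group)
            total_intra += sum(intra)
            total_inter += sum(inter)
        rows.append({"h2": float(h2), "total_intra": total_intra, "total_inter": total_inter})
    return pd.DataFrame(rows)


def clusters_to_frame(clusters: Sequence[Cluster]) -> pd.DataFrame:
    """Tabular view of clusters (one row per cluster)."""
    return pd.DataFrame(
        [
            {
                "cluster_id": c.id,
                "sample": c.sample_id,
                "chrom": c.chrom,
                "peak_pos": c.peak_pos,
                "n_breakends": c.n,
                "span_start": c.span[0],
                "span_end": c.span[1],
                "round": c.round,
            }
            for c in clusters
        ]
    )


def write_clusters_bed(clusters: Sequence[Cluster], path) -> None:
    """Export cluster spans as BED (0-based half-open; name=id, score=size)."""
    with open(path, "w") as fh:
        for c in sorted(clusters, key=lambda c: (c.chrom, c.peak_pos)):
            lo, hi = c.span
            fh.write(f"{c.chrom}\t{int(lo) - 1}\t{int(hi)}\t{c.id}\t{c.n}\n")
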