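"""Permutation validation that breakpoint clusters are not random.

Simulated datasets are built by pooling every breakend of every sample
(keeping each breakend's chromosome and position, so recurrent genomic loci
stay where they are), re-dealing them to samples while preserving each
sample's breakend count, and re-pairing them uniformly at random within each
sample.  Two summary statistics — the average dispersion of successive
breakpoint gaps and the average cluster density (breakpoints per cluster) —
are compared between the observed dataset and the simulated ensemble with a
one-sample Z-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cluster import Cluster, ClusteringConfig, two_step_clustering
from .model import Adjacency, Breakend, SVDataset

logger = logging.getLogger(__name__)


def simulate_breakpoint_dataset(
    dataset: SVDataset, rng: np.random.Generator
) -> SVDataset:
    """One pooled-breakpoint simulation of *dataset*.

    The pooled multiset of (chrom, pos, side) is preserved exactly, as is
    every sample's breakend count; pairing within each sample is uniformly
    random.  A sample left with an odd breakend count drops its last
    unpaired breakend with a warning (cannot happen when counts come from
    whole adjacencies).
    """
    if dataset.n_adjacencies == 0:
        raise ValueError("empty dataset")
    pool: list[tuple[str, int, object]] = []
    counts: list[tuple[str, int]] = []
    for sample_id in dataset.sample_ids:
        adjacencies = dataset.samples[sample_id]
        counts.append((sample_id, 2 * len(adjacencies)))
        for adj in adjacencies:
            for end in adj.ends:
                pool.append((end.chrom, end.pos, end.side))
    order = rng.permutation(len(pool))
    shuffled = [pool[i] for i in order]
    samples: dict[str, list[Adjacency]] = {}
    cursor = 0
    serial = 0
    for sample_id, n in counts:
        chunk = shuffled[cursor : cursor + n]
        cursor += n
        if len(chunk) % 2:
            logger.warning("sample %s: dropping one unpaired breakend", sample_id)
            chunk = chunk[:-1]
        adjacencies = []
        for i in range(0, len(chunk), 2):
            (c1, p1, s1), (c2, p2, s2) = chunk[i], chunk[i + 1]
            adjacencies.append(
                Adjacency(
                    id=f"sim{serial}",
                    sample_id=sample_id,
                    end_a=Breakend(sample_id, c1, p1, s1),
                    end_b=Breakend(sample_id, c2, p2, s2),
                )
            )
            serial += 1
        samples[sample_id] = adjacencies
    return SVDataset(samples=samples, genome=dict(dataset.genome))


@dataclass
class SimulatedDatasetEnsemble:
    datasets: list[SVDataset]
    seed: int

    @property
    def n_datasets(self) -> int:
        return len(self.datasets)


def simulate_ensemble(
    dataset: SVDataset, n_datasets: int = 100, seed: int = 0
) -> SimulatedDatasetEnsemble:
    rng = np.random.default_rng(seed)
    return SimulatedDatasetEnsemble(
        datasets=[simulate_breakpoint_dataset(dataset, rng) for _ in range(n_datasets)],
        seed=seed,
    )


def dispersion_statistic(dataset: SVDataset) -> float:
    """Average dispersion of breakpoints: per sample/chromosome with >= 3
    breakpoints, the population SD of successive gaps of the sorted
    positions; unweighted mean over those sample/chromosomes."""
    groups: dict[tuple[str, str], list[int]] = {}
    for _ref, end in dataset.iter_breakends():
        groups.setdefault((end.sample_id, end.chrom), []).append(end.pos)
    values = []
    for positions in groups.values():
        if len(positions) < 3:
            continue
        gaps = np.diff(np.sort(np.asarray(positions, dtype=float)))
        values.append(float(np.std(gaps)))  # population SD (divisor n)
    if not values:
        raise ValueError("no sample/chromosome with >= 3 breakpoints")
    return float(np.mean(values))


def cluster_density_statistic(clusters: Sequence[Cluster]) -> float:
    """Average number of breakends per cluster."""
    if len(clusters) == 0:
        raise ValueError("no clusters")
    return sum(c.n for c in clusters) / len(clusters)


@dataclass
class ZTestResult:
    observed: float
    sim_mean: float
    sim_sd: float
    z: float
    p_two_sided: float
    p_greater: float  # P(observed at least this large under the null)
    p_less: float
    degenerate: bool = False


def one_sample_z_test(observed: float, sim_values: Sequence[float]) -> ZTestResult:
    """One-sample Z-test of *observed* against the simulated distribution.

    z = (observed - mean) / SD with the sample SD (divisor n-1); the p-value
    uses the normal approximation.  A zero simulated SD yields a degenerate
    result with undefined (NaN) p-values.
    """
    sims = np.asarray(sim_values, dtype=float)
    if sims.size < 2:
        raise ValueError("need at least 2 simulated values")
    mean = float(np.mean(sims))
    sd = float(np.std(sims, ddof=1))
    if sd == 0:
        return ZTestResult(
            observed=float(observed),
            sim_mean=mean,
            sim_sd=0.0,
            z=np.nan,
            p_two_sided=np.nan,
            p_greater=np.nan,
            p_less=np.nan,
            degenerate=True,
        )
    z = (float(observed) - mean) / sd
    return ZTestResult(
        observed=float(observed),
        sim_mean=mean,
        sim_sd=sd,
        z=z,
        p_two_sided=float(2 * stats.norm.sf(abs(z))),
        p_greater=float(stats.norm.sf(z)),
        p_less=float(stats.norm.cdf(z)),
    )


def permutation_validation(
    dataset: SVDataset,
    clustering_config: ClusteringConfig | None = None,
    n_datasets: int = 100,
    seed: int = 0,
) -> dict[str, ZTestResult]:
    """Run both cluster-validation tests against a fresh simulated ensemble.

    Returns Z-test results keyed by ``"dispersion"`` and
    ``"cluster_density"``.  The clustering for the density statistic is the
    same two-step KDE clustering applied to each simulated dataset.
    """
    config = clustering_config or ClusteringConfig()
    ensemble = simulate_ensemble(dataset, n_datasets=n_datasets, seed=seed)
    obs_dispersion = dispersion_statistic(dataset)
    obs_density = cluster_density_statistic(two_step_clustering(dataset, config).clusters)
    sim_dispersion = []
    sim_density = []
    for sim in ensemble.datasets:
        sim_dispersion.append(dispersion_statistic(sim))
        sim_density.append(
            cluster_density_statistic(two_step_clustering(sim, config).clusters)
        )
    return {
        "dispersion": one_sample_z_test(obs_dispersion, sim_dispersion),
        "cluster_density": one_sample_z_test(obs_density, sim_density),
    }


def validation_report(results: dict[str, ZTestResult]) -> pd.DataFrame:
    """TSV-ready report: statistic, observed, sim mean, sim SD, z, p."""
    return pd.DataFrame(
        [
            {
                "statistic": name,
                "observed": r.observed,
                "sim_mean": r.sim_mean,
                "sim_sd": r.sim_sd,
                "z": r.z,
                "p_two_sided": r.p_two_sided,
                "p_greater": r.p_greater,
                "p_less": r.p_less,
            }
            for name, r in results.items()
        ]
    )
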