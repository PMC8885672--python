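"""Shared fixtures: small seeded synthetic datasets and builders."""

from __future__ import annotations

import numpy as np
import pytest

from svmotif.cluster import two_step_clustering
from svmotif.model import Adjacency, Breakend, SVDataset, Side
from svmotif.pipeline import build_graphs
from svmotif.simulate import generate_dataset, simple_config

TEST_GENOME = {"chr1": 10_000_000, "chr2": 10_000_000, "chr3": 10_000_000}


def make_adjacency(
    adj_id: str,
    sample: str,
    end1: tuple[str, int, Side],
    end2: tuple[str, int, Side],
) -> Adjacency:
    return Adjacency(
        id=adj_id,
        sample_id=sample,
        end_a=Breakend(sample, *end1),
        end_b=Breakend(sample, *end2),
    )


def dataset_from_pairs(pairs, genome=None) -> SVDataset:
    """Build a dataset from (sample, chrom1, pos1, chrom2, pos2) tuples.

    Sides default to a non-inverted junction (extends_right / extends_left).
    """
    samples: dict[str, list[Adjacency]] = {}
    for i, (sample, c1, p1, c2, p2) in enumerate(pairs):
        samples.setdefault(sample, []).append(
            make_adjacency(
                f"adj{i}",
                sample,
                (c1, p1, Side.EXTENDS_RIGHT),
                (c2, p2, Side.EXTENDS_LEFT),
            )
        )
    return SVDataset(samples=samples, genome=dict(genome or TEST_GENOME))


@pytest.fixture(scope="session")
def planted():
    """8 samples, one planted triangle each (all four archetypes, twice),
    plus a little uniform background."""
    config = simple_config(
        n_samples=8, n_triangles=8, background_adjacencies=5, seed=3
    )
    dataset, cn_segments, cancer_map, manifest = generate_dataset(config)
    return dataset, cn_segments, cancer_map, manifest


@pytest.fixture(scope="session")
def planted_clustered(planted):
    dataset, cn_segments, cancer_map, manifest = planted
    result = two_step_clustering(dataset)
    graphs = build_graphs(dataset.sample_ids, result)
    return dataset, result, graphs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
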