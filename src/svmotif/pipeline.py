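"""End-to-end orchestration and intermediate-file formats.

The pipeline stages are: two-step KDE clustering -> permutation validation
-> per-sample graph construction -> cycle mining -> switching-null abundance
-> triangle classification.  Each stage's output is a plain TSV/JSON file
carrying a provenance header, and each file is a valid input to the next
stage's standalone CLI subcommand.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .cluster import (
    Cluster,
    ClusteringConfig,
    TwoStepResult,
    clusters_to_frame,
    two_step_clustering,
    write_clusters_bed,
)
from .graph import (
    CycleOccurrence,
    SampleGraph,
    build_sample_graph,
    mine_dataset,
    occurrences_to_records,
    pattern_statistics,
    pattern_statistics_frame,
)
from .model import (
    Adjacency,
    Breakend,
    CancerTypeMap,
    CopyNumberSegment,
    SVDataset,
    Side,
)
from .motifs import (
    SwitchingConfig,
    abundance_frame,
    motif_abundance_report,
    randomized_dataset_ensemble,
)
from .permutation import permutation_validation, validation_report
from .triangles import (
    ClassifierConfig,
    TriangleCall,
    calls_to_frame,
    classify_triangles,
    triangle_overlap_matrix,
    triangle_type_cancer_summary,
)

logger = logging.getLogger(__name__)

ADJACENCY_COLUMNS = [
    "sample", "id", "chrom_a", "pos_a", "side_a", "chrom_b", "pos_b", "side_b",
]


def provenance_header(seed: int | None = None, **params) -> str:
    bits = [f"svmotif={__version__}"]
    if seed is not None:
        bits.append(f"seed={seed}")
    bits.extend(f"{k}={v}" for k, v in params.items())
    return "# " + " ".join(bits) + "\n"


def write_table(df: pd.DataFrame, path: str | Path, seed: int | None = None, **params) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(seed=seed, **params))
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def dataset_to_frame(dataset: SVDataset) -> pd.DataFrame:
    rows = []
    for adj in dataset.iter_adjacencies():
        a, b = adj.ends
        rows.append(
            (adj.sample_id, adj.id, a.chrom, a.pos, a.side.value, b.chrom, b.pos, b.side.value)
        )
    return pd.DataFrame(rows, columns=ADJACENCY_COLUMNS)


def write_dataset(dataset: SVDataset, adj_path: str | Path, genome_path: str | Path,
                  seed: int | None = None) -> None:
    write_table(dataset_to_frame(dataset), adj_path, seed=seed)
    write_table(
        pd.DataFrame(sorted(dataset.genome.items()), columns=["chrom", "length"]),
        genome_path,
        seed=seed,
    )


def read_dataset(adj_path: str | Path, genome_path: str | Path) -> SVDataset:
    adj_df = read_table(adj_path)
    genome_df = read_table(genome_path)
    genome = dict(zip(genome_df["chrom"].astype(str), genome_df["length"].astype(int)))
    samples: dict[str, list[Adjacency]] = {}
    for row in adj_df.itertuples():
        sample = str(row.sample)
        samples.setdefault(sample, []).append(
            Adjacency(
                id=str(row.id),
                sample_id=sample,
                end_a=Breakend(sample, str(row.chrom_a), int(row.pos_a), Side(row.side_a)),
                end_b=Breakend(sample, str(row.chrom_b), int(row.pos_b), Side(row.side_b)),
            )
        )
    return SVDataset(samples=samples, genome=genome)


def build_graphs(dataset_samples: Sequence[str], result: TwoStepResult) -> dict[str, SampleGraph]:
    """One deduplicated cluster graph per sample from the clustering result."""
    return {
        sample_id: build_sample_graph(
            sample_id, result.clusters, result.kept_adjacencies, result.assignment
        )
        for sample_id in sorted(dataset_samples)
    }


def assignment_frame(result: TwoStepResult) -> pd.DataFrame:
    rows = [
        {"adjacency_id": ref[0], "end": ref[1], "cluster_id": cid}
        for ref, cid in sorted(result.assignment.items())
    ]
    return pd.DataFrame(rows)


@dataclass
class PipelineConfig:
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    switching: SwitchingConfig = field(default_factory=SwitchingConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    n_permutations: int = 100
    k_min: int = 3
    k_max: int = 6
    seed: int = 0
    run_permutation_test: bool = True


@dataclass
class PipelineResult:
    clustering: TwoStepResult
    graphs: dict[str, SampleGraph]
    occurrences: list[CycleOccurrence]
    stats: pd.DataFrame
    validation: pd.DataFrame | None
    abundance: pd.DataFrame
    triangle_calls: list[TriangleCall]
    triangle_frame: pd.DataFrame
    overlap_matrix: pd.DataFrame
    cancer_summary: pd.DataFrame | None


def run_pipeline(
    dataset: SVDataset,
    cn_segments: Sequence[CopyNumberSegment] | None = None,
    cancer_map: CancerTypeMap | None = None,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run every stage in order; optionally write all artifact tables."""
    config = config or PipelineConfig()
    logger.info("clustering %d adjacencies", dataset.n_adjacencies)
    clustering = two_step_clustering(dataset, config.clustering)

    validation = None
    if config.run_permutation_test:
        logger.info("permutation validation (%d simulations)", config.n_permutations)
        results = permutation_validation(
            dataset,
            config.clustering,
            n_datasets=config.n_permutations,
            seed=config.seed,
        )
        validation = validation_report(results)

    graphs = build_graphs(dataset.sample_ids, clustering)
    occurrences = mine_dataset(graphs.values(), k_min=config.k_min, k_max=config.k_max)
    stats = pattern_statistics_frame(
        pattern_statistics(
            occurrences, dataset.sample_ids, sizes=range(config.k_min, config.k_max + 1)
        )
    )

    logger.info("randomizing %d datasets", config.switching.n_datasets)
    switching = SwitchingConfig(
        n_datasets=config.switching.n_datasets,
        multiplier=config.switching.multiplier,
        epsilon=config.switching.epsilon,
        seed=config.seed,
    )
    ensemble = randomized_dataset_ensemble(list(graphs.values()), switching)
    sizes = tuple(range(config.k_min, config.k_max + 1))
    ab_results = motif_abundance_report(
        list(graphs.values()), ensemble, sizes=sizes, epsilon=switching.epsilon
    )
    ab_frame = abundance_frame(ab_results, switching.n_datasets, switching.epsilon)

    adjacency_lookup = {adj.id: adj for adj in dataset.iter_adjacencies()}
    calls = classify_triangles(
        occurrences, graphs, adjacency_lookup, cn_segments, config.classifier
    )
    triangle_frame = calls_to_frame(calls)
    overlap = triangle_overlap_matrix(calls)
    cancer_summary = None
    if cancer_map is not None and calls:
        cancer_summary = triangle_type_cancer_summary(calls, cancer_map)

    result = PipelineResult(
        clustering=clustering,
        graphs=graphs,
        occurrences=occurrences,
        stats=stats,
        validation=validation,
        abundance=ab_frame,
        triangle_calls=calls,
        triangle_frame=triangle_frame,
        overlap_matrix=overlap,
        cancer_summary=cancer_summary,
    )
    if outdir is not None:
        save_pipeline_outputs(result, dataset, Path(outdir), config)
    return result


def save_pipeline_outputs(
    result: PipelineResult,
    dataset: SVDataset,
    outdir: Path,
    config: PipelineConfig,
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    write_table(
        clusters_to_frame(result.clustering.clusters),
        outdir / "clusters.tsv",
        seed=seed,
        h1=config.clustering.h1,
        h2=config.clustering.h2,
    )
    write_clusters_bed(result.clustering.clusters, outdir / "clusters.bed")
    write_table(assignment_frame(result.clustering), outdir / "assignments.tsv", seed=seed)
    write_table(
        dataset_to_frame(
            SVDataset(
                samples={
                    s: [a for a in result.clustering.kept_adjacencies if a.sample_id == s]
                    for s in dataset.sample_ids
                },
                genome=dataset.genome,
            )
        ),
        outdir / "kept_adjacencies.tsv",
        seed=seed,
    )
    if result.validation is not None:
        write_table(
            result.validation,
            outdir / "permutation_test.tsv",
            seed=seed,
            n_datasets=config.n_permutations,
        )
    with open(outdir / "occurrences.jsonl", "w") as fh:
        fh.write(provenance_header(seed=seed))
        for rec in occurrences_to_records(result.occurrences, result.graphs):
            fh.write(json.dumps(rec) + "\n")
    write_table(result.stats, outdir / "pattern_stats.tsv", seed=seed)
    write_table(
        result.abundance,
        outdir / "abundance.tsv",
        seed=seed,
        n_datasets=config.switching.n_datasets,
        multiplier=config.switching.multiplier,
        epsilon=config.switching.epsilon,
    )
    write_table(result.triangle_frame, outdir / "triangle_calls.tsv", seed=seed)
    with open(outdir / "triangle_overlap.tsv", "w") as fh:
        fh.write(provenance_header(seed=seed))
        result.overlap_matrix.to_csv(fh, sep="\t")
    if result.cancer_summary is not None:
        write_table(result.cancer_summary, outdir / "triangle_cancer_summary.tsv", seed=seed)
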