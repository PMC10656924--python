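"""Shared fixtures: a tiny hand-built community table and one session-scoped
synthetic experiment (with its cluster map and pathway projection) reused by
the succession, projection and selection tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from microsucc import (
    CommunityTable,
    default_truth,
    generate_experiment,
    metrics,
)
from microsucc import matching, projection


@pytest.fixture()
def small_table() -> CommunityTable:
    counts = pd.DataFrame(
        [[10, 0, 5], [3, 7, 0], [1, 1, 2]],
        index=["s1", "s2", "s3"],
        columns=["a1", "a2", "a3"],
    )
    meta = pd.DataFrame(
        {
            "substrate": ["polyp", "polyp", "tube"],
            "inoculum": ["bL", "bJ", "bA"],
            "timepoint": [2, 28, "inoculum"],
            "replicate": [1, 1, 1],
        },
        index=["s1", "s2", "s3"],
    )
    return CommunityTable(counts=counts, meta=meta).validate()


@pytest.fixture(scope="session")
def default_exp():
    """Default-condition synthetic experiment: 40 taxa, 60 pathways,
    3 inocula x 4 timepoints x 5 replicates x 2 substrates + 3 inocula."""
    spec = default_truth(seed=7, n_taxa=40, n_pathways=60)
    return generate_experiment(spec, n_replicates=5, depth=20_000)


@pytest.fixture(scope="session")
def polyp_rel(default_exp):
    sub = default_exp.table.subset_substrate("polyp", keep_inoculum=False)
    return metrics.relative_abundance(sub), sub.meta


@pytest.fixture(scope="session")
def cluster_map(default_exp):
    cmap = matching.greedy_cluster(default_exp.asv_seqs)
    return matching.assign_genomes(default_exp.genome_seqs, cmap)


@pytest.fixture(scope="session")
def pathway_abundance(default_exp, polyp_rel, cluster_map):
    rel, _ = polyp_rel
    crel = projection.aggregate_to_clusters(rel, cluster_map)
    return projection.project_pathways(crel, default_exp.pathways, cluster_map)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
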