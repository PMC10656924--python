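"""Calibration and planted-truth recovery benchmarks.

These routines quantify what the pipeline's statistics do under known
conditions: type-I error of the PERMANOVA permutation test on exchangeable
data, behaviour of the repeated Boruta selection on label-permuted data,
and recovery of the generator's planted colonizer classes, pathway
associations and sequence clusters.  They are used by the acceptance
machinery and are part of the public surface: rerunning them under a new
seed is the cheapest way to convince yourself the stack is calibrated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from . import matching, metrics, projection, selection, simulate, succession
from .metrics import DistanceMatrix
from .simulate import SyntheticExperiment


def permanova_type_i_error(
    n_sims: int = 1000,
    n_per_group: int = 10,
    n_permutations: int = 199,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Rejection rate of PERMANOVA at level ``alpha`` on exchangeable data
    (two groups drawn from one multivariate normal, Euclidean distances)."""
    rng = np.random.default_rng(seed)
    groups = np.array(["a"] * n_per_group + ["b"] * n_per_group)
    rejections = 0
    for i in range(n_sims):
        X = rng.normal(size=(2 * n_per_group, 3))
        dm = DistanceMatrix(
            d=squareform(pdist(X)),
            sample_ids=[f"s{j}" for j in range(2 * n_per_group)],
            metric_name="euclidean",
        ).validate()
        res = metrics.permanova(
            dm, groups, n_permutations=n_permutations,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        rejections += res.p_value <= alpha
    return rejections / n_sims


def anosim_null_mean_r(
    n_sims: int = 1000, n_per_group: int = 5, seed: int = 0
) -> float:
    """Mean ANOSIM R under random labels on exchangeable data (expect ~0)."""
    rng = np.random.default_rng(seed)
    groups = np.array(["a"] * n_per_group + ["b"] * n_per_group)
    rs = []
    for _ in range(n_sims):
        X = rng.normal(size=(2 * n_per_group, 3))
        dm = DistanceMatrix(
            d=squareform(pdist(X)),
            sample_ids=[f"s{j}" for j in range(2 * n_per_group)],
            metric_name="euclidean",
        ).validate()
        rs.append(metrics.anosim(dm, groups, n_permutations=1, seed=0).statistic)
    return float(np.mean(rs))


def boruta_null_empty_fraction(
    n_trials: int = 20,
    n_samples: int = 60,
    n_pathways: int = 100,
    n_repeats: int = 3,
    n_trees: int = 150,
    max_iter: int = 25,
    seed: int = 0,
) -> float:
    """Fraction of label-permuted trials whose consistent set is empty."""
    rng = np.random.default_rng(seed)
    empty = 0
    y = np.array(["early"] * (n_samples // 2) + ["late"] * (n_samples // 2))
    for t in range(n_trials):
        X = pd.DataFrame(
            rng.normal(size=(n_samples, n_pathways)),
            columns=[f"p{i}" for i in range(n_pathways)],
        )
        yp = y.copy()
        rng.shuffle(yp)
        res = selection.repeated_selection(
            X, yp, n_repeats=n_repeats, n_trees=n_trees, max_iter=max_iter,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        empty += not res.consistent_set
    return empty / n_trials


def colonizer_class_recovery(exp: SyntheticExperiment) -> tuple[float, int]:
    """Agreement between classified and planted early/late classes on the
    host substrate; returns (fraction agreeing, number scored)."""
    table = exp.table.subset_substrate("polyp", keep_inoculum=True)
    rel = metrics.relative_abundance(table)
    prof = succession.succession_profile(rel, table.meta)
    truth = exp.truth.class_of
    scored = [
        int(truth[a] == c)
        for a, c in prof.class_of.items()
        if truth[a] in ("early", "late")
    ]
    return float(np.mean(scored)), len(scored)


def project_experiment(exp: SyntheticExperiment):
    """Cluster the experiment's sequences, assign genomes and project
    pathways on the host substrate; returns (PathwayAbundance, meta, cmap)."""
    polyp = exp.table.subset_substrate("polyp", keep_inoculum=False)
    rel = metrics.relative_abundance(polyp)
    cmap = matching.greedy_cluster(exp.asv_seqs)
    cmap = matching.assign_genomes(exp.genome_seqs, cmap)
    crel = projection.aggregate_to_clusters(rel, cmap)
    pa = projection.project_pathways(crel, exp.pathways, cmap)
    return pa, polyp.meta, cmap


def pathway_selection_recovery(
    exp: SyntheticExperiment,
    n_repeats: int = 3,
    n_trees: int = 150,
    max_iter: int = 30,
    seed: int = 0,
) -> dict[str, float]:
    """Sensitivity / false-confirmation of repeated Boruta against the
    planted pathway associations, plus the CV accuracy on the consistent set."""
    pa, meta, _ = project_experiment(exp)
    res = selection.select_pathways(
        pa.A, meta, exp.truth.subsystem_of,
        n_repeats=n_repeats, n_trees=n_trees, max_iter=max_iter, seed=seed,
    )
    truth = exp.truth.pathway_truth
    planted = {p for p, v in truth.items() if v != "neutral"}
    neutral = set(truth) - planted
    cons = set(res.consistent_set)
    return {
        "sensitivity": len(cons & planted) / len(planted),
        "false_confirmation_rate": len(cons - planted) / len(neutral),
        "cv_accuracy": float(res.cv_accuracy) if res.cv_accuracy is not None else 0.0,
        "n_consistent": float(len(cons)),
        "mean_coverage": float(pa.coverage.mean()),
    }


def cluster_recovery_ari(
    n_clusters: int = 6,
    members_per_cluster: int = 3,
    within_identity: float = 0.99,
    between_identity: float = 0.90,
    length: int = 1000,
    threshold: float = 0.97,
    seed: int = 0,
) -> float:
    """Adjusted Rand index of greedy clustering against planted families."""
    recs, labels = simulate.generate_sequences(
        n_clusters, members_per_cluster, within_identity=within_identity,
        between_identity=between_identity, length=length, seed=seed,
    )
    cmap = matching.greedy_cluster(recs, threshold=threshold)
    truth = [labels[sid] for sid, _ in recs]
    mine = [cmap.cluster_of_asv[sid] for sid, _ in recs]
    return float(adjusted_rand_score(truth, mine))


def substrate_structure_contrast(
    exp: SyntheticExperiment, n_permutations: int = 999, seed: int = 0
) -> dict[str, float]:
    """PERMANOVA R-squared of dpr and inoculum on each substrate.

    On the host, time since recolonization should dominate (host-driven
    reset); on the inert substrate, the inoculum should persist.
    """
    out: dict[str, float] = {}
    for substrate in ("polyp", "tube"):
        sub = exp.table.subset_substrate(substrate, keep_inoculum=False)
        rel = metrics.relative_abundance(sub)
        dm = metrics.distance_matrix(rel, "bray_curtis")
        m = sub.meta.loc[rel.index]
        for factor, groups in (
            ("dpr", m["timepoint"].astype(str).to_numpy()),
            ("inoculum", m["inoculum"].to_numpy()),
        ):
            res = metrics.permanova(
                dm, groups, n_permutations=n_permutations, seed=seed
            )
            out[f"{substrate}_r2_{factor}"] = float(res.effect)
    return out
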