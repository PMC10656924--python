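"""Abundance-weighted projection of genome pathway content onto 16S profiles.

The central bespoke computation: for every metabolic pathway, sum the
relative abundances of all community members (97 % clusters) whose matched
genomes are predicted to encode it.  The result is a "relative cumulative
pathway abundance" per sample — a number in [0, 1] bounded by the sample's
*coverage*, the fraction of community abundance sitting in clusters that
have at least one matched genome.  Clusters without a genome contribute to
no pathway; their mass is reported as 1 - coverage, never silently
renormalised away.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SchemaError
from .io import PathwayPresence, POST_TIMEPOINTS
from .matching import ClusterMap


@dataclass
class PathwayAbundance:
    """Pathways x samples cumulative relative abundances plus coverage."""

    A: pd.DataFrame          # pathways x samples
    coverage: pd.Series      # per-sample fraction covered by matched clusters

    def validate(self) -> "PathwayAbundance":
        a = self.A.to_numpy()
        cov = self.coverage.loc[self.A.columns].to_numpy()
        if (a < -1e-12).any() or (a > cov[None, :] + 1e-9).any():
            raise ValueError("pathway abundance outside [0, coverage]")
        return self


def aggregate_to_clusters(rel: pd.DataFrame, cmap: ClusterMap) -> pd.DataFrame:
    """Sum member-ASV relative abundances per cluster (row sums preserved)."""
    unmapped = [a for a in rel.columns if a not in cmap.cluster_of_asv]
    if unmapped:
        raise SchemaError(f"ASVs missing from the cluster map: {unmapped}")
    labels = [cmap.cluster_of_asv[a] for a in rel.columns]
    out = rel.T.groupby(labels, sort=True).sum().T
    return out


def cluster_pathway_presence(
    pp: PathwayPresence, cmap: ClusterMap, consensus: bool = False
) -> pd.DataFrame:
    """Pathway presence per cluster from its assigned genomes.

    Default is the union over genomes (a pathway is present if any matched
    genome encodes it); ``consensus=True`` requires a strict majority.
    Clusters with no genome get an all-zero row.
    """
    missing = [
        g for genomes in cmap.genomes_of.values() for g in genomes
        if g not in pp.presence.index
    ]
    if missing:
        raise SchemaError(f"genomes absent from presence table: {missing}")
    rows = []
    for c in cmap.clusters:
        genomes = cmap.genomes_of.get(c, [])
        if not genomes:
            rows.append(np.zeros(pp.presence.shape[1]))
        elif consensus:
            rows.append(
                (pp.presence.loc[genomes].mean(axis=0) > 0.5).to_numpy(float)
            )
        else:
            rows.append(pp.presence.loc[genomes].max(axis=0).to_numpy(float))
    return pd.DataFrame(rows, index=cmap.clusters, columns=pp.presence.columns)


def project_pathways(
    cluster_rel: pd.DataFrame,
    pp: PathwayPresence,
    cmap: ClusterMap,
    consensus: bool = False,
) -> PathwayAbundance:
    """A[p, s] = sum over clusters carrying pathway p of cluster_rel[s, c].

    ``coverage[s]`` is the summed relative abundance of clusters with at
    least one assigned genome; A is bounded above by it.
    """
    if pp.presence.shape[1] == 0:
        raise SchemaError("pathway presence table has no pathways")
    if pp.presence.shape[0] == 0:
        raise SchemaError("pathway presence table has no taxa")
    cp = cluster_pathway_presence(pp, cmap, consensus=consensus)
    clusters = [c for c in cluster_rel.columns if c in cp.index]
    missing = [c for c in cluster_rel.columns if c not in cp.index]
    if missing:
        raise SchemaError(f"clusters absent from cluster map: {missing}")
    X = cluster_rel[clusters].to_numpy(float)         # samples x clusters
    P = cp.loc[clusters].to_numpy(float)              # clusters x pathways
    A = pd.DataFrame(
        (X @ P).T, index=cp.columns, columns=cluster_rel.index
    )
    has_genome = np.array(
        [len(cmap.genomes_of.get(c, [])) > 0 for c in clusters], dtype=float
    )
    coverage = pd.Series(X @ has_genome, index=cluster_rel.index, name="coverage")
    return PathwayAbundance(A=A, coverage=coverage).validate()


def pathway_timecourse(
    pa: PathwayAbundance, meta: pd.DataFrame, pathways: list[str]
) -> pd.DataFrame:
    """Tidy (pathway, timepoint, mean, sd, n) summary across replicates and
    inocula, over the recolonization timepoints."""
    if not pathways:
        raise ValueError("empty pathway set")
    missing = [p for p in pathways if p not in pa.A.index]
    if missing:
        raise SchemaError(f"pathways absent from abundance matrix: {missing}")
    meta = meta.loc[pa.A.columns]
    rows = []
    for p in pathways:
        for tp in POST_TIMEPOINTS:
            cols = pa.A.columns[(meta["timepoint"] == tp).to_numpy()]
            if len(cols) == 0:
                continue
            vals = pa.A.loc[p, cols].to_numpy(float)
            rows.append((p, tp, vals.mean(), vals.std(ddof=1), len(vals)))
    return pd.DataFrame(rows, columns=["pathway", "timepoint", "mean", "sd", "n"])
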