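"""Core-taxon filtering, block scaling, row ordering and colonizer classes.

This is the heatmap-style succession analysis: keep only ASVs that are
constantly detected (at or above a relative-abundance floor in *every*
sample) at at least one recolonization timepoint, scale each ASV's
abundances to [0, 1] within each column block (the inocula block plus one
block per timepoint), order rows by hierarchical clustering, and classify
each ASV as an early (peak at 2 or 7 dpr) or late (peak at 14 or 28 dpr)
colonizer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage, optimal_leaf_ordering
from scipy.spatial.distance import pdist

from .errors import SchemaError
from .io import INOCULUM_TIMEPOINT, POST_TIMEPOINTS

#: detection floor: 0.005 % relative abundance
DEFAULT_MIN_ABUND = 5e-5


@dataclass
class SuccessionProfile:
    """Filtered, block-scaled succession matrix plus display order and classes."""

    asv_ids: list[str]
    scaled: pd.DataFrame          # asv x sample, entries in [0, 1]
    block_of: pd.Series           # sample -> block label ("inoculum", "2", ...)
    order: list[str]              # display permutation of asv_ids
    class_of: dict[str, str]      # asv -> "early" | "late"


def filter_core_asvs(
    rel: pd.DataFrame,
    meta: pd.DataFrame,
    min_abund: float = DEFAULT_MIN_ABUND,
) -> list[str]:
    """ASVs constantly detected at >= ``min_abund`` in every sample of at
    least one recolonization timepoint.

    ``rel`` is samples x ASVs relative abundance; inoculum samples are
    ignored.  Raises :class:`SchemaError` if a timepoint has no samples.
    """
    meta = meta.loc[rel.index]
    kept: np.ndarray | None = None
    for tp in POST_TIMEPOINTS:
        mask = (meta["timepoint"] == tp).to_numpy()
        if not mask.any():
            raise SchemaError(f"no samples at timepoint {tp}")
        ok = (rel.loc[mask].to_numpy() >= min_abund).all(axis=0)
        kept = ok if kept is None else (kept | ok)
    return list(rel.columns[kept])


def scale_blocks(
    rel: pd.DataFrame, meta: pd.DataFrame, asv_ids: list[str] | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Scale each ASV to [0, 1] within each column block.

    Blocks follow the heatmap layout: one block for the inoculum samples
    and one per recolonization treatment (inoculum source), each spanning
    all timepoints and replicates.  Within a block each ASV row is divided
    by its block maximum (all-zero block rows stay zero), so each ASV's
    temporal profile is preserved within a treatment while magnitudes are
    comparable across ASVs.  Returns (scaled asv x sample matrix, sample ->
    block labels).
    """
    if asv_ids is not None:
        if not asv_ids:
            raise SchemaError("filtered ASV set is empty")
        rel = rel[asv_ids]
    meta = meta.loc[rel.index]
    block = pd.Series(
        np.where(
            (meta["timepoint"] == INOCULUM_TIMEPOINT).to_numpy(),
            INOCULUM_TIMEPOINT,
            meta["inoculum"].to_numpy(),
        ),
        index=meta.index,
    )
    mat = rel.T.copy().astype(float)  # asv x sample
    for b in block.unique():
        cols = mat.columns[(block == b).to_numpy()]
        sub = mat[cols].to_numpy()
        mx = sub.max(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            scaled = np.where(mx > 0, sub / mx, 0.0)
        mat[cols] = scaled
    return mat, pd.Series(block.to_numpy(), index=mat.columns, name="block")


def order_rows(scaled: pd.DataFrame) -> list[str]:
    """Deterministic display order: average-linkage hierarchical clustering
    on Euclidean row distance with optimal leaf ordering."""
    if scaled.shape[0] < 2:
        return list(scaled.index)
    X = scaled.to_numpy(dtype=float)
    dist = pdist(X, metric="euclidean")
    Z = linkage(dist, method="average")
    Z = optimal_leaf_ordering(Z, dist)
    return [scaled.index[i] for i in leaves_list(Z)]


def classify_colonizers(
    scaled: pd.DataFrame, meta: pd.DataFrame
) -> dict[str, str]:
    """Early/late class per ASV from per-timepoint mean scaled abundance.

    The class is early iff the argmax timepoint over the means at 2, 7, 14
    and 28 dpr lies in {2, 7}; ties break toward the earlier timepoint.
    ASVs absent from every recolonization sample are excluded with a warning.
    """
    meta = meta.loc[scaled.columns]
    means = np.empty((scaled.shape[0], len(POST_TIMEPOINTS)))
    for j, tp in enumerate(POST_TIMEPOINTS):
        cols = scaled.columns[(meta["timepoint"] == tp).to_numpy()]
        if len(cols) == 0:
            raise SchemaError(f"no samples at timepoint {tp}")
        means[:, j] = scaled[cols].to_numpy().mean(axis=1)
    classes: dict[str, str] = {}
    for i, asv in enumerate(scaled.index):
        if means[i].max() == 0:
            warnings.warn(
                f"ASV {asv} absent from all recolonization samples; excluded",
                stacklevel=2,
            )
            continue
        peak = POST_TIMEPOINTS[int(np.argmax(means[i]))]  # argmax = earliest tie
        classes[asv] = "early" if peak in (2, 7) else "late"
    return classes


def succession_profile(
    rel: pd.DataFrame,
    meta: pd.DataFrame,
    min_abund: float = DEFAULT_MIN_ABUND,
    class_override: dict[str, str] | None = None,
) -> SuccessionProfile:
    """Run the full succession analysis on one substrate's table.

    ``class_override`` lets a user-supplied class table replace the
    automatic early/late rule for selected ASVs (the display rule is
    deterministic; curation stays explicit).
    """
    asv_ids = filter_core_asvs(rel, meta, min_abund=min_abund)
    if not asv_ids:
        raise SchemaError("no ASVs pass the core filter")
    scaled, block = scale_blocks(rel, meta, asv_ids)
    recol_cols = scaled.columns[(block != INOCULUM_TIMEPOINT).to_numpy()]
    class_of = classify_colonizers(scaled[recol_cols], meta.loc[recol_cols])
    if class_override:
        class_of.update({k: v for k, v in class_override.items() if k in scaled.index})
    return SuccessionProfile(
        asv_ids=asv_ids,
        scaled=scaled,
        block_of=block,
        order=order_rows(scaled),
        class_of=class_of,
    )
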