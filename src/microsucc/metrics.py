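"""Alpha diversity, dissimilarity matrices, ordination and permutation tests.

Implements the beta-diversity statistics a recolonization time series is
summarised with: Bray-Curtis / Jaccard / binary Jaccard / Jensen-Shannon
distances, classical PCoA, one-way PERMANOVA (adonis-style pseudo-F with an
R-squared effect size), ANOSIM, and a tie-corrected Kruskal-Wallis test.

The permutation tests permute whole-sample labels and report
p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations); with
``n_permutations="exhaustive"`` every distinct label assignment is
enumerated instead and p is the exact tail fraction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon, pdist, squareform
from scipy.stats import chi2, rankdata

from .errors import SchemaError
from .io import CommunityTable

METRICS = ("bray_curtis", "jaccard", "binary_jaccard", "jensen_shannon")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise sample dissimilarities with zero diagonal."""

    d: np.ndarray
    sample_ids: list[str]
    metric_name: str

    def validate(self) -> "DistanceMatrix":
        d = np.asarray(self.d, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have zero diagonal")
        if (d < -1e-12).any():
            raise ValueError("distances must be non-negative")
        self.d = d
        return self

    @property
    def n(self) -> int:
        return self.d.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


@dataclass
class PermTestResult:
    statistic: float
    effect: float | None
    p_value: float
    n_permutations: int
    seed: int | None
    method: str = ""


# ---------------------------------------------------------------------------
# abundance transforms and alpha diversity


def relative_abundance(table: CommunityTable) -> pd.DataFrame:
    """Per-sample relative abundances; each row sums to 1."""
    counts = table.counts
    totals = counts.sum(axis=1)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise SchemaError(f"samples with zero total count: {zero}")
    return counts.div(totals, axis=0)


def chao1(counts_row) -> float:
    """Bias-corrected Chao1 richness: S_obs + f1(f1-1) / (2(f2+1))."""
    arr = np.asarray(counts_row)
    if not np.all(arr == np.floor(arr)) or (arr < 0).any():
        raise ValueError("chao1 requires non-negative integer counts")
    arr = arr.astype(np.int64)
    s_obs = int((arr > 0).sum())
    f1 = int((arr == 1).sum())
    f2 = int((arr == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


# ---------------------------------------------------------------------------
# distances


def distance_matrix(rel: pd.DataFrame, metric: str) -> DistanceMatrix:
    """Pairwise sample dissimilarities on a relative-abundance table.

    bray_curtis:   1 - 2*sum(min(x,y)) / (sum x + sum y)
    jaccard:       2*BC / (1 + BC)  (the abundance-weighted Jaccard, as
                   vegan derives it from Bray-Curtis)
    binary_jaccard: Jaccard on presence/absence
    jensen_shannon: sqrt of the Jensen-Shannon divergence, log base 2
    """
    X = rel.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("relative-abundance table contains NaN")
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if metric == "bray_curtis":
        vec = pdist(X, metric="braycurtis")
    elif metric == "jaccard":
        bc = pdist(X, metric="braycurtis")
        vec = 2.0 * bc / (1.0 + bc)
    elif metric == "binary_jaccard":
        vec = pdist(X > 0, metric="jaccard")
    else:  # jensen_shannon
        n = X.shape[0]
        vec = np.empty(n * (n - 1) // 2)
        k = 0
        for i in range(n):
            for j in range(i + 1, n):
                vec[k] = jensenshannon(X[i], X[j], base=2)
                k += 1
    d = squareform(np.nan_to_num(vec, nan=0.0))
    return DistanceMatrix(
        d=d, sample_ids=list(rel.index), metric_name=metric
    ).validate()


# ---------------------------------------------------------------------------
# ordination


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Classical metric scaling: double-centre -0.5 * J D^2 J, eigendecompose,
    scale eigenvectors by sqrt(eigenvalue).  Negative eigenvalues (non-
    Euclidean input) are dropped; proportions are relative to the positive
    eigenvalue total."""
    dm.validate()
    d2 = dm.d**2
    n = dm.n
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    B = (B + B.T) / 2.0
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(1e-10, 1e-10 * abs(eigval).max()) if eigval.size else 0.0
    pos = eigval > tol
    n_pos = int(pos.sum())
    if n_axes is None:
        n_axes = n_pos
    if n_axes > n_pos:
        import warnings

        warnings.warn(
            f"requested {n_axes} axes but only {n_pos} positive eigenvalues; "
            "truncating",
            stacklevel=2,
        )
        n_axes = n_pos
    lam = eigval[:n_axes]
    coords = eigvec[:, :n_axes] * np.sqrt(lam)
    total = eigval[pos].sum()
    prop = lam / total if total > 0 else np.zeros_like(lam)
    frame = pd.DataFrame(
        coords,
        index=dm.sample_ids,
        columns=[f"PCo{i + 1}" for i in range(n_axes)],
    )
    return OrdinationResult(coordinates=frame, eigenvalues=lam, proportion_explained=prop)


# ---------------------------------------------------------------------------
# permutation tests


def _check_groups(groups: np.ndarray) -> list[np.ndarray]:
    labels, inv = np.unique(groups, return_inverse=True)
    if labels.size < 2:
        raise ValueError("need at least two groups")
    idx = [np.nonzero(inv == k)[0] for k in range(labels.size)]
    small = [str(labels[k]) for k, ix in enumerate(idx) if ix.size < 2]
    if small:
        raise ValueError(f"groups with fewer than 2 samples: {small}")
    return idx


def _pseudo_f(d2: np.ndarray, group_idx: list[np.ndarray]) -> tuple[float, float]:
    """One-way PERMANOVA pseudo-F and R^2 from squared distances."""
    n = d2.shape[0]
    a = len(group_idx)
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for ix in group_idx:
        sub = d2[np.ix_(ix, ix)]
        ss_within += sub[np.triu_indices(ix.size, k=1)].sum() / ix.size
    ss_between = ss_total - ss_within
    f = (ss_between / (a - 1)) / (ss_within / (n - a)) if ss_within > 0 else np.inf
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return f, r2


def _permutation_p(
    stat_fn,
    groups: np.ndarray,
    n_permutations,
    seed: int | None,
) -> tuple[float, int]:
    obs = stat_fn(groups)
    if n_permutations == "exhaustive":
        stats = [stat_fn(g) for g in _iter_exhaustive(groups)]
        n_perm = len(stats)
        p = sum(s >= obs - 1e-12 for s in stats) / n_perm
        return p, n_perm
    rng = np.random.default_rng(seed)
    n_perm = int(n_permutations)
    hits = 0
    g = groups.copy()
    for _ in range(n_perm):
        rng.shuffle(g)
        if stat_fn(g) >= obs - 1e-12:
            hits += 1
    return (1 + hits) / (1 + n_perm), n_perm


def _iter_exhaustive(groups: np.ndarray):
    """Every distinct relabelling of the samples (multiset permutation),
    including the identity."""
    from sympy.utilities.iterables import multiset_permutations

    for perm in multiset_permutations(list(groups)):
        yield np.asarray(perm, dtype=groups.dtype)


def permanova(
    dm: DistanceMatrix,
    groups,
    n_permutations: int | str = 999,
    seed: int | None = 0,
) -> PermTestResult:
    """One-way PERMANOVA (adonis): pseudo-F from squared-distance partitions,
    R^2 = SS_between / SS_total, permutation p-value over sample labels."""
    dm.validate()
    groups = np.asarray(groups)
    if groups.size != dm.n:
        raise ValueError("groups length must match distance matrix")
    _check_groups(groups)
    d2 = dm.d**2

    def stat(g: np.ndarray) -> float:
        return _pseudo_f(d2, _check_groups_nocheck(g))[0]

    f_obs, r2 = _pseudo_f(d2, _check_groups(groups))
    p, n_perm = _permutation_p(stat, groups, n_permutations, seed)
    return PermTestResult(
        statistic=f_obs,
        effect=r2,
        p_value=p,
        n_permutations=n_perm,
        seed=seed if n_permutations != "exhaustive" else None,
        method="permanova",
    )


def _check_groups_nocheck(groups: np.ndarray) -> list[np.ndarray]:
    labels, inv = np.unique(groups, return_inverse=True)
    return [np.nonzero(inv == k)[0] for k in range(labels.size)]


def anosim(
    dm: DistanceMatrix,
    groups,
    n_permutations: int | str = 999,
    seed: int | None = 0,
) -> PermTestResult:
    """ANOSIM: R = (mean rank between - mean rank within) / (n(n-1)/4),
    midranks for ties, permutation p-value as in :func:`permanova`."""
    dm.validate()
    groups = np.asarray(groups)
    if groups.size != dm.n:
        raise ValueError("groups length must match distance matrix")
    _check_groups(groups)
    n = dm.n
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(dm.d[iu])  # midranks
    denom = n * (n - 1) / 4.0

    def stat(g: np.ndarray) -> float:
        within = g[iu[0]] == g[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / denom

    r_obs = stat(groups)
    p, n_perm = _permutation_p(stat, groups, n_permutations, seed)
    return PermTestResult(
        statistic=r_obs,
        effect=None,
        p_value=p,
        n_permutations=n_perm,
        seed=seed if n_permutations != "exhaustive" else None,
        method="anosim",
    )


def pairwise_permanova(
    dm: DistanceMatrix,
    groups,
    n_permutations: int | str = 999,
    seed: int | None = 0,
) -> pd.DataFrame:
    """PERMANOVA on every group pair, Benjamini-Hochberg across pairs.

    Returns a tidy frame (group_a, group_b, pseudo_f, r2, p, q)."""
    groups = np.asarray(groups)
    labels = np.unique(groups)
    rows = []
    for a, b in itertools.combinations(labels, 2):
        mask = np.isin(groups, (a, b))
        idx = np.nonzero(mask)[0]
        sub = DistanceMatrix(
            d=dm.d[np.ix_(idx, idx)],
            sample_ids=[dm.sample_ids[i] for i in idx],
            metric_name=dm.metric_name,
        )
        res = permanova(sub, groups[idx], n_permutations=n_permutations, seed=seed)
        rows.append((a, b, res.statistic, res.effect, res.p_value))
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "pseudo_f", "r2", "p"])
    out["q"] = benjamini_hochberg(out["p"].to_numpy())
    return out


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH step-up adjusted q-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def kruskal_wallis(*groups) -> PermTestResult:
    """Tie-corrected Kruskal-Wallis H with a chi-squared (k-1 df) p-value."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    obs = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size < 1 for g in obs):
        raise ValueError("every group needs at least one observation")
    pooled = np.concatenate(obs)
    n = pooled.size
    ranks = rankdata(pooled)
    h = 0.0
    start = 0
    for g in obs:
        r = ranks[start : start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    ties = ((counts**3 - counts).sum()) / (n**3 - n) if n > 1 else 0.0
    correction = 1.0 - ties
    if correction <= 0:  # all observations identical
        return PermTestResult(
            statistic=0.0, effect=None, p_value=1.0, n_permutations=0, seed=None,
            method="kruskal_wallis",
        )
    h /= correction
    df = len(obs) - 1
    p = float(chi2.sf(h, df))
    return PermTestResult(
        statistic=float(h), effect=None, p_value=p, n_permutations=0, seed=None,
        method="kruskal_wallis",
    )
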