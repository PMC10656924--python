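"""Shadow-feature random-forest selection of stage-separating pathways.

Samples from 2 and 7 days post recolonization are labelled *early*, those
from 14 and 28 dpr *late*.  A Boruta-style procedure decides which pathway
abundances separate the stages: each undecided feature gets a value-permuted
shadow copy, a random forest is fit on real + shadow features, and a real
feature scores a *hit* when its importance beats the best shadow.  Hits
accumulate over iterations and one-sided binomial tests at level alpha
confirm (significantly more hits than half) or reject (significantly fewer)
features; survivors at max_iter stay tentative.

Selection is repeated with independent seeds; the *consistent set* is the
intersection of confirmed features over repeats.  Reported importances are
the forest's impurity importances (mean decrease in impurity), normalised
per repeat so the best pathway scores 1, then averaged — this makes the
subsystem score threshold of 0.5 a meaningful fraction of the top
pathway's importance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .errors import SchemaError
from .io import INOCULUM_TIMEPOINT

EARLY_DAYS = (2, 7)
LATE_DAYS = (14, 28)

DEFAULT_N_TREES = 500
DEFAULT_MAX_ITER = 100
DEFAULT_ALPHA = 0.01
DEFAULT_N_REPEATS = 10
DEFAULT_SUBSYSTEM_THRESHOLD = 0.5


def label_stages(meta: pd.DataFrame) -> pd.Series:
    """Sample -> "early" (2, 7 dpr) or "late" (14, 28 dpr); inoculum samples
    are excluded.  Unknown timepoints raise :class:`SchemaError`."""
    labels = {}
    for sid, tp in meta["timepoint"].items():
        if tp == INOCULUM_TIMEPOINT:
            continue
        if tp in EARLY_DAYS:
            labels[sid] = "early"
        elif tp in LATE_DAYS:
            labels[sid] = "late"
        else:
            raise SchemaError(f"unknown timepoint {tp!r} for sample {sid}")
    return pd.Series(labels, name="stage")


@dataclass
class BorutaResult:
    """One repeat: per-feature decision plus importances."""

    decision: dict[str, str]               # confirmed / rejected / tentative
    importance: dict[str, float]           # permutation importance (raw)
    hit_fraction: dict[str, float]         # shadow-race hits / iterations
    n_iter: int
    seed: int

    @property
    def confirmed(self) -> set[str]:
        return {f for f, d in self.decision.items() if d == "confirmed"}


def _check_classes(y: np.ndarray, min_per_class: int = 4) -> None:
    labels, counts = np.unique(y, return_counts=True)
    if labels.size < 2:
        raise ValueError("need two classes")
    small = [str(l) for l, c in zip(labels, counts) if c < min_per_class]
    if small:
        raise ValueError(f"classes with fewer than {min_per_class} samples: {small}")


def boruta_select(
    X: pd.DataFrame,
    y,
    n_trees: int = DEFAULT_N_TREES,
    max_iter: int = DEFAULT_MAX_ITER,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
) -> BorutaResult:
    """One Boruta repeat on a samples x features matrix.

    Features are decided by accumulating shadow-race hits and applying
    one-sided binomial tests each iteration, Bonferroni-adjusted across
    features (family level ``alpha``, as in the reference Boruta
    implementation); the loop stops when nothing is undecided or at
    ``max_iter``.
    """
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features")
    y = np.asarray(y)
    _check_classes(y)
    rng = np.random.default_rng(seed)
    features = list(X.columns)
    Xv = X.to_numpy(float)
    undecided = set(features)
    hits = {f: 0 for f in features}
    trials = {f: 0 for f in features}
    decision = {f: "tentative" for f in features}

    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        active = [f for f in features if f in undecided]
        cols = [features.index(f) for f in active]
        Xa = Xv[:, cols]
        # shadows of ALL original features, re-permuted each iteration: the
        # shadow maximum stays the max of m fresh null importances, so a
        # fixed chance association (a draw from the same max-of-m law) wins
        # only about half the races and is never confirmed
        shadow = Xv.copy()
        for j in range(shadow.shape[1]):
            rng.shuffle(shadow[:, j])
        data = np.hstack([Xa, shadow])
        rf = RandomForestClassifier(
            n_estimators=n_trees,
            random_state=int(rng.integers(0, 2**31 - 1)),
            n_jobs=1,
        )
        rf.fit(data, y)
        imp = rf.feature_importances_
        shadow_max = imp[len(active):].max() if len(active) else 0.0
        for k, f in enumerate(active):
            trials[f] += 1
            if imp[k] > shadow_max:
                hits[f] += 1
        # binomial decisions on the accumulated record, Bonferroni-adjusted
        # across the feature family
        alpha_adj = alpha / len(features)
        for f in list(undecided):
            n, h = trials[f], hits[f]
            if binom.sf(h - 1, n, 0.5) < alpha_adj:
                decision[f] = "confirmed"
                undecided.discard(f)
            elif binom.cdf(h, n, 0.5) < alpha_adj:
                decision[f] = "rejected"
                undecided.discard(f)
        if not undecided:
            break

    # reported importance: impurity importance (mean decrease in impurity)
    # of a forest on the real features only.  With strongly separating,
    # mutually redundant features a leave-one-out permutation importance is
    # identically zero, so the split-based measure is the informative one.
    rf = RandomForestClassifier(
        n_estimators=n_trees, random_state=int(rng.integers(0, 2**31 - 1)), n_jobs=1
    )
    rf.fit(Xv, y)
    importance = {
        f: max(float(v), 0.0) for f, v in zip(features, rf.feature_importances_)
    }
    hit_fraction = {
        f: hits[f] / trials[f] if trials[f] else 0.0 for f in features
    }
    return BorutaResult(
        decision=decision,
        importance=importance,
        hit_fraction=hit_fraction,
        n_iter=n_iter,
        seed=seed,
    )


@dataclass
class SelectionResult:
    """Aggregate over repeated Boruta runs plus downstream summaries."""

    importance: dict[str, float]           # mean normalised importance in [0,1]
    decision: dict[str, str]               # aggregated over repeats
    consistent_set: list[str]
    n_repeats: int
    seed: int
    per_repeat: list[BorutaResult] = field(default_factory=list)
    cv_accuracy: float | None = None
    subsystem_score: dict[str, float] = field(default_factory=dict)
    lfc: dict[str, float] = field(default_factory=dict)


def repeated_selection(
    X: pd.DataFrame,
    y,
    n_repeats: int = DEFAULT_N_REPEATS,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
    max_iter: int = DEFAULT_MAX_ITER,
    alpha: float = DEFAULT_ALPHA,
) -> SelectionResult:
    """Repeat Boruta with independent seeds and intersect confirmed sets.

    Importance is each repeat's impurity importance scaled to max 1,
    averaged over repeats.  The aggregated decision is confirmed for the
    consistent set, rejected for features rejected in every repeat, and
    tentative otherwise.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rng = np.random.default_rng(seed)
    repeats = [
        boruta_select(
            X, y, n_trees=n_trees, max_iter=max_iter, alpha=alpha,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        for _ in range(n_repeats)
    ]
    features = list(X.columns)
    consistent = set(features)
    for r in repeats:
        consistent &= r.confirmed
    norm_imps = []
    for r in repeats:
        vals = np.array([r.importance[f] for f in features])
        mx = vals.max()
        norm_imps.append(vals / mx if mx > 0 else vals)
    mean_imp = np.mean(norm_imps, axis=0)
    decision = {}
    for f in features:
        if f in consistent:
            decision[f] = "confirmed"
        elif all(r.decision[f] == "rejected" for r in repeats):
            decision[f] = "rejected"
        else:
            decision[f] = "tentative"
    return SelectionResult(
        importance={f: float(v) for f, v in zip(features, mean_imp)},
        decision=decision,
        consistent_set=sorted(consistent),
        n_repeats=n_repeats,
        seed=seed,
        per_repeat=repeats,
    )


def cv_accuracy(
    X: pd.DataFrame,
    y,
    k: int = 5,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
) -> float:
    """Pooled stratified k-fold accuracy of a random forest on ``X``."""
    if X.shape[1] < 1:
        raise ValueError("feature set is empty")
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if k > counts.min():
        raise ValueError(f"k={k} exceeds smallest class size {counts.min()}")
    rng = np.random.default_rng(seed)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(rng.integers(0, 2**31 - 1)))
    Xv = X.to_numpy(float)
    correct = 0
    for train, test in skf.split(Xv, y):
        rf = RandomForestClassifier(
            n_estimators=n_trees, random_state=int(rng.integers(0, 2**31 - 1)),
            n_jobs=1,
        )
        rf.fit(Xv[train], y[train])
        correct += int((rf.predict(Xv[test]) == y[test]).sum())
    return correct / y.size


def subsystem_scores(
    importance: dict[str, float],
    confirmed: set[str] | list[str],
    subsystem_of: dict[str, str],
    threshold: float = DEFAULT_SUBSYSTEM_THRESHOLD,
) -> dict[str, float]:
    """Sum confirmed pathways' importances per subsystem; keep scores >=
    ``threshold``."""
    confirmed = set(confirmed)
    totals: dict[str, float] = {}
    for p, imp in importance.items():
        if p not in confirmed:
            continue
        sub = subsystem_of.get(p, "unassigned")
        totals[sub] = totals.get(sub, 0.0) + imp
    return {s: v for s, v in totals.items() if v >= threshold}


def early_late_lfc(
    X: pd.DataFrame, y, pseudocount: float = 1e-6
) -> dict[str, float]:
    """Signed log2 fold change per pathway: log2((mean_late + pc) /
    (mean_early + pc)).  Early-enriched pathways come out negative."""
    y = np.asarray(y)
    early = X.loc[y == "early"]
    late = X.loc[y == "late"]
    if early.empty or late.empty:
        raise ValueError("both stages must be populated")
    me = early.mean(axis=0) + pseudocount
    ml = late.mean(axis=0) + pseudocount
    return dict(np.log2(ml / me))


def select_pathways(
    A: pd.DataFrame,
    meta: pd.DataFrame,
    subsystem_of: dict[str, str] | None = None,
    n_repeats: int = DEFAULT_N_REPEATS,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
    max_iter: int = DEFAULT_MAX_ITER,
    alpha: float = DEFAULT_ALPHA,
    k: int = 5,
    subsystem_threshold: float = DEFAULT_SUBSYSTEM_THRESHOLD,
) -> SelectionResult:
    """End-to-end selection on a pathways x samples abundance matrix.

    Labels stages from ``meta``, runs repeated Boruta, then fills in CV
    accuracy (on the consistent set), subsystem scores and fold changes.
    """
    stages = label_stages(meta)
    X = A.T.loc[stages.index]  # samples x pathways
    result = repeated_selection(
        X, stages.to_numpy(), n_repeats=n_repeats, seed=seed,
        n_trees=n_trees, max_iter=max_iter, alpha=alpha,
    )
    if result.consistent_set:
        result.cv_accuracy = cv_accuracy(
            X[result.consistent_set], stages.to_numpy(), k=k,
            seed=seed, n_trees=n_trees,
        )
    if subsystem_of:
        result.subsystem_score = subsystem_scores(
            result.importance, result.consistent_set, subsystem_of,
            threshold=subsystem_threshold,
        )
    result.lfc = early_late_lfc(X, stages.to_numpy())
    return result
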