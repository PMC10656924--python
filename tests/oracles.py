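"""Independent reference implementations used as test oracles.

Everything here is deliberately written from the definitions (explicit
loops, enumeration, memoised recursion) and shares no code with the
package under test.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np

# ---------------------------------------------------------------------------
# PERMANOVA / ANOSIM by full enumeration


def pseudo_f_reference(d: np.ndarray, groups) -> float:
    """Pseudo-F from first principles: SS via explicit pair loops."""
    groups = list(groups)
    n = len(groups)
    labels = sorted(set(groups))
    ss_total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ss_total += d[i, j] ** 2
    ss_total /= n
    ss_within = 0.0
    for g in labels:
        idx = [i for i in range(n) if groups[i] == g]
        acc = 0.0
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                acc += d[idx[a], idx[b]] ** 2
        ss_within += acc / len(idx)
    ss_between = ss_total - ss_within
    return (ss_between / (len(labels) - 1)) / (ss_within / (n - len(labels)))


def exhaustive_permanova_p(d: np.ndarray, groups) -> float:
    """Exact tail fraction of F over all distinct label assignments."""
    obs = pseudo_f_reference(d, groups)
    perms = set(itertools.permutations(groups))
    hits = sum(pseudo_f_reference(d, list(p)) >= obs - 1e-12 for p in perms)
    return hits / len(perms)


def _midranks(values) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def anosim_r_reference(d: np.ndarray, groups) -> float:
    groups = list(groups)
    n = len(groups)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    ranks = _midranks([d[i, j] for i, j in pairs])
    within = [r for r, (i, j) in zip(ranks, pairs) if groups[i] == groups[j]]
    between = [r for r, (i, j) in zip(ranks, pairs) if groups[i] != groups[j]]
    return (sum(between) / len(between) - sum(within) / len(within)) / (
        n * (n - 1) / 4
    )


def exhaustive_anosim_p(d: np.ndarray, groups) -> float:
    obs = anosim_r_reference(d, groups)
    perms = set(itertools.permutations(groups))
    hits = sum(anosim_r_reference(d, list(p)) >= obs - 1e-12 for p in perms)
    return hits / len(perms)


# ---------------------------------------------------------------------------
# Needleman-Wunsch with affine gaps (open applies to the first gap column)

MATCH, MISMATCH, OPEN, EXTEND = 1.0, -1.0, -2.0, -1.0
NEG = float("-inf")


def nw_reference(a: str, b: str) -> tuple[float, set[tuple[int, int]]]:
    """Optimal global alignment score and the set of (matches, columns)
    pairs attained by score-optimal alignments.  Matches never include N."""

    def sub(x: str, y: str) -> float:
        return MATCH if (x == y and x != "N") else MISMATCH

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        cands = []
        if i < len(a) and j < len(b):
            cands.append(sub(a[i], b[j]) + best(i + 1, j + 1, "M"))
        if i < len(a):
            cands.append((EXTEND if state == "X" else OPEN) + best(i + 1, j, "X"))
        if j < len(b):
            cands.append((EXTEND if state == "Y" else OPEN) + best(i, j + 1, "Y"))
        return max(cands)

    @lru_cache(maxsize=None)
    def outcomes(i: int, j: int, state: str) -> frozenset:
        """(matches, columns) pairs over optimal completions from here."""
        if i == len(a) and j == len(b):
            return frozenset({(0, 0)})
        target = best(i, j, state)
        acc = set()
        if i < len(a) and j < len(b):
            step = sub(a[i], b[j])
            if step + best(i + 1, j + 1, "M") == target:
                is_match = int(a[i] == b[j] and a[i] != "N")
                acc |= {(m + is_match, c + 1)
                        for m, c in outcomes(i + 1, j + 1, "M")}
        if i < len(a):
            step = EXTEND if state == "X" else OPEN
            if step + best(i + 1, j, "X") == target:
                acc |= {(m, c + 1) for m, c in outcomes(i + 1, j, "X")}
        if j < len(b):
            step = EXTEND if state == "Y" else OPEN
            if step + best(i, j + 1, "Y") == target:
                acc |= {(m, c + 1) for m, c in outcomes(i, j + 1, "Y")}
        return frozenset(acc)

    return best(0, 0, "S"), set(outcomes(0, 0, "S"))
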