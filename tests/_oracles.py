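"""Independent reference implementations used only to check the package.

Everything here is deliberately naive — memoized recursion, explicit loops,
exhaustive enumeration — and shares no code with the implementations under
test.
"""

from __future__ import annotations

import math
from functools import lru_cache


def levenshtein_recursive(a: str, b: str) -> int:
    """Memoized textbook recursion for unit-cost edit distance."""

    @lru_cache(maxsize=None)
    def d(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        return min(
            d(i - 1, j) + 1,
            d(i, j - 1) + 1,
            d(i - 1, j - 1) + (a[i - 1] != b[j - 1]),
        )

    return d(len(a), len(b))


def sphere_exclusion_reference(square, threshold, predicate="strict", recount="dynamic"):
    """Plain-python sphere exclusion; returns list of (centroid, sorted members).

    Neighbour predicate d < t (strict) or d <= t (inclusive); centroid is the
    unassigned item with the most (unassigned, for the dynamic variant)
    neighbours, lowest index on ties.
    """
    n = len(square)
    ok = (lambda d: d < threshold) if predicate == "strict" else (lambda d: d <= threshold)
    neigh = [
        [j for j in range(n) if j != i and ok(square[i][j])] for i in range(n)
    ]
    static = [len(lst) for lst in neigh]
    unassigned = set(range(n))
    clusters = []
    while unassigned:
        best, best_count = None, -1
        for i in sorted(unassigned):
            c = (
                sum(1 for j in neigh[i] if j in unassigned)
                if recount == "dynamic"
                else static[i]
            )
            if c > best_count:
                best, best_count = i, c
        members = [best] + [j for j in neigh[best] if j in unassigned]
        unassigned -= set(members)
        clusters.append((best, sorted(set(members))))
    return clusters


def confusion_metrics_reference(labels, scores, threshold=0.5):
    """Loop-based confusion matrix, accuracy, precision and MCC."""
    tp = fp = tn = fn = 0
    for y, s in zip(labels, scores):
        pred = s >= threshold
        if pred and y == 1:
            tp += 1
        elif pred and y == 0:
            fp += 1
        elif not pred and y == 0:
            tn += 1
        else:
            fn += 1
    n = tp + fp + tn + fn
    accuracy = (tp + tn) / n
    precision = tp / (tp + fp) if tp + fp else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return {"tp": tp, "fp": fp, "tn": tn, "fn": fn,
            "accuracy": accuracy, "precision": precision, "mcc": mcc}


def auc_pair_enumeration(labels, scores):
    """AUC by exhaustive positive/negative pair counting (ties = 1/2)."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    if not pos or not neg:
        return float("nan")
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def composition_stats_reference(sequences, residues):
    """Two-pass per-residue mean/std of per-sequence fractions."""
    fracs = [
        [s.count(r) / len(s) for r in residues] for s in sequences
    ]
    n = len(fracs)
    mean = [sum(f[k] for f in fracs) / n for k in range(len(residues))]
    std = [
        math.sqrt(sum((f[k] - mean[k]) ** 2 for f in fracs) / n)
        for k in range(len(residues))
    ]
    return mean, std
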