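"""Independent brute-force reference implementations used only by tests.

Each function re-derives a quantity from first principles (exhaustive
loops, combinatorial sums, direct rule application) without touching the
package's own code paths, so agreement is a meaningful cross-check.
"""

from __future__ import annotations

import math
from itertools import combinations

BASES = "ACGT"
COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def brute_recurrence(keys_by_cell: dict[str, list]) -> dict:
    """Distinct-cell detection counts by scanning every (cell, key) pair."""
    all_keys = {k for keys in keys_by_cell.values() for k in keys}
    out = {}
    for key in all_keys:
        n = 0
        for cell in keys_by_cell:
            if key in keys_by_cell[cell]:
                n += 1
        out[key] = n
    return out


def brute_labels(
    calls_by_cell: dict[str, list[dict]],
    s_keys_by_cell: dict[str, set],
    n_cells: int,
    min_depth: int = 3,
    floor: int = 3,
    lower_frac: float = 0.10,
    upper_frac: float = 0.80,
    qd_min: float = 2.0,
    fs_max: float = 30.0,
) -> dict:
    """Direct, unoptimized application of the labeling rules.

    ``calls_by_cell`` maps cell -> list of dicts with keys
    key/dp/qd/fs/ad_alt (qd/fs may be None).
    """
    lower = max(floor, math.ceil(lower_frac * n_cells - 1e-9))
    upper = math.floor(upper_frac * n_cells + 1e-9)

    def qpass(c):
        return (
            c["dp"] >= min_depth
            and (c["qd"] is None or c["qd"] >= qd_min)
            and (c["fs"] is None or c["fs"] <= fs_max)
            and c["ad_alt"] >= 1
        )

    all_keys = {c["key"] for calls in calls_by_cell.values() for c in calls}
    labels = {}
    for key in all_keys:
        rec = sum(
            1 for cell in calls_by_cell if any(c["key"] == key for c in calls_by_cell[cell])
        )
        has_a = any(
            key in s_keys_by_cell.get(cell, set())
            and any(c["key"] == key for c in calls_by_cell[cell])
            for cell in calls_by_cell
        )
        a_pass = any(
            key in s_keys_by_cell.get(cell, set()) and qpass(c)
            for cell in calls_by_cell
            for c in calls_by_cell[cell]
            if c["key"] == key
        )
        any_pass = any(
            qpass(c) for cell in calls_by_cell for c in calls_by_cell[cell] if c["key"] == key
        )
        if rec > upper:
            labels[key] = "removed"
        elif a_pass and rec >= lower:
            labels[key] = "positive"
        elif not has_a and not any_pass and rec == 1:
            labels[key] = "negative"
        else:
            labels[key] = "unsure"
    return labels


def brute_auc(y, scores) -> float:
    """Fraction of correctly ordered (pos, neg) pairs, half credit for ties."""
    pos = [s for yy, s in zip(y, scores) if yy == 1]
    neg = [s for yy, s in zip(y, scores) if yy == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_sbs96(ref: str, alt: str, five: str, three: str) -> int:
    """SBS96 class by explicit enumeration of the canonical ordering."""
    ordering = []
    for pyr, mut in (
        ("C", "A"), ("C", "G"), ("C", "T"), ("T", "A"), ("T", "C"), ("T", "G"),
    ):
        for f in BASES:
            for t in BASES:
                ordering.append((pyr, mut, f, t))
    if ref in "GA":
        ref, alt = COMP[ref], COMP[alt]
        five, three = COMP[three], COMP[five]
    return ordering.index((ref, alt, five, three))


def brute_hypergeom_upper(k: int, N: int, K: int, n: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, K, n) by combinatorial summation."""
    total = 0
    for j in range(k, min(K, n) + 1):
        total += math.comb(K, j) * math.comb(N - K, n - j)
    return total / math.comb(N, n)


def brute_hypergeom_by_enumeration(k: int, N: int, K: int, n: int) -> float:
    """Same tail probability by enumerating every n-subset of N items (N small)."""
    items = [1] * K + [0] * (N - K)
    hits = 0
    total = 0
    for combo in combinations(range(N), n):
        total += 1
        if sum(items[i] for i in combo) >= k:
            hits += 1
    return hits / total


def brute_fbeta(precision: float, sensitivity: float, beta: float) -> float:
    """Generic F-beta score."""
    b2 = beta * beta
    return (1 + b2) * precision * sensitivity / (b2 * precision + sensitivity)
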