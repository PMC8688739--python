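"""Independently coded brute-force oracles for the repertoire statistics.

Everything here is deliberately written with plain-Python loops and dicts
(plus scipy's distance routine for the Jensen-Shannon cross-check) so the
vectorised implementations are checked against a structurally different
computation path.
"""

from __future__ import annotations

import math
from collections import Counter

from scipy.spatial.distance import jensenshannon


def entropy_bits(frequencies) -> float:
    h = 0.0
    for p in frequencies:
        if p > 0:
            h -= p * math.log2(p)
    return h


def clonality(counts) -> float:
    n = len(counts)
    if n == 1:
        return 1.0
    total = sum(counts)
    freqs = [c / total for c in counts]
    if len(set(counts)) == 1:
        return 0.0
    return 1.0 - entropy_bits(freqs) / math.log2(n)


def r20(counts, target=0.2) -> float:
    total = sum(counts)
    cum = 0.0
    for k, c in enumerate(sorted(counts, reverse=True), start=1):
        cum += c / total
        if cum >= target - 1e-12:
            return k / len(counts)
    return 1.0


def topn_cumfreq(counts, n) -> float:
    total = sum(counts)
    return sum(sorted(counts, reverse=True)[:n]) / total


def overlap_metric(counts_a: dict, counts_b: dict) -> float:
    shared = set(counts_a) & set(counts_b)
    if not shared:
        return 0.0
    fa = sum(counts_a[k] for k in shared) / sum(counts_a.values())
    fb = sum(counts_b[k] for k in shared) / sum(counts_b.values())
    return (fa + fb) / 2.0


def jsd(counts_a: dict, counts_b: dict) -> float:
    """Square of scipy's base-2 Jensen-Shannon distance on union-aligned vectors."""
    union = sorted(set(counts_a) | set(counts_b))
    ta, tb = sum(counts_a.values()), sum(counts_b.values())
    x = [counts_a.get(k, 0) / ta for k in union]
    y = [counts_b.get(k, 0) / tb for k in union]
    return float(jensenshannon(x, y, base=2) ** 2)


def venn_regions(keysets: list[set]) -> dict[tuple, int]:
    """Region counts keyed by the boolean membership vector."""
    union = set().union(*keysets)
    out: Counter = Counter()
    for key in union:
        out[tuple(key in s for s in keysets)] += 1
    return dict(out)


def rank_order(clones) -> list:
    """clones: iterable of (key, cdr3_aa, v, j, templates); returns keys by rank."""
    ordered = sorted(clones, key=lambda c: (-c[4], c[1], c[2], c[3]))
    return [c[0] for c in ordered]
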