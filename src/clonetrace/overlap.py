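"""Pairwise repertoire comparison: shared clones, overlap metric, JSD, Venn.

Three complementary views of how similar two samples are:

* **Shared clone count** — cardinality of the clonotype-key intersection.
* **Overlap metric** — for each sample, the fraction of its template mass
  carried by clones present in both samples; the two fractions are averaged.
  1 for identical key sets, 0 for disjoint repertoires.
* **Jensen–Shannon divergence (JSD)** — ``H((x+y)/2) − (H(x)+H(y))/2`` with
  base-2 logarithms over clone-frequency vectors aligned on the union of
  keys.  0 means identical repertoires with identical clone frequencies; 1
  means no shared clones.  (The base-2 Jensen–Shannon divergence is the only
  formulation with exactly those endpoints on the [0, 1] scale.)

"Shared reads" are shared *template* counts throughout: templates are the
platform's bias-corrected abundance unit.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .repio import DegenerateRepertoireError, KeyMode, Repertoire, RepertoireSet, TISSUE_ORDER

__all__ = [
    "OverlapResult",
    "PairwiseMatrix",
    "shared_clone_count",
    "overlap_metric",
    "jsd",
    "compare_pair",
    "pairwise_matrix",
    "venn_regions",
]


@dataclass(frozen=True)
class OverlapResult:
    """All pairwise statistics for one sample pair."""

    sample_a: str
    sample_b: str
    shared_clones: int
    overlap_metric: float
    jsd: float


@dataclass(frozen=True)
class PairwiseMatrix:
    """A symmetric sample-by-sample matrix of one statistic."""

    statistic: str
    values: pd.DataFrame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)


def _require_same_key(rep_a: Repertoire, rep_b: Repertoire) -> None:
    if rep_a.key != rep_b.key:
        raise ValueError(
            f"clonotype key mismatch: {rep_a.key.value!r} vs {rep_b.key.value!r}"
        )


def shared_clone_count(rep_a: Repertoire, rep_b: Repertoire) -> int:
    """Number of clonotype keys present in both samples."""
    _require_same_key(rep_a, rep_b)
    return len(rep_a.key_index().intersection(rep_b.key_index()))


def _overlap_from_counts(ca: pd.Series, cb: pd.Series) -> float:
    shared = ca.index.intersection(cb.index)
    if len(shared) == 0:
        return 0.0
    f_a = ca.loc[shared].sum() / ca.sum()
    f_b = cb.loc[shared].sum() / cb.sum()
    return float((f_a + f_b) / 2.0)


def overlap_metric(rep_a: Repertoire, rep_b: Repertoire) -> float:
    """Average of the two per-sample shared-template fractions, in [0, 1]."""
    _require_same_key(rep_a, rep_b)
    return _overlap_from_counts(rep_a.counts(), rep_b.counts())


def _entropy_bits(v: np.ndarray) -> float:
    v = v[v > 0]
    return float(-(v * np.log2(v)).sum())


def _jsd_from_counts(ca: pd.Series, cb: pd.Series) -> float:
    if len(ca.index.intersection(cb.index)) == 0:
        return 1.0  # disjoint supports: exact upper endpoint by construction
    x = ca / ca.sum()
    y = cb / cb.sum()
    x, y = x.align(y, fill_value=0.0)
    xv = x.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    m = (xv + yv) / 2.0
    value = _entropy_bits(m) - (_entropy_bits(xv) + _entropy_bits(yv)) / 2.0
    return float(min(1.0, max(0.0, value)))


def jsd(rep_a: Repertoire, rep_b: Repertoire) -> float:
    """Base-2 Jensen–Shannon divergence of the two clone-frequency vectors.

    Frequency vectors are aligned on the union of clonotype keys with absent
    clones at 0.  Identical repertoires give exactly 0; repertoires with no
    shared clones give exactly 1.
    """
    _require_same_key(rep_a, rep_b)
    return _jsd_from_counts(rep_a.counts(), rep_b.counts())


def compare_pair(rep_a: Repertoire, rep_b: Repertoire) -> OverlapResult:
    """All pairwise statistics for one sample pair in a single pass."""
    _require_same_key(rep_a, rep_b)
    ca, cb = rep_a.counts(), rep_b.counts()
    return OverlapResult(
        sample_a=rep_a.sample_id,
        sample_b=rep_b.sample_id,
        shared_clones=len(ca.index.intersection(cb.index)),
        overlap_metric=_overlap_from_counts(ca, cb),
        jsd=_jsd_from_counts(ca, cb),
    )


_STATISTICS = ("overlap", "jsd", "shared_count")


def pairwise_matrix(reps: RepertoireSet, statistic: str = "overlap") -> PairwiseMatrix:
    """Symmetric matrix of a pairwise statistic across all samples.

    Samples are ordered deterministically by (tissue order, mouse, day).  The
    diagonal is 1 for the overlap metric, 0 for JSD, and the sample's own
    clone count for shared counts.
    """
    if statistic not in _STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; expected one of {_STATISTICS}")
    ordered = sorted(
        reps,
        key=lambda r: (
            TISSUE_ORDER.index(r.meta.tissue),
            r.meta.mouse_id,
            r.meta.day,
            r.sample_id,
        ),
    )
    if len(ordered) < 2:
        raise ValueError("pairwise_matrix requires at least two samples")
    ids = [r.sample_id for r in ordered]
    counts = [r.counts() for r in ordered]
    n = len(ordered)
    mat = np.zeros((n, n), dtype=float)
    for i in range(n):
        if statistic == "overlap":
            mat[i, i] = 1.0
        elif statistic == "jsd":
            mat[i, i] = 0.0
        else:
            mat[i, i] = len(counts[i])
    for i, j in combinations(range(n), 2):
        if statistic == "overlap":
            v = _overlap_from_counts(counts[i], counts[j])
        elif statistic == "jsd":
            v = _jsd_from_counts(counts[i], counts[j])
        else:
            v = len(counts[i].index.intersection(counts[j].index))
        mat[i, j] = mat[j, i] = v
    values = pd.DataFrame(mat, index=ids, columns=ids)
    return PairwiseMatrix(statistic=statistic, values=values)


def venn_regions(reps: Sequence[Repertoire]) -> dict[str, int]:
    """Clone counts for every membership region of 2–4 repertoires.

    Returns all ``2^k − 1`` regions keyed by ``&``-joined sample ids, e.g.
    ``"blood&gut"`` for clones exclusive to the blood∩gut region.  Region
    counts sum to the size of the key union.
    """
    reps = list(reps)
    k = len(reps)
    if not 2 <= k <= 4:
        raise ValueError(f"venn_regions supports 2-4 repertoires, got {k}")
    key0 = reps[0].key
    for r in reps[1:]:
        if r.key != key0:
            raise ValueError("all repertoires must share a clonotype key mode")
    ids = [r.sample_id for r in reps]
    sets = [r.key_set() for r in reps]
    union = set().union(*sets)
    regions: dict[str, int] = {}
    for mask in range(1, 2**k):
        label = "&".join(ids[i] for i in range(k) if mask & (1 << i))
        regions[label] = 0
    for key in union:
        mask = sum(1 << i for i in range(k) if key in sets[i])
        label = "&".join(ids[i] for i in range(k) if mask & (1 << i))
        regions[label] += 1
    return regions
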