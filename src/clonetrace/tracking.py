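"""Clone ranking and cross-sample tracing.

Operations for following individual clonotypes through a transplant
experiment: ranking clones within a sample, locating a sample's top clones in
other tissues (rank heatmaps), tracing recipient top clones back to the
pre-transplant donor graft (detectability), finding clones shared across
replicate recipients within their top-k, and ranking a whole group's clones
by combined frequency.

Ranks use a stable, reproducible tie policy: templates descending, then CDR3
amino acid, V and J ascending lexicographically.  "Detectable" in the donor
means at least one template — no pseudo-counts and no abundance threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .repio import (
    CLONE_COLUMNS,
    KeyMode,
    Repertoire,
    RepertoireSet,
    SampleMeta,
)

__all__ = [
    "RankedClone",
    "TraceResult",
    "SharedClone",
    "CombinedClone",
    "rank_clones",
    "top_clones",
    "rank_in_target",
    "donor_traceback",
    "undetectable_fraction",
    "pool_repertoires",
    "cross_recipient_shared",
    "group_combined_top",
]


@dataclass(frozen=True)
class RankedClone:
    """One clone with its 1-based rank within a sample."""

    key: tuple
    cdr3_aa: str
    v_gene: str
    j_gene: str
    templates: int
    frequency: float
    rank: int


@dataclass(frozen=True)
class TraceResult:
    """Donor trace-back of one recipient clone."""

    key: tuple
    source_sample: str
    donor_templates: int
    donor_frequency: float
    detectable_in_donor: bool


@dataclass(frozen=True)
class SharedClone:
    """A clone found within the top-k of every mouse in a comparison."""

    key: tuple
    cdr3_aa: str
    ranks: Mapping[str, int]  # per-mouse rank in the membership repertoire


@dataclass(frozen=True)
class CombinedClone:
    """A clone ranked by combined template frequency across a sample group."""

    key: tuple
    cdr3_aa: str
    combined_frequency: float
    templates: int
    rank: int
    per_sample_frequency: Mapping[str, float] = field(default_factory=dict)


_TIE_COLUMNS = ["cdr3_aa", "v_gene", "j_gene"]


def _ranked_frame(rep: Repertoire) -> pd.DataFrame:
    df = rep.clones.sort_values(
        ["templates", *_TIE_COLUMNS],
        ascending=[False, True, True, True],
        kind="stable",
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def rank_clones(rep: Repertoire) -> list[RankedClone]:
    """All clones ordered by descending templates with a deterministic tie
    policy (CDR3 AA, then V, then J, ascending); ranks 1..N."""
    df = _ranked_frame(rep)
    total = float(df["templates"].sum())
    keycols = list(rep.key.columns)
    return [
        RankedClone(
            key=tuple(row[c] for c in keycols),
            cdr3_aa=row["cdr3_aa"],
            v_gene=row["v_gene"],
            j_gene=row["j_gene"],
            templates=int(row["templates"]),
            frequency=row["templates"] / total,
            rank=int(row["rank"]),
        )
        for row in df.to_dict("records")
    ]


def top_clones(rep: Repertoire, n: int) -> list[RankedClone]:
    """The ``n`` highest-ranked clones (all clones when ``n`` exceeds N)."""
    if n < 1:
        raise ValueError("n must be a positive integer")
    return rank_clones(rep)[:n]


def _as_key(item) -> tuple:
    if isinstance(item, RankedClone):
        return item.key
    if isinstance(item, tuple):
        return item
    return (item,)


def _rank_lookup(rep: Repertoire) -> dict[tuple, int]:
    return {c.key: c.rank for c in rank_clones(rep)}


def rank_in_target(keys: Iterable, target: Repertoire) -> list[tuple[tuple, int | None]]:
    """Rank of each query key in the target sample, or ``None`` when the key
    carries no templates there (the explicit absent marker)."""
    lookup = _rank_lookup(target)
    return [(k, lookup.get(k)) for k in map(_as_key, keys)]


def donor_traceback(
    recipient_top: Sequence[RankedClone],
    donor: Repertoire,
    source_sample: str | None = None,
) -> list[TraceResult]:
    """Frequency and detectability of recipient top clones in the donor graft.

    A clone is detectable when the donor sample carries at least one template
    for its key; absent keys report frequency 0.
    """
    donor_counts = donor.counts()
    donor_total = float(donor.total_templates)
    lookup = {k: int(v) for k, v in donor_counts.items()}
    out = []
    for clone in recipient_top:
        t = lookup.get(clone.key, 0)
        out.append(
            TraceResult(
                key=clone.key,
                source_sample=source_sample or "",
                donor_templates=t,
                donor_frequency=t / donor_total,
                detectable_in_donor=t >= 1,
            )
        )
    return out


def undetectable_fraction(results: Sequence[TraceResult]) -> float:
    """Fraction of traced clones with zero donor templates."""
    if not results:
        raise ValueError("no trace results given")
    return sum(not r.detectable_in_donor for r in results) / len(results)


def pool_repertoires(reps: Iterable[Repertoire], meta: SampleMeta) -> Repertoire:
    """Pool samples by summing template counts per clonotype key.

    The representative CDR3/segment fields come from the highest-count
    contributing row.
    """
    reps = list(reps)
    if not reps:
        raise ValueError("cannot pool an empty collection of repertoires")
    key = reps[0].key
    for r in reps[1:]:
        if r.key != key:
            raise ValueError("all pooled repertoires must share a clonotype key mode")
    df = pd.concat([r.clones for r in reps], ignore_index=True)
    keycols = list(key.columns)
    rep_cols = [c for c in ("cdr3_nt", "cdr3_aa", "v_gene", "d_gene", "j_gene") if c not in keycols]
    df = df.sort_values("templates", ascending=False, kind="stable")
    agg = {c: "first" for c in rep_cols}
    agg["templates"] = "sum"
    pooled = df.groupby(keycols, sort=True, as_index=False).agg(agg)[list(CLONE_COLUMNS)]
    return Repertoire(meta, pooled, key=key)


def _membership_topk(
    reps: Sequence[Repertoire], top_k: int, mode: str, mouse_id: str
) -> tuple[set[tuple], dict[tuple, int]]:
    """Top-k membership key set for one mouse plus ranks for reporting."""
    if mode == "pooled":
        meta = SampleMeta(
            sample_id=f"{mouse_id}_pooled",
            mouse_id=mouse_id,
            group=reps[0].meta.group,
            tissue=reps[0].meta.tissue,
            day=reps[0].meta.day,
        )
        pooled = pool_repertoires(reps, meta)
        clones = top_clones(pooled, top_k)
        return {c.key for c in clones}, {c.key: c.rank for c in clones}
    per_sample = [{c.key: c.rank for c in top_clones(r, top_k)} for r in reps]
    if mode == "any":
        keys = set().union(*(set(d) for d in per_sample))
    elif mode == "every":
        keys = set.intersection(*(set(d) for d in per_sample))
    else:
        raise ValueError(f"unknown membership mode {mode!r}; expected pooled/any/every")
    best: dict[tuple, int] = {}
    for d in per_sample:
        for k, r in d.items():
            if k in keys and (k not in best or r < best[k]):
                best[k] = r
    return keys, best


def cross_recipient_shared(
    reps_by_mouse: Mapping[str, RepertoireSet | Sequence[Repertoire]],
    top_k: int,
    mode: str = "pooled",
) -> list[SharedClone]:
    """Clones within the top-k of every mouse in the mapping.

    Membership modes: ``pooled`` (default) ranks each mouse's tissues pooled
    into one repertoire, matching a per-mouse top-k framing; ``any`` accepts a
    clone in the top-k of at least one sample of the mouse; ``every`` demands
    the top-k of all of them.  Results are sorted by the summed per-mouse rank
    (most dominant shared clones first), then key.
    """
    if top_k < 1:
        raise ValueError("top_k must be a positive integer")
    if len(reps_by_mouse) < 2:
        raise ValueError("cross-recipient sharing requires at least two mice")
    keysets: list[set[tuple]] = []
    rank_maps: dict[str, dict[tuple, int]] = {}
    for mouse, reps in reps_by_mouse.items():
        reps = list(reps)
        keys, ranks = _membership_topk(reps, top_k, mode, mouse)
        keysets.append(keys)
        rank_maps[mouse] = ranks
    shared_keys = set.intersection(*keysets)
    aa_index = 0  # cdr3_aa is the first element for AA/AA_ONLY keys; fall back below
    out = []
    for key in shared_keys:
        ranks = {mouse: rank_maps[mouse][key] for mouse in reps_by_mouse}
        cdr3_aa = key[aa_index] if isinstance(key[aa_index], str) else ""
        out.append(SharedClone(key=key, cdr3_aa=cdr3_aa, ranks=ranks))
    out.sort(key=lambda s: (sum(s.ranks.values()), s.key))
    return out


def group_combined_top(
    reps: RepertoireSet | Sequence[Repertoire],
    n: int,
    weighting: str = "pooled",
) -> list[CombinedClone]:
    """Top ``n`` clones of a recipient group by combined frequency.

    ``pooled`` (default) sums template counts across samples and divides by
    the grand total, which is robust to unequal sequencing depths; ``mean``
    averages per-sample frequencies instead.  Each result carries the clone's
    frequency in every sample of the group.
    """
    if n < 1:
        raise ValueError("n must be a positive integer")
    if weighting not in ("pooled", "mean"):
        raise ValueError(f"unknown weighting {weighting!r}; expected pooled/mean")
    reps = list(reps)
    if not reps:
        raise ValueError("group_combined_top requires at least one repertoire")
    key = reps[0].key
    freq_by_sample = {}
    count_series = []
    for r in reps:
        if r.key != key:
            raise ValueError("all repertoires must share a clonotype key mode")
        c = r.counts()
        count_series.append(c)
        freq_by_sample[r.sample_id] = c / c.sum()
    totals = pd.concat(count_series, axis=1).fillna(0)
    pooled_counts = totals.sum(axis=1)
    if weighting == "pooled":
        combined = pooled_counts / pooled_counts.sum()
    else:
        freqs = pd.concat(freq_by_sample.values(), axis=1).fillna(0)
        combined = freqs.mean(axis=1)
    order = pd.DataFrame({"combined": combined}).sort_index().sort_values(
        "combined", ascending=False, kind="stable"
    )
    top = order.head(n)
    out = []
    for rank, (key_val, row) in enumerate(top.iterrows(), start=1):
        key_tuple = key_val if isinstance(key_val, tuple) else (key_val,)
        cdr3_aa = key_tuple[0] if isinstance(key_tuple[0], str) else ""
        out.append(
            CombinedClone(
                key=key_tuple,
                cdr3_aa=cdr3_aa,
                combined_frequency=float(row["combined"]),
                templates=int(pooled_counts.loc[key_val]),
                rank=rank,
                per_sample_frequency={
                    sid: float(f.get(key_val, 0.0)) for sid, f in freq_by_sample.items()
                },
            )
        )
    return out
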