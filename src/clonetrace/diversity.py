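"""Per-sample repertoire diversity statistics.

The statistics summarise how evenly template mass is spread across clonotypes
in one sample:

* **Shannon entropy** ``H = −Σ p_i log2 p_i`` (bits) over clone frequencies.
* **Clonality** ``1 − H / log2(N)`` for ``N`` unique clones: 0 for a perfectly
  even repertoire, 1 for a monoclonal one.  The raw evenness ratio
  ``H / log2(N)`` is exposed alongside.
* **R20** — the minimum fraction of unique clones (taken in descending
  abundance) needed to capture 20% of total template mass.  Values below 0.2
  indicate non-uniform clone frequencies; extreme values near ``1/N`` indicate
  a handful of highly dominant clones.
* **Top-N cumulative frequency** — the template-mass share of the N most
  abundant clones.

Entropy uses base-2 logarithms throughout; clonality is base-invariant.  The
single-clone repertoire has ``log2(N) = 0``, which would make clonality 0/0;
it is defined as 1 (maximal expansion).  R20 counts whole clones: the
cumulative threshold is inclusive and no fractional interpolation is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .repio import Repertoire, RepertoireSet

__all__ = [
    "DiversityStats",
    "shannon_entropy",
    "clonality",
    "evenness",
    "r20",
    "topn_cumulative_frequency",
    "diversity_stats",
    "diversity_table",
]

_FREQ_TOL = 1e-9


@dataclass(frozen=True)
class DiversityStats:
    """Diversity summary for one sample."""

    sample_id: str
    total_templates: int
    unique_clones: int
    entropy_bits: float
    max_entropy_bits: float
    evenness: float
    clonality: float
    r20: float
    topn_cumfreq: Mapping[int, float] = field(default_factory=dict)


def _validated_frequencies(frequencies: Iterable[float]) -> np.ndarray:
    p = np.asarray(list(frequencies) if not isinstance(frequencies, np.ndarray) else frequencies,
                   dtype=float)
    if p.size == 0:
        raise ValueError("empty frequency vector")
    if (p < 0).any():
        raise ValueError("frequencies must be non-negative")
    if abs(p.sum() - 1.0) > _FREQ_TOL:
        raise ValueError(f"frequencies must sum to 1 (got {p.sum()!r})")
    return p


def shannon_entropy(frequencies: Iterable[float]) -> float:
    """Shannon entropy in bits of a clone-frequency vector.

    Zero-probability entries contribute nothing and are excluded.  The vector
    must be non-negative and sum to 1 within 1e-9.
    """
    p = _validated_frequencies(frequencies)
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def clonality(rep: Repertoire) -> float:
    """``1 − H/Hmax`` with ``Hmax = log2(unique clones)``; in [0, 1].

    Returns exactly 0 for uniform counts and 1 for a single clone.
    """
    counts = rep.clones["templates"].to_numpy()
    n = counts.size
    if n == 1:
        return 1.0
    if (counts == counts[0]).all():
        return 0.0
    h = shannon_entropy(rep.frequencies)
    value = 1.0 - h / np.log2(n)
    return float(min(1.0, max(0.0, value)))


def evenness(rep: Repertoire) -> float:
    """Raw normalised entropy ``H / log2(N)`` (1 for uniform counts)."""
    n = rep.n_clones
    if n == 1:
        return 0.0
    return 1.0 - clonality(rep)


def r20(rep: Repertoire, target_fraction: float = 0.2) -> float:
    """Minimum clone fraction capturing ``target_fraction`` of template mass.

    Clones are taken in descending template order; ``k`` is the smallest
    number of clones whose cumulative frequency reaches the target
    (inclusive), and ``k / N`` is returned.
    """
    if not (0.0 < target_fraction < 1.0):
        raise ValueError("target_fraction must lie strictly between 0 and 1")
    counts = np.sort(rep.clones["templates"].to_numpy())[::-1]
    cumfreq = np.cumsum(counts) / counts.sum()
    k = int(np.argmax(cumfreq >= target_fraction - 1e-12)) + 1
    return k / counts.size


def topn_cumulative_frequency(rep: Repertoire, n: int) -> float:
    """Summed frequency of the ``n`` most abundant clones (all clones if
    ``n`` exceeds the repertoire size).  Ties at the boundary do not affect
    the sum because tied clones carry equal frequency."""
    if n < 1:
        raise ValueError("n must be a positive integer")
    counts = np.sort(rep.clones["templates"].to_numpy())[::-1]
    top = counts[: min(n, counts.size)]
    return float(top.sum() / counts.sum())


def diversity_stats(rep: Repertoire, topn: Sequence[int] = (10, 20, 30)) -> DiversityStats:
    """All diversity statistics for one sample."""
    h = shannon_entropy(rep.frequencies)
    n = rep.n_clones
    hmax = float(np.log2(n)) if n > 1 else 0.0
    return DiversityStats(
        sample_id=rep.sample_id,
        total_templates=rep.total_templates,
        unique_clones=n,
        entropy_bits=h,
        max_entropy_bits=hmax,
        evenness=evenness(rep),
        clonality=clonality(rep),
        r20=r20(rep),
        topn_cumfreq={int(k): topn_cumulative_frequency(rep, int(k)) for k in topn},
    )


def diversity_table(reps: RepertoireSet, topn_list: Sequence[int] = (10, 20, 30)) -> pd.DataFrame:
    """One row of diversity statistics per sample.

    Rows are ordered deterministically by (group, mouse, tissue, day); top-N
    cumulative frequencies appear as ``cumfreq_top{N}`` columns.
    """
    rows = []
    for rep in reps.sorted():
        s = diversity_stats(rep, topn=topn_list)
        row = {
            "sample_id": s.sample_id,
            "mouse_id": rep.meta.mouse_id,
            "group": rep.meta.group,
            "tissue": rep.meta.tissue,
            "day": rep.meta.day,
            "total_templates": s.total_templates,
            "unique_clones": s.unique_clones,
            "entropy_bits": s.entropy_bits,
            "max_entropy_bits": s.max_entropy_bits,
            "evenness": s.evenness,
            "clonality": s.clonality,
            "r20": s.r20,
        }
        for k in topn_list:
            row[f"cumfreq_top{k}"] = s.topn_cumfreq[int(k)]
        rows.append(row)
    return pd.DataFrame(rows)
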