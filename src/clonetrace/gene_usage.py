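"""V/D/J segment usage and between-group comparison.

Usage of a segment is the summed template frequency of productive clones
carrying that segment label — abundance-weighted, so an expanded clone pulls
its V family up with it.  A unique-clone weighting (each clonotype counted
once) is available for exploration.

Group comparisons run a two-tailed unpaired Student's t-test per segment;
``anova_sidak`` additionally applies the Šidák family-wise correction
``p_adj = 1 − (1 − p)^m`` across the ``m`` segments of the family (via
statsmodels).  Degenerate comparisons (both groups constant and equal) report
p = 1 with a warning rather than failing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .repio import Repertoire, RepertoireSet

__all__ = [
    "UsageComparison",
    "segment_usage",
    "usage_matrix",
    "compare_usage",
    "comparisons_to_frame",
]

_SEGMENT_COLUMNS = {"V": "v_gene", "D": "d_gene", "J": "j_gene"}


@dataclass(frozen=True)
class UsageComparison:
    """Result of one per-segment between-group test."""

    segment: str
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    statistic: float
    pvalue: float
    adjusted_pvalue: float
    direction: str  # "a>b", "a<b" or "a=b"
    significant: bool


def segment_usage(rep: Repertoire, segment: str = "V", weighting: str = "templates") -> pd.Series:
    """Per-segment usage frequencies for one sample (sums to 1).

    ``weighting='templates'`` (default) weights by template counts;
    ``'clones'`` counts each unique clonotype once.
    """
    if segment not in _SEGMENT_COLUMNS:
        raise ValueError(f"unknown segment class {segment!r}; expected one of V/D/J")
    col = _SEGMENT_COLUMNS[segment]
    if weighting == "templates":
        counts = rep.clones.groupby(col)["templates"].sum()
    elif weighting == "clones":
        counts = rep.clones.groupby(col).size()
    else:
        raise ValueError(f"unknown weighting {weighting!r}; expected templates/clones")
    usage = counts / counts.sum()
    usage.name = rep.sample_id
    return usage.sort_index()


def usage_matrix(
    reps: RepertoireSet | Sequence[Repertoire],
    segment: str = "V",
    weighting: str = "templates",
) -> pd.DataFrame:
    """Samples × segments usage-frequency matrix.

    Segments absent from a sample appear as 0; columns are sorted by segment
    label, rows follow the set's deterministic sample ordering.
    """
    reps = list(reps.sorted()) if isinstance(reps, RepertoireSet) else list(reps)
    if not reps:
        raise ValueError("usage_matrix requires at least one repertoire")
    rows = [segment_usage(r, segment=segment, weighting=weighting) for r in reps]
    mat = pd.DataFrame(rows).fillna(0.0)
    return mat[sorted(mat.columns)]


def compare_usage(
    matrix_a: pd.DataFrame,
    matrix_b: pd.DataFrame,
    method: str = "anova_sidak",
    alpha: float = 0.05,
) -> list[UsageComparison]:
    """Per-segment two-sided comparison of two group usage matrices.

    ``t_test`` reports raw p-values; ``anova_sidak`` Šidák-adjusts them
    across the segment family.  Significance is judged on the adjusted value
    at ``alpha``.  Requires at least two samples per group.
    """
    if method not in ("t_test", "anova_sidak"):
        raise ValueError(f"unknown method {method!r}; expected t_test/anova_sidak")
    if len(matrix_a) < 2 or len(matrix_b) < 2:
        raise ValueError("compare_usage requires at least two samples per group")
    segments = sorted(set(matrix_a.columns) | set(matrix_b.columns))
    a = matrix_a.reindex(columns=segments, fill_value=0.0)
    b = matrix_b.reindex(columns=segments, fill_value=0.0)

    stats_rows = []
    pvalues = []
    for seg in segments:
        xa = a[seg].to_numpy(dtype=float)
        xb = b[seg].to_numpy(dtype=float)
        if np.ptp(xa) == 0 and np.ptp(xb) == 0:
            # zero variance in both groups: the t statistic is undefined
            if xa[0] == xb[0]:
                warnings.warn(
                    f"segment {seg}: identical constant usage in both groups; p set to 1",
                    stacklevel=2,
                )
                t_stat, p = 0.0, 1.0
            else:
                t_stat, p = np.inf if xa[0] > xb[0] else -np.inf, 0.0
        else:
            t_stat, p = stats.ttest_ind(xa, xb, equal_var=True)
            t_stat, p = float(t_stat), float(p)
        diff = xa.mean() - xb.mean()
        direction = "a>b" if diff > 0 else ("a<b" if diff < 0 else "a=b")
        stats_rows.append((seg, xa, xb, t_stat, p, direction))
        pvalues.append(p)

    if method == "anova_sidak":
        _, adjusted, _, _ = multipletests(pvalues, alpha=alpha, method="sidak")
    else:
        adjusted = np.asarray(pvalues)

    out = []
    for (seg, xa, xb, t_stat, p, direction), p_adj in zip(stats_rows, adjusted):
        out.append(
            UsageComparison(
                segment=seg,
                mean_a=float(xa.mean()),
                mean_b=float(xb.mean()),
                sd_a=float(xa.std(ddof=1)),
                sd_b=float(xb.std(ddof=1)),
                statistic=t_stat,
                pvalue=p,
                adjusted_pvalue=float(p_adj),
                direction=direction,
                significant=bool(p_adj < alpha),
            )
        )
    return out


def comparisons_to_frame(comparisons: Sequence[UsageComparison]) -> pd.DataFrame:
    """Tabular view of a list of :class:`UsageComparison` results."""
    return pd.DataFrame([c.__dict__ for c in comparisons])
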