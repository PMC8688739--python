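"""Reading, writing and collapsing TCRβ clone tables.

This module holds the domain containers used by every analysis stage:
:class:`ClonotypeRecord` (one rearrangement row), :class:`Repertoire` (a
collapsed, frequency-normalised clone table for one sample) and
:class:`RepertoireSet` (a keyed collection of samples).

Two tab-separated dialects are supported:

* an ImmunoSEQ-style export with columns ``rearrangement``, ``amino_acid``,
  ``v_gene``, ``d_gene``, ``j_gene``, ``templates``, ``frame_type``;
* the AIRR Rearrangement schema with columns ``junction``, ``junction_aa``,
  ``v_call``, ``d_call``, ``j_call``, ``duplicate_count``, ``productive``.

Clonotypes can be keyed three ways (:class:`KeyMode`): CDR3 nucleotide
sequence + V + J, CDR3 amino-acid sequence + V + J, or CDR3 amino acid alone.
Sequencing platforms and IMGT use different segment names (``TCRBV26-01*01``
vs ``TRBV26``); labels are normalised to family-level tokens (``V26``,
``J2-7``) so that repertoires from either dialect are comparable. Template
counts are the abundance unit throughout; frequencies are always derived from
counts and never stored independently.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FormatError",
    "DegenerateRepertoireError",
    "KeyMode",
    "ClonotypeRecord",
    "SampleMeta",
    "Repertoire",
    "RepertoireSet",
    "GROUPS",
    "TISSUE_ORDER",
    "D_UNRESOLVED",
    "normalize_segment",
    "read_rearrangement_table",
    "write_rearrangement_table",
    "filter_productive",
    "collapse_by_key",
    "read_manifest",
    "write_manifest",
    "load_repertoire_set",
]


class FormatError(ValueError):
    """A clone table or manifest does not conform to its declared dialect."""


class DegenerateRepertoireError(ValueError):
    """A repertoire with no productive template mass was requested."""


#: Experimental groups: recipients of syngeneic or allogeneic grafts, plus the
#: pre-transplant donor T-cell sample used for clone trace-back.
GROUPS = ("syngeneic", "allogeneic", "donor_pretransplant")

#: Canonical tissue ordering used for deterministic table/matrix layouts:
#: lymphoid compartments first, then GVHD target organs, then the graft.
TISSUE_ORDER = ("blood", "spleen", "pLN", "mLN", "liver", "lung", "gut", "skin", "graft")

#: Sentinel for rearrangements whose D segment could not be assigned.  D never
#: participates in clonotype keys.
D_UNRESOLVED = "D-unresolved"


class KeyMode(str, Enum):
    """How a clonotype is identified when collapsing and comparing samples.

    ``NT``      CDR3 nucleotide + V + J (the platform's combined-rearrangement
                definition, finest resolution).
    ``AA``      CDR3 amino acid + V + J (default for cross-sample sharing;
                synonymous rearrangements converge on the same key).
    ``AA_ONLY`` CDR3 amino acid alone.
    """

    NT = "nt"
    AA = "aa"
    AA_ONLY = "aa_only"

    @property
    def columns(self) -> tuple[str, ...]:
        return _KEY_COLUMNS[self]


_KEY_COLUMNS: dict[KeyMode, tuple[str, ...]] = {
    KeyMode.NT: ("cdr3_nt", "v_gene", "j_gene"),
    KeyMode.AA: ("cdr3_aa", "v_gene", "j_gene"),
    KeyMode.AA_ONLY: ("cdr3_aa",),
}

#: Column layout of a collapsed clone table.
CLONE_COLUMNS = ("cdr3_nt", "cdr3_aa", "v_gene", "d_gene", "j_gene", "templates")


@dataclass(frozen=True)
class ClonotypeRecord:
    """One rearrangement row of a clone table.

    ``templates`` is the bias-corrected template count (proxy for input cell
    number), not a raw read count.  ``cdr3_nt`` may be empty for AA-only
    sources.
    """

    cdr3_nt: str
    cdr3_aa: str
    v_gene: str
    d_gene: str
    j_gene: str
    templates: int
    productive: bool

    def __post_init__(self) -> None:
        if self.templates < 0:
            raise ValueError(f"templates must be >= 0, got {self.templates}")
        if self.productive:
            if not self.cdr3_aa:
                raise ValueError("productive record requires a non-empty CDR3 amino-acid sequence")
            if not self.v_gene or not self.j_gene:
                raise ValueError("productive record requires non-empty V and J labels")


@dataclass(frozen=True)
class SampleMeta:
    """Identity of one sequenced sample: which mouse, group, tissue and day."""

    sample_id: str
    mouse_id: str
    group: str
    tissue: str
    day: int

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.tissue not in TISSUE_ORDER:
            raise ValueError(f"unknown tissue {self.tissue!r}; expected one of {TISSUE_ORDER}")


# ---------------------------------------------------------------------------
# Segment-label normalisation
# ---------------------------------------------------------------------------

_CANONICAL_RE = re.compile(r"^(?:TCR|TR)B?([VDJ])0*(\d+)(?:[-.]0*(\d+))?")
_ALREADY_NORMAL_RE = re.compile(r"^(?:[VD]\d+|J\d+(?:-\d+)?)$")

_default_segment_map: dict[str, str] | None = None


def _load_default_segment_map() -> dict[str, str]:
    global _default_segment_map
    if _default_segment_map is None:
        text = resources.files(__package__).joinpath("data/segment_map.yaml").read_text()
        _default_segment_map = yaml.safe_load(text) or {}
    return _default_segment_map


def normalize_segment(label: str, mapping: Mapping[str, str] | None = None) -> str:
    """Normalise a V/D/J label to a family-level token (``V26``, ``J2-7``, ``D1``).

    Resolution order: the explicit ``mapping`` (defaults to the table shipped
    in ``data/segment_map.yaml``), then an Adaptive/IMGT pattern match, then
    verbatim pass-through with a warning.  Allele suffixes (``*01``) and
    V-gene sub-family numbers are dropped; J genes keep their ``major-minor``
    form.  Empty or explicitly unresolved labels map to ``D-unresolved``.
    """
    label = (label or "").strip()
    table = _load_default_segment_map() if mapping is None else mapping
    if label in table:
        return table[label]
    if not label or label.lower() in {"unresolved", "unknown", "na", "none"}:
        return D_UNRESOLVED
    if _ALREADY_NORMAL_RE.match(label) or label == D_UNRESOLVED:
        return label
    m = _CANONICAL_RE.match(label)
    if m:
        seg, major, minor = m.group(1), int(m.group(2)), m.group(3)
        if seg == "J":
            return f"J{major}-{int(minor)}" if minor else f"J{major}"
        return f"{seg}{major}"
    warnings.warn(f"segment label {label!r} not recognised; passed through verbatim", stacklevel=2)
    return label


# ---------------------------------------------------------------------------
# Repertoire containers
# ---------------------------------------------------------------------------


class Repertoire:
    """A collapsed clone table for one sample.

    ``clones`` is a DataFrame with columns :data:`CLONE_COLUMNS`; every row is
    a distinct clonotype under ``key`` and carries at least one template.
    Frequencies are computed lazily from template counts.
    """

    def __init__(
        self,
        meta: SampleMeta,
        clones: pd.DataFrame,
        key: KeyMode = KeyMode.AA,
        validate: bool = True,
    ) -> None:
        self.meta = meta
        self.key = KeyMode(key)
        self.clones = clones.reset_index(drop=True)
        if validate:
            self._validate()

    def _validate(self) -> None:
        missing = [c for c in CLONE_COLUMNS if c not in self.clones.columns]
        if missing:
            raise ValueError(f"clone table missing columns: {missing}")
        if len(self.clones) == 0:
            raise DegenerateRepertoireError(
                f"sample {self.meta.sample_id!r} has no productive clones"
            )
        t = self.clones["templates"]
        if (t <= 0).any():
            raise ValueError("all collapsed clones must carry >= 1 template")
        if self.clones.duplicated(list(self.key.columns)).any():
            raise ValueError(f"clone table is not collapsed under key mode {self.key.value!r}")

    # -- derived views ------------------------------------------------------

    @property
    def sample_id(self) -> str:
        return self.meta.sample_id

    @property
    def n_clones(self) -> int:
        return len(self.clones)

    @property
    def total_templates(self) -> int:
        return int(self.clones["templates"].sum())

    @property
    def frequencies(self) -> np.ndarray:
        """Per-clone fraction of total templates (sums to 1)."""
        t = self.clones["templates"].to_numpy(dtype=float)
        return t / t.sum()

    def key_index(self) -> pd.MultiIndex:
        """Clonotype keys as a MultiIndex aligned with ``clones`` rows."""
        cols = self.key.columns
        return pd.MultiIndex.from_arrays(
            [self.clones[c] for c in cols], names=list(cols)
        )

    def key_set(self) -> set[tuple]:
        return set(self.key_index())

    def counts(self) -> pd.Series:
        """Template counts indexed by clonotype key."""
        return pd.Series(
            self.clones["templates"].to_numpy(), index=self.key_index(), name=self.sample_id
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        m = self.meta
        return (
            f"<Repertoire {m.sample_id} ({m.group}/{m.tissue}/d{m.day}): "
            f"{self.n_clones} clones, {self.total_templates} templates, key={self.key.value}>"
        )


def _tissue_rank(tissue: str) -> int:
    return TISSUE_ORDER.index(tissue)


class RepertoireSet:
    """An ordered collection of repertoires collapsed under one key mode."""

    def __init__(self, repertoires: Sequence[Repertoire], key: KeyMode | None = None) -> None:
        reps = list(repertoires)
        if key is None:
            if not reps:
                raise ValueError("cannot infer key mode from an empty RepertoireSet")
            key = reps[0].key
        key = KeyMode(key)
        for r in reps:
            if r.key != key:
                raise ValueError(
                    f"sample {r.sample_id!r} collapsed under {r.key.value!r}, expected {key.value!r}"
                )
        ids = [r.sample_id for r in reps]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample ids in RepertoireSet: {dupes}")
        self.key = key
        self.repertoires = reps
        self._by_id = {r.sample_id: r for r in reps}

    def __iter__(self) -> Iterator[Repertoire]:
        return iter(self.repertoires)

    def __len__(self) -> int:
        return len(self.repertoires)

    def __getitem__(self, sample_id: str) -> Repertoire:
        return self._by_id[sample_id]

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._by_id

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.repertoires]

    def sorted(self) -> "RepertoireSet":
        """Deterministic ordering by (group, mouse, tissue order, day)."""
        reps = sorted(
            self.repertoires,
            key=lambda r: (r.meta.group, r.meta.mouse_id, _tissue_rank(r.meta.tissue), r.meta.day),
        )
        return RepertoireSet(reps, key=self.key)

    def subset(
        self,
        group: str | None = None,
        mouse_id: str | None = None,
        tissue: str | None = None,
        day: int | None = None,
    ) -> "RepertoireSet":
        reps = [
            r
            for r in self.repertoires
            if (group is None or r.meta.group == group)
            and (mouse_id is None or r.meta.mouse_id == mouse_id)
            and (tissue is None or r.meta.tissue == tissue)
            and (day is None or r.meta.day == day)
        ]
        return RepertoireSet(reps, key=self.key)

    def mice(self) -> list[str]:
        return sorted({r.meta.mouse_id for r in self.repertoires})


# ---------------------------------------------------------------------------
# Table readers / writers
# ---------------------------------------------------------------------------

_IMMUNOSEQ_COLS = {
    "rearrangement": "cdr3_nt",
    "amino_acid": "cdr3_aa",
    "v_gene": "v_gene",
    "d_gene": "d_gene",
    "j_gene": "j_gene",
    "templates": "templates",
    "frame_type": "frame_type",
}
_AIRR_COLS = {
    "junction": "cdr3_nt",
    "junction_aa": "cdr3_aa",
    "v_call": "v_gene",
    "d_call": "d_gene",
    "j_call": "j_gene",
    "duplicate_count": "templates",
    "productive": "productive",
}
_DIALECTS = {"immunoseq": _IMMUNOSEQ_COLS, "airr": _AIRR_COLS}
_AIRR_TRUE = {"t", "true", "1", "yes"}


def _check_dialect(dialect: str) -> dict[str, str]:
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECTS)}")
    return _DIALECTS[dialect]


def read_rearrangement_table(
    path: str | Path,
    dialect: str = "airr",
    normalize_segments: bool = True,
    segment_map: Mapping[str, str] | None = None,
) -> list[ClonotypeRecord]:
    """Read a clone table into one :class:`ClonotypeRecord` per data row.

    Rows with zero templates are retained (they are dropped later, at
    collapse time).  The productive flag is derived from ``frame_type == In``
    (ImmunoSEQ) or the AIRR ``productive`` column.

    Raises :class:`FormatError` when a required column is missing or a count
    cannot be parsed as an integer (the error names the offending column or
    1-based data row).
    """
    colmap = _check_dialect(dialect)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in colmap if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {missing} for dialect {dialect!r}"
        )
    df = df.rename(columns=colmap)

    raw_counts = df["templates"].str.strip()
    counts = pd.to_numeric(raw_counts, errors="coerce")
    bad = counts.isna() | (counts != counts.round())
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise FormatError(
            f"{path}: non-integer template count {raw_counts.iloc[row]!r} at data row {row + 1}"
        )
    templates = counts.astype(int)

    if dialect == "immunoseq":
        productive = df["frame_type"].str.strip().str.lower().eq("in")
    else:
        productive = df["productive"].str.strip().str.lower().isin(_AIRR_TRUE)

    if normalize_segments:
        for col in ("v_gene", "d_gene", "j_gene"):
            uniq = {lab: normalize_segment(lab, segment_map) for lab in df[col].unique()}
            df[col] = df[col].map(uniq)

    return [
        ClonotypeRecord(
            cdr3_nt=nt,
            cdr3_aa=aa,
            v_gene=v,
            d_gene=d or D_UNRESOLVED,
            j_gene=j,
            templates=int(t),
            productive=bool(p),
        )
        for nt, aa, v, d, j, t, p in zip(
            df["cdr3_nt"], df["cdr3_aa"], df["v_gene"], df["d_gene"], df["j_gene"],
            templates, productive,
        )
    ]


def filter_productive(records: Iterable[ClonotypeRecord]) -> list[ClonotypeRecord]:
    """Keep only in-frame, stop-free rearrangements; order preserved."""
    return [r for r in records if r.productive]


def collapse_by_key(
    records: Sequence[ClonotypeRecord],
    key: KeyMode,
    meta: SampleMeta,
) -> Repertoire:
    """Merge records sharing a clonotype key and normalise frequencies.

    Template counts are summed within a key; the representative CDR3/segment
    fields are taken from the highest-count member (first occurrence on ties).
    Zero-template rows carry no frequency mass and are dropped.  A sample with
    no remaining templates raises :class:`DegenerateRepertoireError`.
    """
    key = KeyMode(key)
    rows = [r for r in records if r.templates > 0]
    if not rows:
        raise DegenerateRepertoireError(
            f"sample {meta.sample_id!r}: no productive templates to collapse"
        )
    df = pd.DataFrame(
        {
            "cdr3_nt": [r.cdr3_nt for r in rows],
            "cdr3_aa": [r.cdr3_aa for r in rows],
            "v_gene": [r.v_gene for r in rows],
            "d_gene": [r.d_gene for r in rows],
            "j_gene": [r.j_gene for r in rows],
            "templates": [r.templates for r in rows],
        }
    )
    keycols = list(key.columns)
    rep_cols = [c for c in ("cdr3_nt", "cdr3_aa", "v_gene", "d_gene", "j_gene") if c not in keycols]
    # highest-count member first, stable, so groupby("first") picks it
    df = df.sort_values("templates", ascending=False, kind="stable")
    agg = {c: "first" for c in rep_cols}
    agg["templates"] = "sum"
    collapsed = df.groupby(keycols, sort=True, as_index=False).agg(agg)
    collapsed = collapsed[list(CLONE_COLUMNS)]
    return Repertoire(meta, collapsed, key=key)


def write_rearrangement_table(rep: Repertoire, path: str | Path, dialect: str = "airr") -> None:
    """Write a collapsed repertoire back to delimited text.

    Round-trip guarantee: reading the written file and collapsing under the
    same key reproduces identical (key, templates) pairs.
    """
    colmap = _check_dialect(dialect)
    if len(rep.clones) == 0:  # defensive; Repertoire construction forbids this
        raise DegenerateRepertoireError("refusing to write an empty repertoire")
    out = rep.clones.copy()
    if dialect == "immunoseq":
        out["frame_type"] = "In"
    else:
        out["productive"] = "T"
    out = out.rename(columns={v: k for k, v in colmap.items() if v in out.columns})
    out[list(colmap)].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sample manifests
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ("file", "sample_id", "mouse_id", "group", "tissue", "day")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a sample manifest mapping clone-table files to sample metadata."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: manifest missing column(s) {missing}")
    df = df[list(MANIFEST_COLUMNS)].copy()
    df["day"] = df["day"].astype(int)
    return df


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest[list(MANIFEST_COLUMNS)].to_csv(path, sep="\t", index=False)


def load_repertoire_set(
    manifest_path: str | Path,
    dialect: str = "airr",
    key: KeyMode = KeyMode.AA,
    base_dir: str | Path | None = None,
    normalize_segments: bool = True,
) -> RepertoireSet:
    """Read every sample listed in a manifest, filter to productive rows and
    collapse under ``key``.  File paths are resolved relative to the manifest
    unless ``base_dir`` is given."""
    manifest_path = Path(manifest_path)
    base = Path(base_dir) if base_dir is not None else manifest_path.parent
    manifest = read_manifest(manifest_path)
    reps = []
    for row in manifest.itertuples(index=False):
        meta = SampleMeta(
            sample_id=row.sample_id,
            mouse_id=row.mouse_id,
            group=row.group,
            tissue=row.tissue,
            day=int(row.day),
        )
        records = read_rearrangement_table(
            base / row.file, dialect=dialect, normalize_segments=normalize_segments
        )
        reps.append(collapse_by_key(filter_productive(records), key, meta))
    return RepertoireSet(reps, key=KeyMode(key))
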