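"""Clone-table parsing, collapsing, normalisation and round trips."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from clonetrace.repio import (
    ClonotypeRecord,
    D_UNRESOLVED,
    DegenerateRepertoireError,
    FormatError,
    KeyMode,
    SampleMeta,
    collapse_by_key,
    filter_productive,
    load_repertoire_set,
    normalize_segment,
    read_manifest,
    read_rearrangement_table,
    write_manifest,
    write_rearrangement_table,
)

META = SampleMeta("s1", "m1", "syngeneic", "blood", 7)

AIRR_HEADER = "junction\tjunction_aa\tv_call\td_call\tj_call\tduplicate_count\tproductive\n"
IMMUNOSEQ_HEADER = "rearrangement\tamino_acid\tv_gene\td_gene\tj_gene\ttemplates\tframe_type\n"


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


def rec(aa="CASSLGF", v="V12", j="J2-7", nt="", d="D1", templates=1, productive=True):
    return ClonotypeRecord(nt, aa, v, d, j, templates, productive)


class TestReadRearrangementTable:
    def test_airr_rows_parsed(self, tmp_path):
        p = _write(
            tmp_path,
            "a.tsv",
            AIRR_HEADER
            + "TGTGCA\tCASSF\tTRBV26*01\tTRBD1\tTRBJ2-7*01\t5\tT\n"
            + "TGTGCC\tCASRF\tTRBV31\t\tTRBJ1-1\t3\tT\n",
        )
        records = read_rearrangement_table(p, dialect="airr")
        assert [r.templates for r in records] == [5, 3]
        assert records[0].v_gene == "V26" and records[0].j_gene == "J2-7"
        assert records[1].d_gene == D_UNRESOLVED
        assert all(r.productive for r in records)

    def test_immunoseq_frame_type_sets_productive(self, tmp_path):
        p = _write(
            tmp_path,
            "i.tsv",
            IMMUNOSEQ_HEADER
            + "TGTGCA\tCASSF\tTCRBV26-01*01\tTCRBD01-01\tTCRBJ02-07*01\t4\tIn\n"
            + "TGTGCC\t\tTCRBV12-01\tTCRBD02-01\tTCRBJ01-01\t2\tOut\n",
        )
        records = read_rearrangement_table(p, dialect="immunoseq")
        assert [r.productive for r in records] == [True, False]
        assert records[0].v_gene == "V26"
        assert records[0].d_gene == "D1"

    def test_header_only_file_gives_empty_list(self, tmp_path):
        p = _write(tmp_path, "e.tsv", AIRR_HEADER)
        assert read_rearrangement_table(p, dialect="airr") == []

    def test_missing_column_names_it(self, tmp_path):
        text = "junction\tjunction_aa\td_call\tj_call\tduplicate_count\tproductive\nx\tCAF\t\tJ1\t1\tT\n"
        p = _write(tmp_path, "bad.tsv", text)
        with pytest.raises(FormatError, match="v_call"):
            read_rearrangement_table(p, dialect="airr")

    def test_non_integer_count_reports_row(self, tmp_path):
        p = _write(
            tmp_path,
            "bad2.tsv",
            AIRR_HEADER + "A\tCAF\tV1\tD1\tJ1-1\t5\tT\nA\tCAF\tV1\tD1\tJ1-1\tlots\tT\n",
        )
        with pytest.raises(FormatError, match="row 2"):
            read_rearrangement_table(p, dialect="airr")

    def test_zero_template_rows_retained(self, tmp_path):
        p = _write(tmp_path, "z.tsv", AIRR_HEADER + "A\tCAF\tV1\tD1\tJ1-1\t0\tT\n")
        records = read_rearrangement_table(p, dialect="airr")
        assert len(records) == 1 and records[0].templates == 0


class TestFilterProductive:
    def test_keeps_only_productive_in_order(self):
        records = [rec(aa="A1F"), rec(aa="", v="", j="", productive=False), rec(aa="A2F")]
        kept = filter_productive(records)
        assert [r.cdr3_aa for r in kept] == ["A1F", "A2F"]

    def test_empty_and_all_nonproductive(self):
        assert filter_productive([]) == []
        assert filter_productive([rec(aa="", v="", j="", productive=False)]) == []


class TestCollapseByKey:
    def test_same_aa_key_merges_counts(self):
        records = [rec(templates=4), rec(templates=6)]
        rep = collapse_by_key(records, KeyMode.AA, META)
        assert rep.n_clones == 1
        assert rep.total_templates == 10
        assert rep.frequencies[0] == 1.0

    def test_different_j_splits_clones(self):
        records = [rec(j="J2-7"), rec(j="J1-1")]
        rep = collapse_by_key(records, KeyMode.AA, META)
        assert rep.n_clones == 2

    def test_nt_key_finer_than_aa_key(self):
        records = [rec(nt="TGTGCA", templates=2), rec(nt="TGCGCA", templates=3)]
        assert collapse_by_key(records, KeyMode.NT, META).n_clones == 2
        assert collapse_by_key(records, KeyMode.AA, META).n_clones == 1

    def test_zero_rows_dropped_and_all_zero_raises(self):
        rep = collapse_by_key([rec(templates=5), rec(aa="OTHERF", templates=0)], KeyMode.AA, META)
        assert rep.n_clones == 1
        with pytest.raises(DegenerateRepertoireError):
            collapse_by_key([rec(templates=0)], KeyMode.AA, META)

    def test_representative_fields_from_highest_count_member(self):
        records = [rec(nt="AAA", templates=2), rec(nt="CCC", templates=9)]
        rep = collapse_by_key(records, KeyMode.AA, META)
        assert rep.clones["cdr3_nt"].iloc[0] == "CCC"

    def test_idempotent(self):
        records = [rec(aa="A1F", templates=4), rec(aa="A1F", templates=6), rec(aa="A2F", templates=1)]
        rep1 = collapse_by_key(records, KeyMode.AA, META)
        again = [
            ClonotypeRecord(*row, productive=True)
            for row in rep1.clones[["cdr3_nt", "cdr3_aa", "v_gene", "d_gene", "j_gene", "templates"]]
            .itertuples(index=False)
        ]
        rep2 = collapse_by_key(again, KeyMode.AA, META)
        pd.testing.assert_frame_equal(rep1.clones, rep2.clones)


@given(
    st.lists(
        st.tuples(
            st.sampled_from(["CAAF", "CABF", "CACF", "CADF"]),
            st.sampled_from(["V1", "V2"]),
            st.sampled_from(["J1-1", "J2-7"]),
            st.integers(min_value=0, max_value=50),
        ),
        min_size=1,
        max_size=30,
    ).filter(lambda rows: sum(r[3] for r in rows) > 0)
)
def test_collapse_properties(rows):
    """Frequencies sum to 1; NT key never coarser than AA key; counts conserved."""
    records = [
        ClonotypeRecord(cdr3_nt=f"NT{i}", cdr3_aa=aa, v_gene=v, d_gene="D1", j_gene=j,
                        templates=t, productive=True)
        for i, (aa, v, j, t) in enumerate(rows)
    ]
    aa_rep = collapse_by_key(records, KeyMode.AA, META)
    nt_rep = collapse_by_key(records, KeyMode.NT, META)
    assert abs(aa_rep.frequencies.sum() - 1.0) < 1e-9
    assert nt_rep.n_clones >= aa_rep.n_clones
    assert nt_rep.total_templates == aa_rep.total_templates == sum(r[3] for r in rows)


class TestRoundTrip:
    @pytest.mark.parametrize("dialect", ["airr", "immunoseq"])
    def test_write_read_collapse_identity(self, tmp_path, dialect, make_rep):
        rep = make_rep([50, 30, 20], v_gene=["V12", "V26", "V31"])
        path = tmp_path / f"rt.{dialect}.tsv"
        write_rearrangement_table(rep, path, dialect=dialect)
        back = collapse_by_key(
            filter_productive(read_rearrangement_table(path, dialect=dialect)),
            KeyMode.AA,
            rep.meta,
        )
        assert back.key_set() == rep.key_set()
        pd.testing.assert_series_equal(
            back.counts().sort_index(), rep.counts().sort_index(), check_names=False
        )

    def test_airr_output_columns(self, tmp_path, make_rep):
        path = tmp_path / "cols.tsv"
        write_rearrangement_table(make_rep([3]), path, dialect="airr")
        header = path.read_text().splitlines()[0].split("\t")
        assert "junction_aa" in header and "duplicate_count" in header


class TestNormalizeSegment:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("TCRBV26-01*01", "V26"),
            ("TRBV26", "V26"),
            ("TCRBJ02-07*01", "J2-7"),
            ("TRBJ1-1", "J1-1"),
            ("TCRBD01-01", "D1"),
            ("V26", "V26"),
            ("", D_UNRESOLVED),
            ("unresolved", D_UNRESOLVED),
            ("TCRBDX", D_UNRESOLVED),
        ],
    )
    def test_known_forms(self, raw, expected):
        assert normalize_segment(raw) == expected

    def test_unknown_label_passes_through_with_warning(self):
        with pytest.warns(UserWarning, match="weird"):
            assert normalize_segment("weird-label") == "weird-label"


class TestManifest:
    def test_manifest_round_trip_and_loading(self, tmp_path, make_rep):
        rep1 = make_rep([5, 3], sample_id="s1", tissue="blood")
        rep2 = make_rep([7, 2], sample_id="s2", tissue="gut")
        write_rearrangement_table(rep1, tmp_path / "s1.tsv")
        write_rearrangement_table(rep2, tmp_path / "s2.tsv")
        manifest = pd.DataFrame(
            {
                "file": ["s1.tsv", "s2.tsv"],
                "sample_id": ["s1", "s2"],
                "mouse_id": ["m1", "m1"],
                "group": ["syngeneic", "syngeneic"],
                "tissue": ["blood", "gut"],
                "day": [7, 7],
            }
        )
        write_manifest(manifest, tmp_path / "manifest.tsv")
        loaded = read_manifest(tmp_path / "manifest.tsv")
        assert list(loaded["sample_id"]) == ["s1", "s2"]
        reps = load_repertoire_set(tmp_path / "manifest.tsv")
        assert reps["s1"].total_templates == 8
        assert reps["s2"].meta.tissue == "gut"

    def test_manifest_missing_column(self, tmp_path):
        (tmp_path / "m.tsv").write_text("file\tsample_id\n a\tb\n")
        with pytest.raises(FormatError, match="mouse_id"):
            read_manifest(tmp_path / "m.tsv")
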