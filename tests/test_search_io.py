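"""Parsers for BLAST tabular, HHR, the DALI dialect, domtblout, coordinates."""

import io
import textwrap

import pytest

from ecod.ranges import SegmentSet
from ecod.search_io import (
    Hit,
    SearchIOError,
    parse_blast_tabular,
    parse_dali_rows,
    parse_hhr,
    parse_hmmer_domtblout,
    read_ca_coordinates,
    read_fasta,
    write_blast_tabular,
    write_dali_rows,
    write_hhr,
    write_hmmer_domtblout,
)


class TestBlastTabular:
    ROW = "q1\te00001\t95.00\t100\t0\t0\t1\t100\t1\t100\t1e-05\t200.0\n"

    def test_single_row(self):
        hits = parse_blast_tabular(self.ROW, method="domain_blast")
        assert len(hits) == 1
        hit = hits[0]
        assert hit.query_range == SegmentSet.single("q1", 1, 100)
        assert hit.evalue == 1e-5
        assert hit.target_id == "e00001"
        assert hit.method == "domain_blast"

    def test_comment_only_fmt7_stream_is_empty(self):
        text = "# BLASTP 2.12.0+\n# Query: q1\n# 0 hits found\n"
        assert parse_blast_tabular(text) == []

    def test_non_numeric_evalue_rejected_naming_line(self):
        bad = self.ROW.replace("1e-05", "abc")
        with pytest.raises(SearchIOError, match="line 1"):
            parse_blast_tabular(bad)

    def test_chain_context_sets_target_kind(self):
        hit = parse_blast_tabular(self.ROW, method="chain_blast")[0]
        assert hit.target_kind == "chain"


class TestHHR:
    def _render(self, hits, qseq, tseqs):
        buf = io.StringIO()
        write_hhr(buf, "q1", qseq, hits, tseqs)
        return buf.getvalue()

    def test_probability_and_evalue_recovered(self):
        # the kind of values HHsearch prints for a confident remote hit
        qseq = "MKVLITGAGSGIGLE"
        tseq = "MKVLITGAGSGIGLE"
        hit = Hit(
            query_id="q1",
            query_range=SegmentSet.single("q1", 1, 15),
            target_id="e00042",
            target_kind="profile",
            method="hhsearch",
            probability=97.89,
            evalue=9.4e-09,
            identity=17.0,
            aligned_pairs=tuple((i + 1, i + 1) for i in range(15)),
        )
        parsed = parse_hhr(self._render([hit], qseq, {"e00042": tseq}))
        assert len(parsed) == 1
        assert parsed[0].probability == 97.89
        assert parsed[0].evalue == 9.4e-09
        assert parsed[0].aligned_pairs == hit.aligned_pairs

    def test_header_with_zero_hits(self):
        assert parse_hhr("Query         q1\nMatch_columns 10\n\n") == []

    def test_two_segment_alignment_concatenates_increasing_pairs(self):
        # pairs with a gap in the middle on both sides
        pairs = tuple((i, i + 2) for i in range(1, 11)) + tuple(
            (i, i + 6) for i in range(15, 25)
        )
        qseq = "A" * 30
        tseq = "G" * 40
        hit = Hit(
            query_id="q1",
            query_range=SegmentSet.from_positions(("q1", q) for q, _ in pairs),
            target_id="t1",
            target_kind="profile",
            method="hhsearch",
            probability=95.0,
            evalue=1e-10,
            aligned_pairs=pairs,
        )
        parsed = parse_hhr(self._render([hit], qseq, {"t1": tseq}))
        assert parsed[0].aligned_pairs == pairs

    def test_truncated_alignment_block_is_an_error(self):
        text = (
            "Query         q1\n\nNo 1\n>t1\n"
            "Probab=95.00  E-value=1e-10\n\n"
            "Q q1             1 AAAA    4 (10)\n"
        )
        with pytest.raises(SearchIOError, match="truncated"):
            parse_hhr(text)


class TestDali:
    HEADER = "query_id\ttarget_id\tz_score\trmsd\tnalign\tpairs\n"

    def test_z_score_parsed(self):
        # a borderline structure hit like the reciprocal barrel-domain case
        row = "q1\te2f9h\t6.0\t2.30\t3\t1:1,2:2,3:3\n"
        hits = parse_dali_rows(self.HEADER + row)
        assert hits[0].z_score == 6.0
        assert hits[0].method == "dali"
        assert hits[0].target_kind == "structure"

    def test_empty_stream(self):
        assert parse_dali_rows("") == []
        assert parse_dali_rows(self.HEADER) == []

    def test_decreasing_pair_list_rejected(self):
        row = "q1\tt1\t9.0\t2.30\t3\t1:5,2:4,3:3\n"
        with pytest.raises(SearchIOError, match="increasing"):
            parse_dali_rows(self.HEADER + row)

    def test_missing_z_score_rejected(self):
        row = "q1\tt1\t\t2.30\t2\t1:1,2:2\n"
        with pytest.raises(SearchIOError, match="z_score"):
            parse_dali_rows(self.HEADER + row)


class TestDomtblout:
    def _row(self, ievalue="1e-20", env="5 120"):
        e_from, e_to = env.split()
        return (
            f"PF00001.1 PF00001 120 q1 - 200 1e-25 80.0 0.1 1 1 1e-22 {ievalue} "
            f"79.0 0.1 1 116 4 119 {e_from} {e_to} 0.98 some description\n"
        )

    def test_envelope_and_ievalue(self):
        hits = parse_hmmer_domtblout(self._row())
        assert hits[0].query_range == SegmentSet.single("q1", 5, 120)
        assert hits[0].evalue == 1e-20
        assert hits[0].target_id == "PF00001"
        assert hits[0].method == "hmmer"

    def test_comment_only_stream(self):
        assert parse_hmmer_domtblout("# comment\n#\n") == []

    def test_reversed_envelope_rejected(self):
        with pytest.raises(SearchIOError, match="envelope"):
            parse_hmmer_domtblout(self._row(env="120 5"))

    def test_column_count_mismatch_rejected(self):
        with pytest.raises(SearchIOError, match="columns"):
            parse_hmmer_domtblout("PF00001 PF00001 120 q1 -\n")


PDB_3RES = textwrap.dedent(
    """\
    ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
    ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
    ATOM      3  CA  GLY A   2       8.121   4.973  -4.834  1.00  0.00           C
    ATOM      4  CA  SER A   3       5.220   5.872  -6.982  1.00  0.00           C
    END
    """
)

PDB_ALTLOC = textwrap.dedent(
    """\
    ATOM      1  CA AALA A   1      11.639   6.071  -5.147  0.50  0.00           C
    ATOM      2  CA BALA A   1      11.700   6.100  -5.200  0.50  0.00           C
    ATOM      3  CA  GLY A   2       8.121   4.973  -4.834  1.00  0.00           C
    END
    """
)

PDB_LIGAND_ONLY = textwrap.dedent(
    """\
    HETATM    1  CA   CA A 201      10.000  10.000  10.000  1.00  0.00          CA
    END
    """
)


class TestCoordinates:
    def test_three_residue_pdb(self, tmp_path):
        path = tmp_path / "toy.pdb"
        path.write_text(PDB_3RES)
        coords = read_ca_coordinates(path)
        assert len(coords) == 3

    def test_altloc_residue_counted_once(self, tmp_path):
        path = tmp_path / "altloc.pdb"
        path.write_text(PDB_ALTLOC)
        coords = read_ca_coordinates(path)
        assert len(coords) == 2

    def test_ligand_only_file_rejected(self, tmp_path):
        path = tmp_path / "ligand.pdb"
        path.write_text(PDB_LIGAND_ONLY)
        with pytest.raises(SearchIOError, match="no CA"):
            read_ca_coordinates(path)


def test_fasta_round_trip():
    from ecod.search_io import write_fasta

    seqs = {"q1": "MKV" * 30, "q2": "ACDEFGH"}
    buf = io.StringIO()
    write_fasta(seqs, buf)
    assert read_fasta(buf.getvalue()) == seqs


class TestHitInvariants:
    def test_hit_without_any_score_rejected(self):
        with pytest.raises(SearchIOError, match="no score"):
            Hit(
                query_id="q",
                query_range=SegmentSet.single("q", 1, 10),
                target_id="t",
                target_kind="domain",
                method="domain_blast",
            )

    def test_non_monotone_pairs_rejected(self):
        with pytest.raises(SearchIOError, match="increasing"):
            Hit(
                query_id="q",
                query_range=SegmentSet.single("q", 1, 10),
                target_id="t",
                target_kind="domain",
                method="domain_blast",
                evalue=1e-5,
                aligned_pairs=((1, 1), (2, 2), (2, 3)),
            )


class TestRoundTrips:
    """write -> parse -> write is bit-exact for the internal dialects."""

    def _hits(self):
        return [
            Hit(
                query_id="q1",
                query_range=SegmentSet.single("q1", 1, 50),
                target_id="e00001",
                target_kind="domain",
                method="domain_blast",
                evalue=3.1e-12,
                identity=87.25,
                aligned_pairs=tuple((i, i) for i in range(1, 51)),
            ),
            Hit(
                query_id="q1",
                query_range=SegmentSet.single("q1", 60, 99),
                target_id="e00002",
                target_kind="domain",
                method="domain_blast",
                evalue=4.5e-04,
                identity=55.00,
                aligned_pairs=tuple((i + 59, i) for i in range(1, 41)),
            ),
        ]

    def _round_trip(self, writer, parser, hits, **kwargs):
        buf1 = io.StringIO()
        writer(hits, buf1)
        parsed = parser(buf1.getvalue())
        buf2 = io.StringIO()
        writer(parsed, buf2)
        assert buf1.getvalue() == buf2.getvalue()
        return parsed

    def test_blast_tabular(self):
        self._round_trip(write_blast_tabular, parse_blast_tabular, self._hits())

    def test_dali(self):
        hits = [
            Hit(
                query_id="q1",
                query_range=SegmentSet.single("q1", 1, 30),
                target_id="e00001",
                target_kind="structure",
                method="dali",
                z_score=12.3,
                aligned_pairs=tuple((i, i) for i in range(1, 31)),
            )
        ]
        self._round_trip(write_dali_rows, parse_dali_rows, hits)

    def test_domtblout(self):
        hits = [
            Hit(
                query_id="q1",
                query_range=SegmentSet.single("q1", 5, 120),
                target_id="PF00001",
                target_kind="profile",
                method="hmmer",
                evalue=1e-20,
            )
        ]
        self._round_trip(write_hmmer_domtblout, parse_hmmer_domtblout, hits)

    def test_hhr(self):
        qseq = "ACDEFGHIKLMNPQRSTVWY" * 3
        tseq = "ACDEFGHIKLMNPQRSTVWY" * 3
        hits = [
            Hit(
                query_id="q1",
                query_range=SegmentSet.single("q1", 1, 40),
                target_id="e00009",
                target_kind="profile",
                method="hhsearch",
                probability=93.47,
                evalue=2.5e-08,
                identity=64.0,
                aligned_pairs=tuple((i, i + 3) for i in range(1, 41)),
            )
        ]
        buf1 = io.StringIO()
        write_hhr(buf1, "q1", qseq, hits, {"e00009": tseq})
        parsed = parse_hhr(buf1.getvalue())
        buf2 = io.StringIO()
        write_hhr(buf2, "q1", qseq, parsed, {"e00009": tseq})
        assert buf1.getvalue() == buf2.getvalue()

    def test_parsed_hits_keep_monotone_pairs(self):
        for hit in self._hits():
            pairs = hit.aligned_pairs
            assert all(
                q2 > q1 and t2 > t1
                for (q1, t1), (q2, t2) in zip(pairs, pairs[1:])
            )
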