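"""FASTA, imported-topology and results I/O."""

import pytest
from hypothesis import given, settings, strategies as st

from sectat import seqio
from sectat.dgscale import SegmentScore
from sectat.errors import AlphabetError, FastaError, TopologyFormatError
from sectat.tatmotif import RRMotif


class TestFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "one.fasta"
        p.write_text(">p1\nMKR\n")
        recs = seqio.read_fasta(p)
        assert len(recs) == 1
        assert recs[0].id == "p1"
        assert recs[0].seq == "MKR"

    def test_wrapped_lowercase_and_stop(self, tmp_path):
        p = tmp_path / "w.fasta"
        p.write_text(">p1 some description\nmkrl\nlivf\na*\n")
        rec = seqio.read_fasta(p)[0]
        assert rec.seq == "MKRLLIVFA"
        assert rec.description == "some description"

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "dup.fasta"
        p.write_text(">a\nMK\n>a\nMR\n")
        with pytest.raises(FastaError, match="duplicate.*a"):
            seqio.read_fasta(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(FastaError, match="no FASTA records"):
            seqio.read_fasta(p)

    def test_illegal_residue_named_with_position(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">p1\nMKB\n")
        with pytest.raises(AlphabetError, match="p1.*'B' at position 3"):
            seqio.read_fasta(p)

    def test_x_allowed_u_mapped(self):
        rec = seqio.ProteinRecord("p", "MXU")
        assert rec.seq == "MXC"
        assert rec.has_x

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        entries=st.lists(
            st.tuples(
                st.integers(0, 10**6),
                st.text(alphabet="ACDEFGHIKLMNPQRSTVWYX", min_size=1, max_size=80),
            ),
            min_size=1,
            max_size=6,
            unique_by=lambda t: t[0],
        )
    )
    def test_roundtrip_identity(self, entries, tmp_path_factory):
        """FASTA read -> write -> read is the identity on (id, seq)."""
        records = [seqio.ProteinRecord(f"rec{i}", seq) for i, seq in entries]
        path = tmp_path_factory.mktemp("fa") / "rt.fasta"
        seqio.write_fasta(records, path)
        back = seqio.read_fasta(path)
        assert [(r.id, r.seq) for r in back] == [(r.id, r.seq) for r in records]


class TestTmhmmShort:
    def test_one_helix(self, tmp_path):
        p = tmp_path / "t.tmhmm"
        p.write_text("p1\tlen=200\tPredHel=1\tTopology=i10-32o\n")
        (imp,) = seqio.read_tmhmm_short(p)
        assert imp.segments == ((10, 32),)
        assert imp.orientation_of_first_loop == "inside"
        assert imp.n_in_probability is None

    def test_zero_helices(self, tmp_path):
        p = tmp_path / "t.tmhmm"
        p.write_text("p1 len=200 PredHel=0 Topology=o\n")
        (imp,) = seqio.read_tmhmm_short(p)
        assert imp.segments == ()
        assert imp.orientation_of_first_loop == "outside"

    def test_two_helices_alternating_loops(self, tmp_path):
        # hand-decoded: helices 10-32 and 40-62, loops i/o/i
        p = tmp_path / "t.tmhmm"
        p.write_text("p1 len=200 PredHel=2 Topology=i10-32o40-62i\n")
        (imp,) = seqio.read_tmhmm_short(p)
        assert imp.segments == ((10, 32), (40, 62))
        assert imp.orientation_of_first_loop == "inside"

    def test_probnin_token(self, tmp_path):
        p = tmp_path / "t.tmhmm"
        p.write_text("p1 len=99 PredHel=1 Topology=i10-32o ProbNin=0.950\n")
        assert seqio.read_tmhmm_short(p)[0].n_in_probability == 0.95

    @pytest.mark.parametrize(
        "line",
        [
            "p1 len=200 PredHel=2 Topology=i10-32o",  # count mismatch
            "p1 len=200 PredHel=1 Topology=x10-32o",  # bad leading char
            "p1 len=200 PredHel=1 Topology=i32-10o",  # inverted span
            "p1 len=200 PredHel=2 Topology=i10-32o30-62i",  # overlap
            "p1 len=200 PredHel=1",  # no topology field
        ],
    )
    def test_malformed_lines_name_the_line(self, tmp_path, line):
        p = tmp_path / "bad.tmhmm"
        p.write_text(line + "\n")
        with pytest.raises(TopologyFormatError, match=":1"):
            seqio.read_tmhmm_short(p)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(data=st.data())
    def test_decode_inverts_encode(self, data, tmp_path_factory):
        """Decoding is the inverse of a synthetic encoder over random valid
        topologies."""
        n = data.draw(st.integers(0, 6))
        first = data.draw(st.sampled_from(["inside", "outside"]))
        segments = []
        pos = 1
        for _ in range(n):
            start = pos + data.draw(st.integers(1, 30))
            end = start + data.draw(st.integers(0, 30))
            segments.append((start, end))
            pos = end
        prob = data.draw(st.one_of(st.none(), st.floats(0, 1, width=16)))
        line = seqio.format_tmhmm_short("px", pos + 10, segments, first, prob)
        path = tmp_path_factory.mktemp("t") / "x.tmhmm"
        path.write_text(line + "\n")
        (imp,) = seqio.read_tmhmm_short(path)
        assert imp.segments == tuple(segments)
        assert imp.orientation_of_first_loop == first
        if prob is None:
            assert imp.n_in_probability is None
        else:
            assert imp.n_in_probability == pytest.approx(prob, abs=5e-4)


class TestTopologyStrings:
    def test_decode(self, tmp_path):
        p = tmp_path / "t.topo"
        p.write_text("p1\tiiMMMooMMMMii\n")
        (imp,) = seqio.read_topology_strings(p)
        assert imp.segments == ((3, 5), (8, 11))
        assert imp.orientation_of_first_loop == "inside"

    def test_non_alternating_rejected(self, tmp_path):
        p = tmp_path / "t.topo"
        p.write_text("p1\tiiMMMiiMMMii\n")
        with pytest.raises(TopologyFormatError, match="alternate"):
            seqio.read_topology_strings(p)


class TestResults:
    def test_empty_rows_header_only(self, tmp_path):
        out = tmp_path / "r.tsv"
        seqio.write_results([], out, format="tsv")
        df = seqio.read_results_tsv(out)
        assert list(df.columns) == seqio.RESULT_COLUMNS
        assert len(df) == 0

    def test_tsv_roundtrip(self, tmp_path):
        out = tmp_path / "r.tsv"
        row = {"id": "p1", "class": "N-in-even", "n_before": 2, "rr_pos": 161}
        seqio.write_results([row], out, format="tsv", header_lines=["max_gap=30"])
        df = seqio.read_results_tsv(out)
        assert len(df) == 1
        assert df.loc[0, "id"] == "p1"
        assert df.loc[0, "class"] == "N-in-even"
        assert df.loc[0, "n_before"] == 2
        assert "# max_gap=30" in out.read_text()

    def test_gff3_feature_counts(self, tmp_path):
        # 3 TMDs + 1 RR motif -> 3 helix lines + 1 motif line
        segs = [SegmentScore(10, 30, -2.0), SegmentScore(40, 60, -1.0),
                SegmentScore(90, 110, 0.5)]
        motifs = [RRMotif(pos=70, context="SRRGFLK", consensus_score=4)]
        out = tmp_path / "r.gff3"
        seqio.write_results(
            [{"id": "p1", "segments": segs, "motifs": motifs}], out, format="gff3"
        )
        lines = [l for l in out.read_text().splitlines() if not l.startswith("#")]
        assert sum("transmembrane_helix" in l for l in lines) == 3
        assert sum("sequence_motif" in l for l in lines) == 1
        helix1 = next(l for l in lines if "tmd1" in l).split("\t")
        assert (helix1[3], helix1[4]) == ("10", "30")
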