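"""ΔG_app scoring, window scanning and what-if substitutions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sectat import dgscale
from sectat.dgscale import scan_segments, segment_dg, variant_dg
from sectat.errors import SpanError
from sectat.seqio import ProteinRecord
from sectat.synth import SyntheticSpec, make_protein

AA = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_scan(seq, scale, threshold=0.0, all_minima=False):
    """Independent oracle: enumerate every (start, length) window, score it
    by direct summation, then pick non-overlapping windows by ascending
    (ΔG, start, length)."""
    wins = []
    for s in range(1, len(seq) + 1):
        for L in range(scale.l_min, scale.l_max + 1):
            e = s + L - 1
            if e > len(seq):
                continue
            dg = sum(scale.contribution(seq[s - 1 + i], i, L) for i in range(L))
            if all_minima or dg <= threshold:
                wins.append((dg, s, L))
    chosen = []
    for dg, s, L in sorted(wins):
        e = s + L - 1
        if all(e < cs or s > ce for _, cs, ce in chosen):
            chosen.append((dg, s, e))
    return sorted((s, e, dg) for dg, s, e in chosen)


def random_protein(rng, n, hydrophobic_bias=0.35):
    """Random sequence with enough hydrophobic mass for windows to pass."""
    greasy = "LIVFMA"
    out = []
    for _ in range(n):
        pool = greasy if rng.random() < hydrophobic_bias else AA
        out.append(pool[rng.integers(len(pool))])
    return ProteinRecord("rand", "".join(out))


class TestSegmentDg:
    def test_polyleucine_hand_sum(self, uniform_scale):
        """21-mer poly-L with uniform weights is exactly 21 x dg0(L)."""
        rec = ProteinRecord("p", "L" * 21)
        expected = 21 * uniform_scale.dg0("L")
        assert segment_dg(rec, 1, 21, uniform_scale).dg_app == pytest.approx(expected)

    def test_length_correction_zero_at_reference(self, scale):
        rec = ProteinRecord("p", "L" * 40)
        ref = scale.length_ref
        with_corr = segment_dg(rec, 1, ref, scale, length_correction=True)
        without = segment_dg(rec, 1, ref, scale, length_correction=False)
        assert with_corr.dg_app == without.dg_app
        longer = segment_dg(rec, 1, ref + 2, scale, length_correction=True)
        longer_no = segment_dg(rec, 1, ref + 2, scale, length_correction=False)
        assert longer.dg_app > longer_no.dg_app

    def test_translation_invariance(self, scale):
        """dg depends only on the span's residue string, not its position."""
        core = "LIVFWMALGSTVIML"
        rec = ProteinRecord("p", "GGGG" + core + "KKKKKKK" + core + "DD")
        a = segment_dg(rec, 5, 4 + len(core), scale).dg_app
        b = segment_dg(rec, 12 + len(core), 11 + 2 * len(core), scale).dg_app
        assert a == pytest.approx(b)

    @pytest.mark.parametrize("start,end", [(5, 3), (0, 10), (1, 100)])
    def test_bad_spans_rejected(self, scale, start, end):
        rec = ProteinRecord("p", "L" * 30)
        with pytest.raises(SpanError):
            segment_dg(rec, start, end, scale)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(data=st.data())
    def test_local_substitution_is_exact_under_uniform_weights(
        self, data, uniform_scale
    ):
        """With flat weights, r -> r' at any in-span position changes dg_app
        by exactly dg0(r') - dg0(r)."""
        seq = data.draw(st.text(alphabet=AA, min_size=5, max_size=40))
        rec = ProteinRecord("p", seq)
        pos = data.draw(st.integers(1, len(seq)))
        new = data.draw(st.sampled_from(AA))
        before = segment_dg(rec, 1, len(seq), uniform_scale).dg_app
        vs = variant_dg(rec, [(pos, new)], 1, len(seq), uniform_scale)
        expected = uniform_scale.dg0(new) - uniform_scale.dg0(seq[pos - 1])
        assert vs.dg_variant - before == pytest.approx(expected)

    def test_appending_unfavourable_residue_raises_dg(self, uniform_scale):
        rec = ProteinRecord("p", "LIVFMALIVFMALIVFMALK")
        short = segment_dg(rec, 1, 19, uniform_scale).dg_app
        longer = segment_dg(rec, 1, 20, uniform_scale).dg_app
        assert longer == pytest.approx(short + uniform_scale.dg0("K"))
        assert longer > short


class TestScan:
    def test_polyglycine_yields_nothing(self, scale):
        rec = ProteinRecord("p", "G" * 100)
        assert scan_segments(rec, scale) == []

    def test_short_sequence_warns_and_is_empty(self, scale):
        rec = ProteinRecord("p", "LIVFM")
        with pytest.warns(UserWarning, match="shorter than minimum helix"):
            assert scan_segments(rec, scale) == []

    def test_three_strong_tmds_recovered(self, scale):
        """A 3-TMD fixture at ΔG -2.0 per TMD gives exactly 3 segments, each
        overlapping its ground-truth span by >= 90%."""
        spec = SyntheticSpec(
            seed=11, n_tmd=3, tmd_target_dg=(-2.0, -2.0, -2.0), name="scan3"
        )
        rec, truth = make_protein(spec, scale)
        segs = scan_segments(rec, scale)
        assert len(segs) == 3
        for (ts, te), seg in zip(truth.segments, segs):
            shared = min(te, seg.end) - max(ts, seg.start) + 1
            assert shared >= 0.9 * (te - ts + 1)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_enumeration(self, scale, seed):
        """Greedy window selection equals the brute-force oracle on random
        sequences up to 200 aa."""
        rng = np.random.default_rng(seed)
        rec = random_protein(rng, int(rng.integers(19, 201)))
        got = [(s.start, s.end, s.dg_app) for s in scan_segments(rec, scale)]
        expected = brute_force_scan(rec.seq, scale)
        assert [(s, e) for s, e, _ in got] == [(s, e) for s, e, _ in expected]
        for (_, _, a), (_, _, b) in zip(got, expected):
            assert a == pytest.approx(b)

    def test_all_minima_includes_subthreshold_windows(self, scale):
        rec = ProteinRecord("p", "S" * 30 + "L" * 8 + "S" * 10 + "L" * 8 + "S" * 30)
        assert scan_segments(rec, scale) == []
        everything = scan_segments(rec, scale, all_minima=True)
        assert everything  # weakly hydrophobic windows are still rankable
        assert all(e.dg_app > 0 for e in everything)


class TestVariants:
    def test_self_substitution_is_neutral(self, scale):
        rec = ProteinRecord("p", "LIVFMALIVFMALIVFMALIV")
        vs = variant_dg(rec, [(5, "M")], 1, 21, scale)  # M -> M
        assert vs.delta == 0.0

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(data=st.data())
    def test_center_best_residue_never_unfavourable(self, data, scale):
        """Substituting the exact centre of an odd-length span (where every
        residue contributes its dg0) with the scale's most favourable
        residue can only lower dg_app."""
        best = min(AA, key=scale.dg0)
        half = data.draw(st.integers(4, 20))
        seq = data.draw(st.text(alphabet=AA, min_size=2 * half + 1,
                                max_size=2 * half + 1))
        rec = ProteinRecord("p", seq)
        center = half + 1
        vs = variant_dg(rec, [(center, best)], 1, len(seq), scale)
        assert vs.delta >= -1e-12

    def test_rescanned_span_reported(self, scale):
        rec = ProteinRecord("p", "S" * 10 + "L" * 21 + "S" * 10)
        vs = variant_dg(rec, [(11, "L")], 11, 31, scale)
        assert vs.rescanned_span[0] >= 1
        assert vs.dg_variant_rescanned <= vs.dg_variant + 1e-12

    def test_invalid_substitutions_rejected(self, scale):
        rec = ProteinRecord("p", "L" * 25)
        with pytest.raises(SpanError):
            variant_dg(rec, [(40, "A")], 1, 21, scale)
        with pytest.raises(Exception):
            variant_dg(rec, [(5, "B")], 1, 21, scale)

    def test_parse_substitution(self):
        assert dgscale.parse_substitution("S179L") == (179, "S", "L")
        with pytest.raises(SpanError):
            dgscale.parse_substitution("S17")
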