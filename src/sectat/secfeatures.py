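"""Sec-release feature rubric for dual-targeting candidates.

Three sequence features conspire to make the Sec translocon abort insertion
of the final, Tat-dependent TMD and release it to the cytoplasmic side:

* the final TMD is only weakly hydrophobic (positive ΔG_app), in contrast to
  the strongly hydrophobic first TMD;
* basic residues (K/R) crowd the C-terminal flank of the final TMD — a
  "Sec-avoidance" arrangement that opposes translocation of that flank;
* the cytoplasmic loop upstream of the twin-arginine motif must leave the
  motif enough room (about eight residues) to be recognized by Tat.

:func:`report` assembles these into a feature vector with flags; the loop
length and first-vs-last ΔG comparison are reported raw (the literature
states no hard cutoffs for them).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from sectat.dgscale import (
    HydrophobicityScale,
    SegmentScore,
    VariantScore,
    segment_dg,
    variant_dg,
)
from sectat.dualscreen import DualCandidate
from sectat.errors import SectatError, SpanError
from sectat.seqio import ProteinRecord
from sectat.topology import POSITIVE_RESIDUES, TopologyModel

DEFAULT_MIN_LOOP = 8
DEFAULT_CTERM_WINDOW = 20


@dataclass(frozen=True)
class SecReleaseReport:
    """Feature vector for one candidate.

    ``dg_gap = final_tmd_dg - first_tmd_dg`` (how much less hydrophobic the
    Tat-dependent helix is than the first); ``flags`` is a subset of
    ``{"weak_final_tmd", "sec_avoidance", "short_loop"}``.
    """

    protein_id: str
    final_tmd_dg: float
    first_tmd_dg: float
    dg_gap: float
    loop_len: int
    cterm_basic_count: int
    cterm_window: tuple[int, int]
    flags: frozenset[str]


def loop_length(candidate: DualCandidate, topology: TopologyModel) -> int:
    """Residues between the end of the last TMD upstream of the motif and
    the twin-arginine pair: ``rr.pos - tmd.end - 1``."""
    if candidate.rr is None:
        raise SectatError(f"{candidate.protein_id}: candidate has no RR motif")
    pos = candidate.rr.pos
    upstream = [s for s in topology.segments if s.end < pos]
    if not upstream:
        raise SectatError(
            f"{candidate.protein_id}: no TMD upstream of the RR motif"
        )
    return pos - upstream[-1].end - 1


def cterm_basic_count(
    record: ProteinRecord,
    final_tmd: SegmentScore,
    window_len: int = DEFAULT_CTERM_WINDOW,
) -> int:
    """K+R count in the window after the final TMD, truncated at the
    sequence end (strictly after ``final_tmd.end``; H is not counted)."""
    if final_tmd.end > len(record.seq):
        raise SpanError(f"{record.id}: final TMD outside sequence")
    lo = final_tmd.end + 1
    hi = min(final_tmd.end + window_len, len(record.seq))
    return sum(1 for ch in record.seq[lo - 1 : hi] if ch in POSITIVE_RESIDUES)


def cterm_window(
    record: ProteinRecord,
    final_tmd: SegmentScore,
    window_len: int = DEFAULT_CTERM_WINDOW,
) -> tuple[int, int]:
    """The (possibly empty) window scanned by :func:`cterm_basic_count`."""
    lo = final_tmd.end + 1
    hi = min(final_tmd.end + window_len, len(record.seq))
    return (lo, hi)


def leucine_whatif(
    record: ProteinRecord,
    final_tmd: SegmentScore,
    scale: HydrophobicityScale,
    n_subs: int = 1,
    length_correction: bool = False,
) -> list[tuple[tuple[tuple[int, str], ...], VariantScore]]:
    """What-if leucine substitutions of the least-hydrophobic span residues.

    For k = 1..n_subs, the k residues of the final TMD with the highest
    helix-centre ΔG contribution (ties broken N-terminal first) are replaced
    by leucine and the span is rescored; each substitution set is returned
    with its :class:`~sectat.dgscale.VariantScore` (``delta`` >= 0 whenever
    the replaced residues contribute less favourably than leucine, which
    holds for every polar or charged target).
    """
    if not 1 <= n_subs <= 3:
        raise SectatError("n_subs must be 1, 2 or 3")
    span_len = final_tmd.end - final_tmd.start + 1
    if span_len < n_subs:
        raise SpanError(
            f"{record.id}: span {final_tmd.span()} shorter than n_subs={n_subs}"
        )
    positions = list(range(final_tmd.start, final_tmd.end + 1))
    ranked = sorted(positions, key=lambda p: (-scale.dg0(record.residue(p)), p))
    out = []
    for k in range(1, n_subs + 1):
        subs = tuple((p, "L") for p in sorted(ranked[:k]))
        score = variant_dg(
            record,
            list(subs),
            final_tmd.start,
            final_tmd.end,
            scale,
            length_correction,
        )
        out.append((subs, score))
    return out


def report(
    candidate: DualCandidate,
    topology: TopologyModel,
    record: ProteinRecord,
    scale: HydrophobicityScale,
    min_loop: int = DEFAULT_MIN_LOOP,
    window_len: int = DEFAULT_CTERM_WINDOW,
    length_correction: bool = False,
) -> SecReleaseReport:
    """Assemble the Sec-release feature vector for a classified candidate."""
    if candidate.cls == "none":
        raise SectatError(
            f"{candidate.protein_id}: cannot build a feature report for an "
            "unclassified protein"
        )
    assert candidate.final_tmd is not None and candidate.rr is not None
    final = candidate.final_tmd
    first = topology.segments[0]
    final_dg = final.dg_app
    first_dg = first.dg_app
    if math.isnan(first_dg):
        first_dg = segment_dg(
            record, first.start, first.end, scale, length_correction
        ).dg_app
    if math.isnan(final_dg):
        final_dg = segment_dg(
            record, final.start, final.end, scale, length_correction
        ).dg_app
    loop = loop_length(candidate, topology)
    count = cterm_basic_count(record, final, window_len)
    flags = set()
    if final_dg > 0:
        flags.add("weak_final_tmd")
    if count >= 2:
        flags.add("sec_avoidance")
    if loop < min_loop:
        flags.add("short_loop")
    return SecReleaseReport(
        protein_id=candidate.protein_id,
        final_tmd_dg=final_dg,
        first_tmd_dg=first_dg,
        dg_gap=final_dg - first_dg,
        loop_len=loop,
        cterm_basic_count=count,
        cterm_window=cterm_window(record, final, window_len),
        flags=frozenset(flags),
    )
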