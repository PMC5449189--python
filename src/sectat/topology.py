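"""Oriented topology models and the positive-inside orientation score.

Cytoplasmic loops of polytopic membrane proteins are enriched in lysine and
arginine (the positive-inside rule).  When no imported prediction is
available, orientation is inferred from the K+R bias between even- and
odd-parity loops:

    n_in_score = (P_even + c) / (P_even + P_odd + 2c),   c = 1

where loop 0 is the region N-terminal of the first helix, P_even counts K+R
in loops 0, 2, 4, ... and P_odd in loops 1, 3, ...  A pseudocount of one per
parity keeps the score defined and away from the extremes for sparse loops.
The N terminus is called cytoplasmic (N-in) when the score is >= 0.5; exact
ties go to N-in and are flagged.  Imported predictions (and their explicit
N-in probabilities, when present) always take precedence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from sectat.dgscale import HydrophobicityScale, SegmentScore, segment_dg
from sectat.errors import SectatError
from sectat.seqio import ImportedTopology, ProteinRecord

POSITIVE_RESIDUES = frozenset("KR")  # His is not counted


@dataclass(frozen=True)
class TopologyModel:
    """Ordered TM segments with an orientation call.

    ``orientation`` is ``"N-in"`` iff ``n_in_score >= 0.5``; ``source``
    records whether segments came from the ΔG scanner (``predicted``) or an
    external predictor (``imported``).  ``flags`` may contain ``no-TM``,
    ``orientation-tie`` and ``orientation-from-import`` (an imported topology
    without an explicit probability: the score is pinned to 1 or 0 by its
    first-loop side).
    """

    protein_id: str
    segments: tuple[SegmentScore, ...]
    orientation: str
    n_in_score: float
    source: str
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not 0.0 <= self.n_in_score <= 1.0:
            raise SectatError(f"{self.protein_id}: n_in_score outside [0, 1]")
        if (self.orientation == "N-in") != (self.n_in_score >= 0.5):
            raise SectatError(
                f"{self.protein_id}: orientation inconsistent with n_in_score"
            )
        prev_end = 0
        for seg in self.segments:
            if seg.start <= prev_end:
                raise SectatError(
                    f"{self.protein_id}: segments overlap or are out of order"
                )
            prev_end = seg.end

    @property
    def n_helices(self) -> int:
        return len(self.segments)

    def loops(self, seq_len: int) -> list[tuple[int, int]]:
        """Loop spans (1-based inclusive; empty loops have end < start).

        Loop 0 runs from residue 1 to just before the first segment; the
        C-terminal tail is the last loop.
        """
        bounds: list[tuple[int, int]] = []
        prev_end = 0
        for seg in self.segments:
            bounds.append((prev_end + 1, seg.start - 1))
            prev_end = seg.end
        bounds.append((prev_end + 1, seq_len))
        return bounds

    def loop_side(self, loop_index: int) -> str:
        """'inside' or 'outside' for loop ``loop_index`` given orientation."""
        n_in = self.orientation == "N-in"
        even = loop_index % 2 == 0
        return "inside" if (even == n_in) else "outside"


def orient_by_charge(
    record: ProteinRecord, segments: list[SegmentScore]
) -> tuple[str, float]:
    """Positive-inside orientation call from the loop K+R bias.

    Returns ``(orientation, n_in_score)``; ties score exactly 0.5 and are
    called N-in (the caller flags them).
    """
    if not segments:
        raise SectatError(f"{record.id}: orientation needs at least one segment")
    counts = [0, 0]  # even-parity loops, odd-parity loops
    prev_end = 0
    for k, seg in enumerate(segments):
        loop = record.seq[prev_end : seg.start - 1]
        counts[k % 2] += sum(1 for ch in loop if ch in POSITIVE_RESIDUES)
        prev_end = seg.end
    tail = record.seq[prev_end:]
    counts[len(segments) % 2] += sum(1 for ch in tail if ch in POSITIVE_RESIDUES)
    c = 1.0
    score = (counts[0] + c) / (counts[0] + counts[1] + 2 * c)
    return ("N-in" if score >= 0.5 else "N-out"), score


def build_topology(
    record: ProteinRecord,
    segments: list[SegmentScore] | None = None,
    imported: ImportedTopology | None = None,
    scale: HydrophobicityScale | None = None,
    length_correction: bool = False,
) -> TopologyModel:
    """Assemble a topology model from predicted segments or an import.

    An imported topology takes precedence: its spans, first-loop side and
    (when present) N-in probability are used, and its spans are ΔG-scored
    when a scale is supplied (otherwise ``dg_app`` is NaN).  Without an
    import, orientation comes from :func:`orient_by_charge`; a protein with
    no segments at all is N-in by convention with score 0.5 and flag
    ``no-TM``.
    """
    flags: set[str] = set()
    if imported is not None:
        if imported.protein_id != record.id:
            raise SectatError(
                f"imported topology is for {imported.protein_id!r}, "
                f"record is {record.id!r}"
            )
        segs = []
        for start, end in imported.segments:
            if scale is not None:
                segs.append(segment_dg(record, start, end, scale, length_correction))
            else:
                segs.append(SegmentScore(start=start, end=end, dg_app=math.nan))
        orientation = (
            "N-in" if imported.orientation_of_first_loop == "inside" else "N-out"
        )
        if imported.n_in_probability is not None:
            score = imported.n_in_probability
            # the probability is authoritative for the orientation call
            orientation = "N-in" if score >= 0.5 else "N-out"
            if score == 0.5:
                flags.add("orientation-tie")
        else:
            score = 1.0 if orientation == "N-in" else 0.0
            flags.add("orientation-from-import")
        if not segs:
            flags.add("no-TM")
        return TopologyModel(
            protein_id=record.id,
            segments=tuple(segs),
            orientation=orientation,
            n_in_score=score,
            source="imported",
            flags=frozenset(flags),
        )
    segments = segments or []
    if not segments:
        return TopologyModel(
            protein_id=record.id,
            segments=(),
            orientation="N-in",
            n_in_score=0.5,
            source="predicted",
            flags=frozenset({"no-TM", "orientation-tie"}),
        )
    orientation, score = orient_by_charge(record, segments)
    if score == 0.5:
        flags.add("orientation-tie")
    return TopologyModel(
        protein_id=record.id,
        segments=tuple(segments),
        orientation=orientation,
        n_in_score=score,
        source="predicted",
        flags=frozenset(flags),
    )
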