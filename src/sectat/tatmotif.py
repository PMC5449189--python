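"""Twin-arginine (RR) motif detection and consensus-context scoring.

Tat signal sequences carry a near-invariant consecutive arginine pair in the
consensus context S/T-R-R-x-F-L-K.  Detection keys on the RR pair alone
(the default for genome screening, where the adjacency-to-TMD requirement of
the downstream screen supplies the specificity); the surrounding consensus
can be scored as an optional stringency filter.
"""

from __future__ import annotations

from dataclasses import dataclass

from sectat.errors import SectatError
from sectat.seqio import ProteinRecord

#: scored context positions as offsets from the first arginine; the 'x' of
#: the consensus (offset +2) is unscored.
CONSENSUS_CHECKS: tuple[tuple[int, frozenset[str]], ...] = (
    (-1, frozenset("ST")),
    (+3, frozenset("F")),
    (+4, frozenset("L")),
    (+5, frozenset("K")),
)

MAX_CONSENSUS_SCORE = len(CONSENSUS_CHECKS)


@dataclass(frozen=True)
class RRMotif:
    """A twin-arginine pair.

    ``pos`` is the 1-based position of the first arginine; ``context`` is
    the consensus window (offsets -1..+5 from the first arginine, clipped at
    the sequence ends); ``consensus_score`` counts satisfied consensus
    positions (0..4).
    """

    pos: int
    context: str
    consensus_score: int

    def __post_init__(self) -> None:
        if not 0 <= self.consensus_score <= MAX_CONSENSUS_SCORE:
            raise SectatError("consensus_score outside 0..4")


def _score_context(seq: str, pos: int) -> int:
    score = 0
    for offset, allowed in CONSENSUS_CHECKS:
        idx = pos + offset  # 1-based
        if 1 <= idx <= len(seq) and seq[idx - 1] in allowed:
            score += 1
    return score


def find_rr_motifs(
    record: ProteinRecord,
    mode: str = "rr-only",
    min_score: int = 2,
) -> list[RRMotif]:
    """All twin-arginine pairs of a sequence, in ascending position.

    Overlapping pairs (``RRR`` yields two) are all reported.  In
    ``consensus`` mode only motifs with ``consensus_score >= min_score``
    are returned; ``rr-only`` returns every pair.
    """
    if mode not in ("rr-only", "consensus"):
        raise SectatError(f"unknown motif mode {mode!r}")
    seq = record.seq
    out: list[RRMotif] = []
    for i in range(1, len(seq)):  # i = 1-based position of first residue
        if seq[i - 1] == "R" and seq[i] == "R":
            score = _score_context(seq, i)
            if mode == "consensus" and score < min_score:
                continue
            lo = max(1, i - 1)
            hi = min(len(seq), i + 5)
            out.append(RRMotif(pos=i, context=seq[lo - 1 : hi], consensus_score=score))
    return out
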