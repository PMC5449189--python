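"""The combined screen for dual Sec/Tat-targeted polytopic membrane proteins.

A protein qualifies when a twin-arginine motif sits in a cytoplasmic loop
with exactly one TM helix downstream of it, the upstream helix count and the
orientation agree (two classes):

* ``N-in-even`` — an even number (>= 2) of TMDs before the motif, one after,
  N-in score above ``n_in_threshold`` (default 0.9);
* ``N-out-odd`` — an odd number (1, 3, 5 or 7) of TMDs before the motif, one
  after, N-in score below ``n_out_threshold`` (default 0.5).

Proteins whose N-in score falls between the two thresholds are deliberately
left unclassified (reason ``orientation``).

Because the Tat-dependent final TMD is only weakly hydrophobic (positive
ΔG_app in every characterized family), a plain threshold scanner misses it;
with ``rescue_weak_final_tmd`` on (the default) the scanner is re-queried
for the best sub-threshold window downstream of the motif before a candidate
is rejected for lacking a final TMD.
"""

from __future__ import annotations

from dataclasses import dataclass

from sectat.dgscale import (
    HydrophobicityScale,
    SegmentScore,
    best_window_after,
    scan_segments,
)
from sectat.errors import SectatError
from sectat.seqio import ImportedTopology, ProteinRecord
from sectat.tatmotif import RRMotif, find_rr_motifs
from sectat.topology import TopologyModel, build_topology

#: rejection reason codes, from most to least fundamental
REASONS = ("no-RR", "tmd-count", "gap", "orientation")


@dataclass(frozen=True)
class ScreenParams:
    """Tunable thresholds of the screen (defaults follow the published
    genome-scale parameterization where one exists).

    ``max_gap`` bounds the residues between the twin-arginine pair and the
    start of the final TMD; the motif "directly precedes" the final helix in
    the known families (gap 6 in the actinobacterial Rieske protein), and the
    bound prevents pairing distant motifs with unrelated helices.
    ``allow_zero_before`` admits the formally even count of zero upstream
    TMDs (off by default: the screen targets internal signal anchors).
    """

    n_in_threshold: float = 0.9
    n_out_threshold: float = 0.5
    max_gap: int = 30
    rescue_weak_final_tmd: bool = True
    allow_zero_before: bool = False
    threshold_dg: float = 0.0
    length_correction: bool = False
    motif_mode: str = "rr-only"
    motif_min_score: int = 2


@dataclass(frozen=True)
class DualCandidate:
    """Screen verdict for one protein.

    ``cls`` is ``N-in-even``, ``N-out-odd`` or ``none`` (with ``reason``);
    ``rr_to_tmd_gap`` counts the residues separating the twin-arginine pair
    from the final TMD (``final_tmd.start - rr.pos - 1``).  ``rescued`` marks
    a final TMD recovered by the sub-threshold re-query.
    """

    protein_id: str
    cls: str
    rr: RRMotif | None = None
    n_tmd_before: int = 0
    n_tmd_after: int = 0
    final_tmd: SegmentScore | None = None
    rr_to_tmd_gap: int | None = None
    reason: str | None = None
    rescued: bool = False
    all_motifs: tuple[RRMotif, ...] = ()

    def __post_init__(self) -> None:
        if self.cls not in ("N-in-even", "N-out-odd", "none"):
            raise SectatError(f"unknown class {self.cls!r}")
        if self.cls == "none" and self.reason not in REASONS:
            raise SectatError(f"rejection needs a reason code from {REASONS}")


def _classify_motif(
    topology: TopologyModel,
    motif: RRMotif,
    params: ScreenParams,
    record: ProteinRecord | None,
    scale: HydrophobicityScale | None,
) -> DualCandidate:
    """Evaluate one motif against the class rules; cls='none' with the first
    failing reason otherwise."""
    pos = motif.pos
    segments = list(topology.segments)
    # Boundary semantics: a predicted helix that straddles the arginine pair
    # and extends downstream is the TMD the motif precedes (gap 0); one that
    # merely ends at the pair belongs upstream.  Motifs strictly interior to
    # a helix were already discarded by the caller.
    before: list[SegmentScore] = []
    after: list[SegmentScore] = []
    for s in segments:
        if s.end < pos:
            before.append(s)
        elif s.start > pos + 1 or s.end > pos + 1:
            after.append(s)
        else:
            before.append(s)
    rescued = False
    if (
        not after
        and params.rescue_weak_final_tmd
        and record is not None
        and scale is not None
    ):
        win = best_window_after(
            record,
            scale,
            min_start=pos + 2,
            length_correction=params.length_correction,
            exclude=segments,
        )
        if win is not None:
            after = [win]
            rescued = True

    def reject(reason: str) -> DualCandidate:
        return DualCandidate(
            protein_id=topology.protein_id,
            cls="none",
            rr=motif,
            n_tmd_before=len(before),
            n_tmd_after=len(after),
            final_tmd=after[0] if len(after) == 1 else None,
            rr_to_tmd_gap=max(0, after[0].start - pos - 1) if len(after) == 1 else None,
            reason=reason,
            rescued=rescued,
        )

    if len(after) != 1:
        return reject("tmd-count")
    final = after[0]
    gap = max(0, final.start - pos - 1)
    if gap > params.max_gap:
        return reject("gap")
    n_before = len(before)
    score = topology.n_in_score
    if n_before % 2 == 0:
        if n_before == 0 and not params.allow_zero_before:
            return reject("tmd-count")
        if score > params.n_in_threshold:
            cls = "N-in-even"
        else:
            return reject("orientation")
    else:
        if n_before not in (1, 3, 5, 7):
            return reject("tmd-count")
        if score < params.n_out_threshold:
            cls = "N-out-odd"
        else:
            return reject("orientation")
    return DualCandidate(
        protein_id=topology.protein_id,
        cls=cls,
        rr=motif,
        n_tmd_before=n_before,
        n_tmd_after=1,
        final_tmd=final,
        rr_to_tmd_gap=gap,
        reason=None,
        rescued=rescued,
    )


def screen(
    topology: TopologyModel,
    motifs: list[RRMotif],
    params: ScreenParams | None = None,
    record: ProteinRecord | None = None,
    scale: HydrophobicityScale | None = None,
) -> DualCandidate:
    """Classify one protein from its topology model and its RR motifs.

    Motifs are evaluated in ascending position; a motif lying strictly
    inside a TM span is skipped; the first motif satisfying either class
    wins (all motifs are echoed in the verdict).  ``record`` and ``scale``
    enable the weak-final-TMD rescue; without them rescue is silently
    unavailable.
    """
    params = params or ScreenParams()
    usable = []
    for motif in sorted(motifs, key=lambda m: m.pos):
        interior = any(
            s.start < motif.pos and motif.pos + 1 < s.end for s in topology.segments
        )
        if not interior:
            usable.append(motif)
    if not usable:
        return DualCandidate(
            protein_id=topology.protein_id,
            cls="none",
            reason="no-RR",
            all_motifs=tuple(motifs),
        )
    first_rejection: DualCandidate | None = None
    for motif in usable:
        verdict = _classify_motif(topology, motif, params, record, scale)
        if verdict.cls != "none":
            return DualCandidate(
                **{**verdict.__dict__, "all_motifs": tuple(motifs)}
            )
        if first_rejection is None:
            first_rejection = verdict
    assert first_rejection is not None
    return DualCandidate(**{**first_rejection.__dict__, "all_motifs": tuple(motifs)})


def screen_record(
    record: ProteinRecord,
    scale: HydrophobicityScale,
    params: ScreenParams | None = None,
    imported: ImportedTopology | None = None,
) -> tuple[DualCandidate, TopologyModel, list[RRMotif]]:
    """Full per-record pipeline: scan (or import) topology, find motifs,
    screen.  Returns the verdict together with its inputs for reporting."""
    params = params or ScreenParams()
    if imported is not None:
        topo = build_topology(
            record, imported=imported, scale=scale,
            length_correction=params.length_correction,
        )
    else:
        segs = scan_segments(
            record,
            scale,
            threshold_dg=params.threshold_dg,
            length_correction=params.length_correction,
        )
        topo = build_topology(record, segments=segs)
    motifs = find_rr_motifs(
        record, mode=params.motif_mode, min_score=params.motif_min_score
    )
    verdict = screen(topo, motifs, params, record=record, scale=scale)
    return verdict, topo, motifs
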