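"""Synthetic protein fixtures with known TM architecture and ground truth.

The generator builds multi-spanning membrane proteins to order: each TMD is
a hydrophobic stretch hill-climbed until its ΔG_app under the configured
scale sits within a tolerance of its target; loops are drawn from a polar
alphabet with a controlled number of K residues on the designated membrane
side (driving the positive-inside orientation signal); a twin-arginine motif
in its consensus context (``SRRGFLK``) can be planted a chosen number of
residues upstream of any TMD.  Everything is reproducible from a single
integer seed, and the emitted ground truth (spans, motif position,
orientation, expected screen class) is consistent with the constructed
sequence by construction.

The stock architectures emulate the four characterized dual Sec/Tat
protein families: a 2+1-TMD N-in protein (actinobacterial Rieske-like), two
4+1-TMD N-in proteins (heme/MoCo-binding-like and polyferredoxin-like,
differing in loop geometry and final-TMD strength) and a 3+1-TMD N-out
protein (YkuE-like metallophosphoesterase), plus negative controls.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from sectat.dgscale import HydrophobicityScale
from sectat.errors import SynthesisError
from sectat.seqio import ProteinRecord, format_tmhmm_short

#: residues the TMD hill-climb may use (no charges, no C, no X)
TMD_ALPHABET = "LIVFMAGSTWYNQP"
#: polar loop background (no K/R so the only RR pair is the planted motif)
LOOP_ALPHABET = "STNQGPDE"
RR_CONTEXT = "SRRGFLK"  # S/T-R-R-x-F-L-K consensus, x = G

DEFAULT_TOL = 0.2


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic protein.

    ``rr_gap`` is the number of residues between the twin-arginine pair and
    the start of the TMD it precedes (None: no motif).  ``rr_before_tmd``
    selects which TMD the motif precedes (1-based; default the last).
    ``inside_kr_per_loop``/``outside_kr_per_loop`` are K counts inserted per
    loop on the cytoplasmic/extracytoplasmic side; ``cterm_kr`` places
    additional K residues in the C-terminal tail close to the final TMD
    (a Sec-avoidance arrangement).
    """

    seed: int
    n_tmd: int
    tmd_target_dg: tuple[float, ...]
    tmd_len: int = 21
    loop_lens: tuple[int, ...] | None = None
    inside_kr_per_loop: int = 4
    outside_kr_per_loop: int = 0
    rr_gap: int | None = None
    rr_before_tmd: int | None = None
    orientation: str = "N-in"
    cterm_kr: int = 0
    tol: float = DEFAULT_TOL
    name: str = "synth"

    def resolved_loop_lens(self) -> tuple[int, ...]:
        if self.loop_lens is not None:
            if len(self.loop_lens) != self.n_tmd + 1:
                raise SynthesisError(
                    f"need {self.n_tmd + 1} loop lengths, got {len(self.loop_lens)}"
                )
            return self.loop_lens
        return tuple([20] * self.n_tmd + [30])


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually built (1-based coordinates)."""

    segments: tuple[tuple[int, int], ...]
    tmd_dg: tuple[float, ...]
    rr_pos: int | None
    orientation: str
    expected_class: str
    loop_sides: tuple[str, ...]

    def first_loop_side(self) -> str:
        return self.loop_sides[0]


def _segment_dg_str(seq: str, scale: HydrophobicityScale) -> float:
    length = len(seq)
    return sum(scale.contribution(ch, i, length) for i, ch in enumerate(seq))


def _build_tmd(
    rng: np.random.Generator,
    target: float,
    length: int,
    scale: HydrophobicityScale,
    tol: float,
    index: int,
    max_iter: int = 6000,
) -> str:
    """Hill-climb a residue string until its ΔG_app hits the target.

    Local search rather than analytic composition: the position profile
    makes the contribution of a residue depend on where it sits, so exact
    target composition is scale-dependent.  The two residues at each end
    are pinned to strong hydrophobics (as in real TM helices, whose ends
    abut the lipid headgroups) so the constructed span is a sharp local
    optimum for window scanners; only interior positions are mutated.
    """
    anchor = 2 if length >= 8 else 0
    alphabet = np.array(list(TMD_ALPHABET))
    seq = list(rng.choice(np.array(list("LIVF")), size=length))
    for i in range(anchor, length - anchor):
        seq[i] = str(rng.choice(np.array(list("LIVFMA"))))
    current = _segment_dg_str("".join(seq), scale)
    for _ in range(max_iter):
        if abs(current - target) <= tol:
            return "".join(seq)
        idx = anchor + int(rng.integers(length - 2 * anchor))
        new_res = str(rng.choice(alphabet))
        if new_res == seq[idx]:
            continue
        old_res = seq[idx]
        seq[idx] = new_res
        candidate = _segment_dg_str("".join(seq), scale)
        if abs(candidate - target) < abs(current - target):
            current = candidate
        else:
            seq[idx] = old_res
    raise SynthesisError(
        f"TMD {index + 1}: could not reach target ΔG {target:+.2f} "
        f"(stuck at {current:+.2f}) within {max_iter} iterations"
    )


def _build_loop(
    rng: np.random.Generator,
    length: int,
    n_charges: int,
    reserve_tail: int = 0,
) -> list[str]:
    """A polar loop with ``n_charges`` K residues, avoiding the last
    ``reserve_tail`` positions (kept free for a planted motif)."""
    loop = [str(c) for c in rng.choice(np.array(list(LOOP_ALPHABET)), size=length)]
    free = length - reserve_tail
    if n_charges > 0:
        if free <= 0:
            raise SynthesisError("loop too short for its charge insertions")
        n_charges = min(n_charges, free)
        positions = rng.choice(free, size=n_charges, replace=False)
        for p in positions:
            loop[int(p)] = "K"
    return loop


def _local_best_window(
    seq: str, span: tuple[int, int], scale: HydrophobicityScale
) -> tuple[int, int]:
    """Best-scoring window with a start within 6 residues of the span's
    (ties as in the scanner: ΔG, then start, then length)."""
    s0 = span[0]
    best_key = None
    best = span
    for st in range(max(1, s0 - 6), s0 + 7):
        for length in range(scale.l_min, scale.l_max + 1):
            en = st + length - 1
            if en > len(seq):
                break
            dg = _segment_dg_str(seq[st - 1 : en], scale)
            key = (dg, st, length)
            if best_key is None or key < best_key:
                best_key = key
                best = (st, en)
    return best


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def make_protein(
    spec: SyntheticSpec, scale: HydrophobicityScale
) -> tuple[ProteinRecord, GroundTruth]:
    """Construct a synthetic protein and its ground-truth annotation."""
    if spec.orientation not in ("N-in", "N-out"):
        raise SynthesisError("orientation must be N-in or N-out")
    if len(spec.tmd_target_dg) != spec.n_tmd:
        raise SynthesisError(
            f"need {spec.n_tmd} ΔG targets, got {len(spec.tmd_target_dg)}"
        )
    loop_lens = spec.resolved_loop_lens()
    rr_before = spec.rr_before_tmd if spec.rr_before_tmd is not None else spec.n_tmd
    if spec.rr_gap is not None:
        if not 1 <= rr_before <= spec.n_tmd:
            raise SynthesisError("rr_before_tmd out of range")
        if spec.rr_gap < 1:
            raise SynthesisError("rr_gap must be >= 1")
        rr_loop_len = loop_lens[rr_before - 1]
        if rr_loop_len < spec.rr_gap + 2:
            raise SynthesisError(
                "loop upstream of the motif-bearing TMD too short for rr_gap"
            )
    rng = np.random.default_rng(spec.seed)
    n_in = spec.orientation == "N-in"

    def side(loop_index: int) -> str:
        return "inside" if ((loop_index % 2 == 0) == n_in) else "outside"

    tmds = [
        _build_tmd(rng, t, spec.tmd_len, scale, spec.tol, i)
        for i, t in enumerate(spec.tmd_target_dg)
    ]
    loops: list[list[str]] = []
    for k, length in enumerate(loop_lens):
        n_charges = (
            spec.inside_kr_per_loop if side(k) == "inside" else spec.outside_kr_per_loop
        )
        reserve = 0
        if spec.rr_gap is not None and k == rr_before - 1:
            reserve = spec.rr_gap + len(RR_CONTEXT)  # keep the motif region clean
        loop = _build_loop(rng, length, n_charges, reserve_tail=reserve)
        if k == len(loop_lens) - 1 and spec.cterm_kr > 0:
            # Sec-avoidance charges right after the final TMD
            for j in range(min(spec.cterm_kr, length)):
                loop[2 * j % length] = "K" if j % 2 == 0 else "R"
        loops.append(loop)

    rr_pos: int | None = None
    if spec.rr_gap is not None:
        loop = loops[rr_before - 1]
        length = len(loop)
        first_r_off = length - spec.rr_gap - 1  # 0-based offset of first R
        ctx_start = first_r_off - 1
        for j, ch in enumerate(RR_CONTEXT):
            off = ctx_start + j
            if 0 <= off < length:
                loop[off] = ch

    def assemble() -> tuple[str, list[tuple[int, int]], int | None]:
        parts: list[str] = []
        spans: list[tuple[int, int]] = []
        rr: int | None = None
        pos = 0
        for k in range(spec.n_tmd):
            if spec.rr_gap is not None and k == rr_before - 1:
                rr = pos + (len(loops[k]) - spec.rr_gap - 1) + 1
            parts.append("".join(loops[k]))
            pos += len(loops[k])
            spans.append((pos + 1, pos + spec.tmd_len))
            parts.append(tmds[k])
            pos += spec.tmd_len
        parts.append("".join(loops[spec.n_tmd]))
        return "".join(parts), spans, rr

    # Well-posedness: a fixture's ground truth is only meaningful for a
    # window scanner if the constructed span is the best-scoring window in
    # its own neighbourhood.  Strongly hydrophobic TMDs whose local optimum
    # drifted > ~2 residues (the hill-climb can concentrate hydrophobic
    # mass off-centre) are rebuilt from fresh random starts.
    seq, segments, rr_pos = assemble()
    for _ in range(25):
        offender = None
        for k, (span, target) in enumerate(zip(segments, spec.tmd_target_dg)):
            if target > -1.0:
                continue
            best = _local_best_window(seq, span, scale)
            if _overlap(best, span) < 0.9 * spec.tmd_len:
                offender = k
                break
        if offender is None:
            break
        tmds[offender] = _build_tmd(
            rng, spec.tmd_target_dg[offender], spec.tmd_len, scale, spec.tol, offender
        )
        seq, segments, rr_pos = assemble()
    else:
        raise SynthesisError(
            "could not construct locally optimal TMD spans for this recipe"
        )

    measured = tuple(_segment_dg_str(t, scale) for t in tmds)
    for i, (dg, target) in enumerate(zip(measured, spec.tmd_target_dg)):
        if abs(dg - target) > spec.tol + 1e-9:
            raise SynthesisError(f"TMD {i + 1} missed its ΔG target")

    expected = _expected_class(spec, rr_before)
    record = ProteinRecord(
        id=f"{spec.name}-{spec.seed}",
        seq=seq,
        description=(
            f"synthetic seed={spec.seed} n_tmd={spec.n_tmd} "
            f"orientation={spec.orientation} rr_gap={spec.rr_gap} "
            f"expected={expected}"
        ),
    )
    truth = GroundTruth(
        segments=tuple(segments),
        tmd_dg=measured,
        rr_pos=rr_pos,
        orientation=spec.orientation,
        expected_class=expected,
        loop_sides=tuple(side(k) for k in range(spec.n_tmd + 1)),
    )
    return record, truth


def _expected_class(spec: SyntheticSpec, rr_before: int) -> str:
    if spec.rr_gap is None:
        return "none"
    n_before = rr_before - 1
    n_after = spec.n_tmd - rr_before + 1
    if n_after != 1:
        return "none"
    if spec.orientation == "N-in" and n_before % 2 == 0 and n_before >= 2:
        return "N-in-even"
    if spec.orientation == "N-out" and n_before % 2 == 1 and n_before <= 7:
        return "N-out-odd"
    return "none"


# ---------------------------------------------------------------------------
# Stock architectures
# ---------------------------------------------------------------------------

def _rieske_like(seed: int) -> SyntheticSpec:
    """2+1 TMDs, N-in: actinobacterial Rieske-like architecture."""
    return SyntheticSpec(
        seed=seed,
        n_tmd=3,
        tmd_target_dg=(-2.0, -2.0, 0.5),
        loop_lens=(25, 15, 43, 30),
        rr_gap=6,
        orientation="N-in",
        name="rieske",
    )


def _moco_like(seed: int) -> SyntheticSpec:
    """4+1 TMDs, N-in: heme/MoCo-binding-protein-like architecture."""
    return SyntheticSpec(
        seed=seed,
        n_tmd=5,
        tmd_target_dg=(-2.0, -1.8, -1.6, -2.0, 0.8),
        loop_lens=(20, 15, 15, 15, 25, 30),
        rr_gap=6,
        orientation="N-in",
        name="moco",
    )


def _pfd_like(seed: int) -> SyntheticSpec:
    """4+1 TMDs, N-in: polyferredoxin-like architecture (longer loops,
    marginal final TMD)."""
    return SyntheticSpec(
        seed=seed,
        n_tmd=5,
        tmd_target_dg=(-2.2, -1.6, -1.7, -1.9, 0.4),
        loop_lens=(12, 25, 25, 25, 30, 35),
        rr_gap=8,
        orientation="N-in",
        name="pfd",
    )


def _ykue_like(seed: int) -> SyntheticSpec:
    """3+1 TMDs, N-out: YkuE-like metallophosphoesterase architecture."""
    return SyntheticSpec(
        seed=seed,
        n_tmd=4,
        tmd_target_dg=(-1.8, -2.0, -1.9, 1.0),
        loop_lens=(15, 20, 20, 25, 30),
        rr_gap=6,
        orientation="N-out",
        name="ykue",
    )


def _no_rr_negative(seed: int) -> SyntheticSpec:
    """Negative control: dual-like architecture with the motif scrambled
    away (no RR anywhere)."""
    return replace(_rieske_like(seed), rr_gap=None, name="neg-norr")


def _two_after_negative(seed: int) -> SyntheticSpec:
    """Negative control: RR motif with two strongly hydrophobic TMDs after
    it (violates the exactly-one rule)."""
    return SyntheticSpec(
        seed=seed,
        n_tmd=4,
        tmd_target_dg=(-2.0, -2.0, -2.0, -2.0),
        loop_lens=(20, 15, 25, 15, 30),
        rr_gap=6,
        rr_before_tmd=3,
        orientation="N-in",
        name="neg-twoafter",
    )


ARCHITECTURES = {
    "rieske": _rieske_like,
    "moco": _moco_like,
    "pfd": _pfd_like,
    "ykue": _ykue_like,
    "neg-norr": _no_rr_negative,
    "neg-twoafter": _two_after_negative,
}

FAMILY_ARCHITECTURES = ("rieske", "moco", "pfd", "ykue")
NEGATIVE_ARCHITECTURES = ("neg-norr", "neg-twoafter")


def family_spec(name: str, seed: int, cterm_kr: int = 0) -> SyntheticSpec:
    """A stock architecture by name, optionally with Sec-avoidance tail
    charges."""
    spec = ARCHITECTURES[name](seed)
    if cterm_kr:
        spec = replace(spec, cterm_kr=cterm_kr)
    return spec


def simulate_panel(
    scale: HydrophobicityScale,
    base_seed: int,
    n_per_arch: int,
    architectures: tuple[str, ...] = FAMILY_ARCHITECTURES + NEGATIVE_ARCHITECTURES,
) -> list[tuple[ProteinRecord, GroundTruth]]:
    """A seeded panel of fixtures across architectures; seeds are derived
    deterministically from ``base_seed``."""
    out = []
    for a, arch in enumerate(architectures):
        for j in range(n_per_arch):
            seed = (base_seed * 10007 + a * 1009 + j) % (2**31 - 1)
            out.append(make_protein(ARCHITECTURES[arch](seed), scale))
    return out


def tmhmm_line(
    record: ProteinRecord, truth: GroundTruth, n_in_probability: float | None = None
) -> str:
    """Render the fixture's ground truth as an importable TMHMM-short line."""
    if n_in_probability is None:
        n_in_probability = 0.95 if truth.orientation == "N-in" else 0.05
    return format_tmhmm_short(
        record.id,
        len(record.seq),
        truth.segments,
        truth.first_loop_side(),
        n_in_probability,
    )


def ground_truth_rows(
    items: list[tuple[ProteinRecord, GroundTruth]]
) -> list[dict]:
    """Ground truth as TSV-ready rows (used by the ``simulate`` command)."""
    rows = []
    for record, truth in items:
        rows.append(
            {
                "id": record.id,
                "length": len(record.seq),
                "segments": ";".join(f"{s}-{e}" for s, e in truth.segments),
                "tmd_dg": ";".join(f"{d:.3f}" for d in truth.tmd_dg),
                "rr_pos": truth.rr_pos if truth.rr_pos is not None else "",
                "orientation": truth.orientation,
                "expected_class": truth.expected_class,
            }
        )
    return rows
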