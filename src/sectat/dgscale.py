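"""Apparent free energy of membrane insertion (ΔG_app) of helix segments.

The score follows the "biological" hydrophobicity scale measured for
translocon-mediated insertion: each residue contributes a free energy that
depends on the residue type and on its fractional position along the helix
(polar and charged residues are most costly at the helix centre; the
aromatics W and Y prefer the membrane interfaces).  The segment score is

    dG_app(start..end) = sum_i  f_aa(res_i, p_i)  [+ dG_len(L)]

with p_i the scaled position in [-9, 9] across the span and dG_len an
optional smooth length penalty, zero at the reference length.  Negative
dG_app favours membrane insertion by the Sec translocon; the weakly
hydrophobic, Tat-dependent final TMDs of dual-targeted proteins score
positive.

The numerical content of the scale ships as a versioned YAML data file and
is pluggable; a ``uniform`` position profile (every residue contributes its
helix-centre value regardless of position) is always available and is used
by the hand-sum oracles in the test suite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import yaml

from sectat.errors import ScaleError, SpanError
from sectat.seqio import ProteinRecord, STANDARD_AA

DEFAULT_SCALE_RESOURCE = "biological_scale.yaml"


@dataclass(frozen=True)
class HydrophobicityScale:
    """Per-residue ΔG contributions with a position-dependence profile.

    Parameters
    ----------
    profiles : dict
        For each residue a tuple ``(a0, a1)`` or ``(a0, a1, a2, a3, a4)``
        parameterizing the position dependence (see module docstring).
        ``a0`` terms are helix-centre contributions in kcal/mol.
    profile_kind : str
        ``"gaussian"`` applies the position profile; ``"uniform"`` scores
        every in-span residue with its helix-centre contribution (weight 1
        everywhere), which makes the segment score a plain sum.
    length_ref, length_quad : length-correction coefficients;
        ``dG_len(L) = length_quad * (L - length_ref)**2``.
    l_min, l_max : allowed lengths for *predicted* helices (explicit spans
        may have any length >= 1).
    x_dg : contribution of the ambiguity residue X (flagged in output).
    """

    name: str
    version: str
    profiles: dict[str, tuple[float, ...]]
    position_span: float = 9.0
    length_ref: int = 21
    length_quad: float = 0.0123
    l_min: int = 19
    l_max: int = 23
    x_dg: float = 0.0
    profile_kind: str = "gaussian"

    def __post_init__(self) -> None:
        missing = STANDARD_AA - set(self.profiles)
        if missing:
            raise ScaleError(
                f"scale {self.name!r}: missing residues {''.join(sorted(missing))}"
            )
        for aa, params in self.profiles.items():
            if len(params) not in (2, 5):
                raise ScaleError(
                    f"scale {self.name!r}: residue {aa} needs 2 or 5 parameters"
                )
        if self.profile_kind not in ("gaussian", "uniform"):
            raise ScaleError(f"unknown profile kind {self.profile_kind!r}")
        if not 1 <= self.l_min <= self.l_max:
            raise ScaleError("need 1 <= l_min <= l_max")

    def dg0(self, aa: str) -> float:
        """Helix-centre contribution of residue ``aa`` (kcal/mol)."""
        if aa == "X":
            return self.x_dg
        try:
            params = self.profiles[aa]
        except KeyError as exc:
            raise ScaleError(f"residue {aa!r} not in scale {self.name!r}") from exc
        if len(params) == 2:
            return params[0]
        a0, a1, a2, a3, a4 = params
        return a0 + 2.0 * a2 * math.exp(-a3 * a4 * a4)

    def contribution(self, aa: str, index: int, length: int) -> float:
        """Contribution of residue ``aa`` at 0-based ``index`` in a helix of
        ``length`` residues."""
        if aa == "X":
            return self.x_dg
        if self.profile_kind == "uniform":
            return self.dg0(aa)
        if length == 1:
            p = 0.0
        else:
            p = self.position_span * (2.0 * index / (length - 1) - 1.0)
        try:
            params = self.profiles[aa]
        except KeyError as exc:
            raise ScaleError(f"residue {aa!r} not in scale {self.name!r}") from exc
        if len(params) == 2:
            a0, a1 = params
            return a0 * math.exp(-a1 * p * p)
        a0, a1, a2, a3, a4 = params
        return a0 * math.exp(-a1 * p * p) + a2 * (
            math.exp(-a3 * (p - a4) ** 2) + math.exp(-a3 * (p + a4) ** 2)
        )

    def length_penalty(self, length: int) -> float:
        return self.length_quad * (length - self.length_ref) ** 2

    def with_uniform_weights(self) -> "HydrophobicityScale":
        """Copy of this scale with the flat position profile (oracle use)."""
        return replace(self, profile_kind="uniform")

    @property
    def min_dg0(self) -> float:
        return min(self.dg0(aa) for aa in STANDARD_AA)


def load_scale(path: str | Path | None = None) -> HydrophobicityScale:
    """Load a hydrophobicity scale from YAML; default: the packaged
    biological insertion scale."""
    if path is None:
        with resources.files("sectat.data").joinpath(DEFAULT_SCALE_RESOURCE).open() as fh:
            raw = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    try:
        length = raw.get("length_correction", {})
        return HydrophobicityScale(
            name=raw["name"],
            version=str(raw.get("version", "")),
            profiles={aa: tuple(map(float, v)) for aa, v in raw["profiles"].items()},
            position_span=float(raw.get("position_span", 9.0)),
            length_ref=int(length.get("reference_length", 21)),
            length_quad=float(length.get("quadratic", 0.0)),
            l_min=int(raw.get("l_min", 19)),
            l_max=int(raw.get("l_max", 23)),
            x_dg=float(raw.get("x_dg", 0.0)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ScaleError(f"malformed scale file: {exc}") from exc


@dataclass(frozen=True)
class SegmentScore:
    """A scored helix span (1-based inclusive coordinates)."""

    start: int
    end: int
    dg_app: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "SegmentScore") -> bool:
        return self.start <= other.end and other.start <= self.end

    def span(self) -> str:
        return f"{self.start}-{self.end}"


def segment_dg(
    record: ProteinRecord,
    start: int,
    end: int,
    scale: HydrophobicityScale,
    length_correction: bool = False,
) -> SegmentScore:
    """Score the helix span ``start..end`` (1-based inclusive).

    Deterministic; values are conventionally reported to 3 decimals but the
    stored ``dg_app`` keeps full precision so that downstream deltas are
    exact.
    """
    n = len(record.seq)
    if start > end:
        raise SpanError(f"{record.id}: empty span {start}-{end}")
    if not (1 <= start and end <= n):
        raise SpanError(
            f"{record.id}: span {start}-{end} outside sequence of length {n}"
        )
    length = end - start + 1
    total = 0.0
    for idx in range(length):
        total += scale.contribution(record.seq[start - 1 + idx], idx, length)
    if length_correction:
        total += scale.length_penalty(length)
    return SegmentScore(start=start, end=end, dg_app=total)


def _candidate_windows(
    record: ProteinRecord,
    scale: HydrophobicityScale,
    length_correction: bool,
    region_start: int = 1,
    region_end: int | None = None,
) -> list[SegmentScore]:
    """All windows of length l_min..l_max inside the region, scored."""
    n = len(record.seq)
    region_end = n if region_end is None else min(region_end, n)
    out: list[SegmentScore] = []
    for start in range(region_start, region_end + 1):
        for length in range(scale.l_min, scale.l_max + 1):
            end = start + length - 1
            if end > region_end:
                break
            out.append(segment_dg(record, start, end, scale, length_correction))
    return out


def _greedy_select(windows: list[SegmentScore]) -> list[SegmentScore]:
    """Non-overlapping selection by ascending ΔG; ties broken by smaller
    start, then shorter length (determinism)."""
    chosen: list[SegmentScore] = []
    for win in sorted(windows, key=lambda w: (w.dg_app, w.start, w.length)):
        if not any(win.overlaps(c) for c in chosen):
            chosen.append(win)
    return sorted(chosen, key=lambda w: w.start)


def scan_segments(
    record: ProteinRecord,
    scale: HydrophobicityScale,
    threshold_dg: float = 0.0,
    length_correction: bool = False,
    all_minima: bool = False,
) -> list[SegmentScore]:
    """Predict TM helix spans by exhaustive ΔG window search.

    Every window of length ``l_min..l_max`` is scored; windows with
    ``dg_app <= threshold_dg`` (all windows when ``all_minima`` is set, which
    is how weakly hydrophobic Tat-dependent final TMDs are recovered) enter a
    greedy non-overlapping selection by ascending ΔG.  Returned segments are
    sorted by start.
    """
    if len(record.seq) < scale.l_min:
        warnings.warn(
            f"{record.id}: sequence shorter than minimum helix length "
            f"{scale.l_min}; no segments predicted",
            stacklevel=2,
        )
        return []
    windows = _candidate_windows(record, scale, length_correction)
    if not all_minima:
        windows = [w for w in windows if w.dg_app <= threshold_dg]
    return _greedy_select(windows)


def best_window_after(
    record: ProteinRecord,
    scale: HydrophobicityScale,
    min_start: int,
    length_correction: bool = False,
    exclude: list[SegmentScore] | None = None,
) -> SegmentScore | None:
    """Best (lowest-ΔG) window starting at or after ``min_start`` that does
    not overlap any segment in ``exclude``; ``None`` when no window fits.

    This is the sub-threshold re-query used to call weakly hydrophobic final
    TMDs downstream of a twin-arginine motif.
    """
    if min_start < 1 or min_start + scale.l_min - 1 > len(record.seq):
        return None
    windows = _candidate_windows(record, scale, length_correction, region_start=min_start)
    if exclude:
        windows = [w for w in windows if not any(w.overlaps(s) for s in exclude)]
    if not windows:
        return None
    return min(windows, key=lambda w: (w.dg_app, w.start, w.length))


@dataclass(frozen=True)
class VariantScore:
    """What-if rescoring of a span after residue substitutions.

    ``delta = dg_wildtype - dg_variant``: positive means the variant is more
    insertion-favourable.  Because the cited ΔG tables do not state whether
    the helix span was re-predicted after substitution, both the same-span
    rescoring (``dg_variant``) and a re-scanned best window over the mutated
    sequence (``dg_variant_rescanned`` over ``rescanned_span``) are reported.
    """

    substitutions: tuple[tuple[int, str], ...]
    span: tuple[int, int]
    dg_wildtype: float
    dg_variant: float
    delta: float
    dg_variant_rescanned: float
    rescanned_span: tuple[int, int]


def apply_substitutions(
    record: ProteinRecord, substitutions: list[tuple[int, str]]
) -> ProteinRecord:
    seq = list(record.seq)
    for pos, new in substitutions:
        new = new.upper()
        if not 1 <= pos <= len(seq):
            raise SpanError(
                f"{record.id}: substitution position {pos} outside sequence"
            )
        if new not in STANDARD_AA:
            raise ScaleError(f"{record.id}: invalid replacement residue {new!r}")
        seq[pos - 1] = new
    return ProteinRecord(
        id=record.id, seq="".join(seq), description=record.description
    )


def variant_dg(
    record: ProteinRecord,
    substitutions: list[tuple[int, str]],
    start: int,
    end: int,
    scale: HydrophobicityScale,
    length_correction: bool = False,
) -> VariantScore:
    """Rescore a span after substitutions (e.g. leucine what-ifs)."""
    variant = apply_substitutions(record, substitutions)
    wt = segment_dg(record, start, end, scale, length_correction)
    var = segment_dg(variant, start, end, scale, length_correction)
    # re-scan: best window of the mutated sequence overlapping the span
    lo = max(1, start - scale.l_max + 1)
    windows = [
        w
        for w in _candidate_windows(variant, scale, length_correction, region_start=lo)
        if w.start <= end and w.end >= start
    ]
    best = min(windows, key=lambda w: (w.dg_app, w.start, w.length)) if windows else var
    return VariantScore(
        substitutions=tuple((p, r.upper()) for p, r in substitutions),
        span=(start, end),
        dg_wildtype=wt.dg_app,
        dg_variant=var.dg_app,
        delta=wt.dg_app - var.dg_app,
        dg_variant_rescanned=best.dg_app,
        rescanned_span=(best.start, best.end),
    )


def parse_substitution(text: str) -> tuple[int, str, str]:
    """Parse mutation shorthand like ``S179L`` -> (179, 'S', 'L')."""
    text = text.strip()
    ref, new = text[:1].upper(), text[-1:].upper()
    if (
        len(text) < 3
        or not text[1:-1].isdigit()
        or ref not in STANDARD_AA
        or new not in STANDARD_AA
    ):
        raise SpanError(f"cannot parse substitution {text!r} (expected e.g. S179L)")
    return int(text[1:-1]), ref, new
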