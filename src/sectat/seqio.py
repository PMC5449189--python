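"""Input/output: FASTA, imported topology predictions, TSV/GFF3 results.

All coordinates handled by this package are 1-based and inclusive on both
ends, matching the residue numbering conventions of the membrane-protein
literature (e.g. a helix spanning "aa 58-80" contains residues 58 and 80).
"""

from __future__ import annotations

import math
import re
import urllib.request
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from sectat.errors import AlphabetError, FastaError, SectatError, TopologyFormatError

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
#: residues accepted in a :class:`ProteinRecord` (the 20 standard + ambiguity X)
ACCEPTED_AA = STANDARD_AA | {"X"}


def _clean_sequence(raw: str, record_id: str) -> str:
    """Uppercase, strip a terminal stop, map U->C, reject anything else.

    'X' is kept (it is scored with a configurable contribution and flagged
    downstream): a genome-scale screen must not silently drop records with
    ambiguous residues.  B/Z/J and other letters are rejected with the
    offending 1-based position because they make the free-energy score
    meaningless.
    """
    seq = raw.strip().upper()
    if seq.endswith("*"):
        seq = seq[:-1]
    seq = seq.replace("U", "C")  # selenocysteine scored as cysteine
    for i, ch in enumerate(seq, start=1):
        if ch not in ACCEPTED_AA:
            raise AlphabetError(
                f"record {record_id!r}: illegal residue {ch!r} at position {i}"
            )
    if not seq:
        raise FastaError(f"record {record_id!r}: empty sequence")
    return seq


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with 1-based residue coordinates.

    Attributes
    ----------
    id : str
        Accession or identifier (text up to the first whitespace of the
        FASTA header).
    seq : str
        Uppercase amino-acid string over the 20-letter alphabet plus X.
    description : str
        Free text after the first whitespace of the header.
    """

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", _clean_sequence(self.seq, self.id))

    def __len__(self) -> int:
        return len(self.seq)

    def residue(self, pos: int) -> str:
        """Residue at 1-based position ``pos``."""
        if not 1 <= pos <= len(self.seq):
            raise SectatError(
                f"position {pos} outside sequence {self.id!r} (length {len(self.seq)})"
            )
        return self.seq[pos - 1]

    @property
    def has_x(self) -> bool:
        return "X" in self.seq


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a (wrapped or unwrapped) protein FASTA file.

    Raises on empty files, duplicate identifiers and illegal residues; a
    terminal ``*`` stop is stripped.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinRecord(id=rec.id, seq=str(rec.seq), description=rec.description[len(rec.id):].strip()))
        seen[rec.id] = seen.get(rec.id, 0) + 1
    if not records:
        raise FastaError(f"{path}: no FASTA records found")
    dups = sorted(i for i, n in seen.items() if n > 1)
    if dups:
        raise FastaError(f"{path}: duplicate record ids: {', '.join(dups)}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(r.seq), id=r.id, description=r.description) for r in records
    ]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Imported topology predictions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImportedTopology:
    """A topology prediction imported from an external predictor.

    ``segments`` are 1-based inclusive helix spans, strictly increasing and
    non-overlapping; loops alternate sides starting from
    ``orientation_of_first_loop``.  ``n_in_probability`` is the predictor's
    whole-protein probability that the N terminus is cytoplasmic, when the
    input carries one (the classic short output format does not).
    """

    protein_id: str
    n_helices: int
    segments: tuple[tuple[int, int], ...]
    orientation_of_first_loop: str  # "inside" | "outside"
    n_in_probability: float | None = None

    def __post_init__(self) -> None:
        if self.orientation_of_first_loop not in ("inside", "outside"):
            raise TopologyFormatError(
                f"{self.protein_id}: first-loop side must be 'inside' or 'outside'"
            )
        if self.n_helices != len(self.segments):
            raise TopologyFormatError(
                f"{self.protein_id}: PredHel={self.n_helices} but "
                f"{len(self.segments)} helix spans decoded"
            )
        prev_end = 0
        for start, end in self.segments:
            if not (0 < start <= end):
                raise TopologyFormatError(
                    f"{self.protein_id}: bad helix span {start}-{end}"
                )
            if start <= prev_end:
                raise TopologyFormatError(
                    f"{self.protein_id}: helix spans overlap or are out of order"
                )
            prev_end = end
        p = self.n_in_probability
        if p is not None and not (0.0 <= p <= 1.0):
            raise TopologyFormatError(
                f"{self.protein_id}: N-in probability {p} outside [0, 1]"
            )


_TOPO_RE = re.compile(r"(\d+)-(\d+)([io])")


def _decode_topology_string(topo: str, protein_id: str) -> tuple[str, tuple[tuple[int, int], ...]]:
    """Decode ``i10-32o40-62i``-style topology grammar."""
    if not topo or topo[0] not in "io":
        raise TopologyFormatError(
            f"{protein_id}: topology string must start with 'i' or 'o': {topo!r}"
        )
    first = "inside" if topo[0] == "i" else "outside"
    rest = topo[1:]
    segments: list[tuple[int, int]] = []
    pos = 0
    expected = "o" if topo[0] == "i" else "i"
    for m in _TOPO_RE.finditer(rest):
        if m.start() != pos:
            raise TopologyFormatError(
                f"{protein_id}: malformed topology string {topo!r}"
            )
        if m.group(3) != expected:
            raise TopologyFormatError(
                f"{protein_id}: loops do not alternate in {topo!r}"
            )
        segments.append((int(m.group(1)), int(m.group(2))))
        expected = "i" if expected == "o" else "o"
        pos = m.end()
    if pos != len(rest):
        raise TopologyFormatError(f"{protein_id}: malformed topology string {topo!r}")
    return first, tuple(segments)


def encode_topology_string(
    segments: Sequence[tuple[int, int]], first_loop: str
) -> str:
    """Inverse of the topology-string decoder (used for round-trip tests and
    for emitting synthetic import files)."""
    side = "i" if first_loop == "inside" else "o"
    out = [side]
    for start, end in segments:
        side = "o" if side == "i" else "i"
        out.append(f"{start}-{end}{side}")
    return "".join(out)


def read_tmhmm_short(path: str | Path) -> list[ImportedTopology]:
    """Parse short-format output lines from the TMHMM topology predictor.

    Expected tokens per line include ``PredHel=<n>`` and ``Topology=<string>``;
    an optional ``ProbNin=<p>`` (or ``Nin=<p>``) token supplies the N-in
    probability when the producer recorded one.
    """
    path = Path(path)
    out: list[ImportedTopology] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            kv = {}
            for tok in fields[1:]:
                if "=" in tok:
                    key, _, val = tok.partition("=")
                    kv[key] = val
            if "PredHel" not in kv or "Topology" not in kv:
                raise TopologyFormatError(
                    f"{path}:{lineno}: line lacks PredHel=/Topology= fields"
                )
            try:
                n_hel = int(kv["PredHel"])
            except ValueError as exc:
                raise TopologyFormatError(
                    f"{path}:{lineno}: bad PredHel value {kv['PredHel']!r}"
                ) from exc
            prob: float | None = None
            for key in ("ProbNin", "Nin"):
                if key in kv:
                    prob = float(kv[key])
            try:
                first, segments = _decode_topology_string(kv["Topology"], fields[0])
                out.append(
                    ImportedTopology(
                        protein_id=fields[0],
                        n_helices=n_hel,
                        segments=segments,
                        orientation_of_first_loop=first,
                        n_in_probability=prob,
                    )
                )
            except TopologyFormatError as exc:
                raise TopologyFormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def format_tmhmm_short(
    protein_id: str,
    seq_len: int,
    segments: Sequence[tuple[int, int]],
    first_loop: str,
    n_in_probability: float | None = None,
) -> str:
    """Render one TMHMM-style short line (the importer's inverse)."""
    topo = encode_topology_string(segments, first_loop)
    line = f"{protein_id}\tlen={seq_len}\tPredHel={len(segments)}\tTopology={topo}"
    if n_in_probability is not None:
        line += f"\tProbNin={n_in_probability:.3f}"
    return line


def read_topology_strings(path: str | Path) -> list[ImportedTopology]:
    """Read per-residue topology strings: ``id<TAB>iiiMMMMooo...``.

    ``M`` marks membrane-spanning residues; ``i``/``o`` mark inside/outside
    loops, which must alternate between consecutive helices.
    """
    path = Path(path)
    out: list[ImportedTopology] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            try:
                pid, topo = line.split("\t")
            except ValueError as exc:
                raise TopologyFormatError(
                    f"{path}:{lineno}: expected 'id<TAB>topology-string'"
                ) from exc
            bad = set(topo) - set("ioM")
            if bad or topo[0] not in "io":
                raise TopologyFormatError(
                    f"{path}:{lineno}: per-residue string must be over i/o/M and "
                    "start with i or o"
                )
            # runs of identical characters, with 1-based coordinates
            runs: list[tuple[str, int, int]] = []
            for i, ch in enumerate(topo, start=1):
                if runs and runs[-1][0] == ch:
                    runs[-1] = (ch, runs[-1][1], i)
                else:
                    runs.append((ch, i, i))
            segments = [(s, e) for ch, s, e in runs if ch == "M"]
            loops = [ch for ch, _, _ in runs if ch != "M"]
            for a, b in zip(runs, runs[1:]):
                if a[0] != "M" and b[0] != "M":
                    raise TopologyFormatError(
                        f"{path}:{lineno}: loop switches side without a helix"
                    )
            for a, b in zip(loops, loops[1:]):
                if a == b:
                    raise TopologyFormatError(
                        f"{path}:{lineno}: loops do not alternate sides"
                    )
            first = "inside" if loops[0] == "i" else "outside"
            out.append(
                ImportedTopology(
                    protein_id=pid,
                    n_helices=len(segments),
                    segments=tuple(segments),
                    orientation_of_first_loop=first,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Results output
# ---------------------------------------------------------------------------

#: stable column order of the consolidated results table
RESULT_COLUMNS = [
    "id",
    "class",
    "n_before",
    "n_after",
    "rr_pos",
    "gap",
    "n_in_score",
    "orientation",
    "source",
    "final_tmd_span",
    "final_tmd_dg",
    "first_tmd_dg",
    "dg_gap",
    "loop_len",
    "cterm_basic_count",
    "flags",
    "reason",
]


def write_results(
    rows: Iterable[dict],
    path: str | Path,
    format: str = "tsv",
    header_lines: Sequence[str] = (),
) -> None:
    """Write screen/feature rows as TSV, or TM segments + RR motifs as GFF3.

    ``rows`` are plain mappings; for TSV the documented ``RESULT_COLUMNS``
    are emitted (missing keys become empty cells).  For GFF3 each row must
    carry ``id``, ``segments`` (objects with ``start``/``end``/``dg_app``)
    and ``motifs`` (objects with ``pos``/``consensus_score``); coordinates
    are written 1-based inclusive, per the GFF3 convention.
    """
    path = Path(path)
    if format == "tsv":
        table = pd.DataFrame(
            [{c: r.get(c, "") for c in RESULT_COLUMNS} for r in rows],
            columns=RESULT_COLUMNS,
        )
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            table.to_csv(fh, sep="\t", index=False)
    elif format == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for line in header_lines:
                fh.write(f"# {line}\n")
            for r in rows:
                pid = r["id"]
                for k, seg in enumerate(r.get("segments", []), start=1):
                    score = (
                        f"{seg.dg_app:.3f}"
                        if seg.dg_app is not None and not math.isnan(seg.dg_app)
                        else "."
                    )
                    fh.write(
                        f"{pid}\tsectat\ttransmembrane_helix\t{seg.start}\t{seg.end}"
                        f"\t{score}\t.\t.\tID={pid}.tmd{k}\n"
                    )
                for k, motif in enumerate(r.get("motifs", []), start=1):
                    fh.write(
                        f"{pid}\tsectat\tsequence_motif\t{motif.pos}\t{motif.pos + 1}"
                        f"\t{motif.consensus_score}\t.\t.\t"
                        f"ID={pid}.rr{k};Name=twin_arginine\n"
                    )
    else:
        raise SectatError(f"unknown results format {format!r} (tsv or gff3)")


def read_results_tsv(path: str | Path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_results` (round-trip helper)."""
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# Optional single-accession retrieval
# ---------------------------------------------------------------------------

UNIPROT_FASTA_URL = "https://rest.uniprot.org/uniprotkb/{accession}.fasta"


def fetch_uniprot(
    accession: str,
    cache_dir: str | Path | None = None,
    timeout: float = 30.0,
) -> ProteinRecord:
    """Fetch a single UniProt accession as a :class:`ProteinRecord`.

    Looks for ``<cache_dir>/<accession>.fasta`` first so that validation
    against named reference proteins can run without network access; on a
    cache miss the UniProt REST endpoint is queried and, when a cache
    directory was given, the reply is stored there.
    """
    if cache_dir is not None:
        cached = Path(cache_dir) / f"{accession}.fasta"
        if cached.exists():
            return read_fasta(cached)[0]
    url = UNIPROT_FASTA_URL.format(accession=accession)
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            text = resp.read().decode()
    except Exception as exc:  # noqa: BLE001 - network failure modes are many
        raise SectatError(
            f"could not fetch {accession} from UniProt ({exc}); place "
            f"{accession}.fasta in a cache directory to work offline"
        ) from exc
    if cache_dir is not None:
        Path(cache_dir).mkdir(parents=True, exist_ok=True)
        (Path(cache_dir) / f"{accession}.fasta").write_text(text)
    lines = text.splitlines()
    if not lines or not lines[0].startswith(">"):
        raise FastaError(f"UniProt reply for {accession} is not FASTA")
    header = lines[0][1:]
    pid = header.split()[0]
    return ProteinRecord(
        id=pid, seq="".join(lines[1:]), description=header[len(pid):].strip()
    )
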