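"""Sequence and annotation I/O.

Reads FASTA (via Biopython) and the four-line family record format used for
register-annotated coiled-coil training data, and writes per-residue
prediction tables as TSV.

The four-line record format is, per sequence::

    name line            (free text identifier)
    descriptor line      (controlled vocabulary, e.g. "long parallel homo dimer")
    sequence line        (one-letter amino acids)
    register line        (heptad letters a-g under annotated coil residues,
                          '-', '.' or space elsewhere)

Coordinates are 0-based half-open internally and 1-based in printed output.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, TextIO

from Bio import SeqIO

from .model_core import HEPTADS, OligomerClass, next_heptad

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
#: ambiguous / non-standard residue codes folded to X
_AMBIGUOUS = {"B": "X", "Z": "X", "J": "X", "U": "X", "O": "X", "*": "X"}
_VALID_RE = re.compile(f"^[{CANONICAL_AA}X]+$")

#: descriptor tokens recognized on the second line of a family record
DESCRIPTOR_VOCABULARY = frozenset(
    {
        "long", "short", "parallel", "antiparallel", "homo", "hetero",
        "dimer", "trimer", "tetramer", "coiled", "coil",
    }
)

_REGISTER_GAP = " .-"


class SequenceFormatError(ValueError):
    """Malformed FASTA or family-record input."""


class RegisterError(SequenceFormatError):
    """Heptad register line inconsistent with the sequence it annotates."""


def normalize_residues(raw: str) -> str:
    """Uppercase and fold non-standard residue codes to X.

    Raises :class:`SequenceFormatError` on characters outside the amino-acid
    alphabet.
    """
    seq = raw.strip().upper()
    seq = "".join(_AMBIGUOUS.get(c, c) for c in seq)
    if not seq:
        raise SequenceFormatError("empty sequence")
    if not _VALID_RE.match(seq):
        bad = sorted(set(seq) - set(CANONICAL_AA + "X"))
        raise SequenceFormatError(f"illegal residue characters: {bad}")
    return seq


@dataclass(frozen=True)
class ProteinSequence:
    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", normalize_residues(self.residues))

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class CoilAnnotation:
    """A contiguous annotated coil: [start, end) with its aligned register."""

    start: int
    end: int
    register: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("bad annotation interval")
        if len(self.register) != self.end - self.start:
            raise RegisterError("register length does not match interval")
        validate_register_continuity(self.register)

    def __len__(self) -> int:
        return self.end - self.start


def validate_register_continuity(register: str) -> None:
    """Require the register to advance cyclically a->b->...->g->a."""
    for c in register:
        if c not in HEPTADS:
            raise RegisterError(f"bad register letter {c!r}")
    for prev, cur in zip(register, register[1:]):
        if cur != next_heptad(prev):
            raise RegisterError(f"register discontinuity {prev!r}->{cur!r}")


@dataclass
class NpsRecord:
    """One annotated training sequence from a family file."""

    name: str
    descriptors: frozenset[str]
    sequence: ProteinSequence
    annotations: list[CoilAnnotation]
    oligomer: OligomerClass | str  # "tetramer" kept as a tag, never trained on
    family: str = ""


@dataclass(frozen=True)
class PredictionRow:
    """Per-residue output: register call and posterior oligomer probabilities."""

    position: int  # 1-based
    residue: str
    best_register: str  # a-g, or '-' when the coil posterior is weak
    p_dimer: float
    p_trimer: float

    @property
    def p_coil(self) -> float:
        return self.p_dimer + self.p_trimer


def read_fasta(source: TextIO | str) -> list[ProteinSequence]:
    """Read a FASTA stream into normalized :class:`ProteinSequence` objects.

    Order is preserved; duplicate ids, empty input and illegal residue
    characters are errors.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    seqs: list[ProteinSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(source, "fasta"):
        if rec.id in seen:
            raise SequenceFormatError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seqs.append(ProteinSequence(rec.id, str(rec.seq)))
    if not seqs:
        raise SequenceFormatError("no sequences found in FASTA input")
    return seqs


def write_fasta(seqs: Iterable[ProteinSequence], sink: TextIO) -> None:
    for s in seqs:
        sink.write(f">{s.id}\n{s.residues}\n")


def _oligomer_from_descriptors(tokens: frozenset[str]) -> OligomerClass | str:
    states = tokens & {"dimer", "trimer", "tetramer"}
    if len(states) != 1:
        raise SequenceFormatError(
            f"descriptor line must name exactly one oligomer state, got {sorted(states)}"
        )
    (state,) = states
    if state == "tetramer":
        return "tetramer"
    return OligomerClass(state)


def _annotations_from_register_line(seq: str, reg_line: str) -> list[CoilAnnotation]:
    reg_line = reg_line.rstrip("\n")
    if len(reg_line.rstrip(_REGISTER_GAP)) > len(seq):
        raise RegisterError("register line longer than sequence line")
    reg_line = reg_line.ljust(len(seq))
    annotations: list[CoilAnnotation] = []
    i = 0
    while i < len(seq):
        if reg_line[i] in _REGISTER_GAP:
            i += 1
            continue
        j = i
        while j < len(seq) and reg_line[j] not in _REGISTER_GAP:
            j += 1
        annotations.append(CoilAnnotation(i, j, reg_line[i:j]))
        i = j
    return annotations


def parse_nps_family_file(
    source: TextIO | str,
    family_name: str,
    *,
    strict: bool = True,
    vocabulary: frozenset[str] = DESCRIPTOR_VOCABULARY,
) -> list[NpsRecord]:
    """Parse a four-line-per-sequence family file.

    With ``strict=True`` any malformed record raises; otherwise malformed
    records are skipped with a warning collected into the return path being
    simply shorter.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    lines = [ln.rstrip("\n") for ln in source]
    while lines and not lines[-1].strip():
        lines.pop()
    if len(lines) % 4 != 0:
        raise SequenceFormatError(
            f"family file line count {len(lines)} is not a multiple of 4"
        )
    records: list[NpsRecord] = []
    for off in range(0, len(lines), 4):
        name, desc_line, seq_line, reg_line = lines[off : off + 4]
        try:
            tokens = frozenset(desc_line.lower().split())
            unknown = tokens - vocabulary
            if unknown:
                raise SequenceFormatError(
                    f"unknown descriptor tokens {sorted(unknown)}"
                )
            seq = ProteinSequence(name.lstrip(">").strip() or f"record{off // 4}", seq_line)
            annotations = _annotations_from_register_line(seq.residues, reg_line)
            records.append(
                NpsRecord(
                    name=seq.id,
                    descriptors=tokens,
                    sequence=seq,
                    annotations=annotations,
                    oligomer=_oligomer_from_descriptors(tokens),
                    family=family_name,
                )
            )
        except SequenceFormatError:
            if strict:
                raise
    return records


def write_nps_family_file(records: Iterable[NpsRecord], sink: TextIO) -> None:
    """Inverse of :func:`parse_nps_family_file` (register gaps written as '-')."""
    for rec in records:
        reg = ["-"] * len(rec.sequence)
        for ann in rec.annotations:
            reg[ann.start : ann.end] = list(ann.register)
        sink.write(rec.name + "\n")
        sink.write(" ".join(sorted(rec.descriptors)) + "\n")
        sink.write(rec.sequence.residues + "\n")
        sink.write("".join(reg) + "\n")


_PREDICTION_HEADER = "position\tresidue\tbest_register\tp_dimer\tp_trimer\tp_coil"


def write_predictions(rows: list[PredictionRow], sink: TextIO) -> None:
    """Write the per-residue prediction table as TSV (6 decimal places)."""
    if not rows:
        raise ValueError("no prediction rows to write")
    sink.write(_PREDICTION_HEADER + "\n")
    for r in rows:
        sink.write(
            f"{r.position}\t{r.residue}\t{r.best_register}\t"
            f"{r.p_dimer:.6f}\t{r.p_trimer:.6f}\t{r.p_coil:.6f}\n"
        )


def read_predictions(source: TextIO | str) -> list[PredictionRow]:
    if isinstance(source, str):
        source = io.StringIO(source)
    rows: list[PredictionRow] = []
    header = source.readline().rstrip("\n")
    if header != _PREDICTION_HEADER:
        raise SequenceFormatError("missing prediction table header")
    for ln in source:
        pos, res, reg, pd_, pt, pc = ln.rstrip("\n").split("\t")
        row = PredictionRow(int(pos), res, reg, float(pd_), float(pt))
        # each printed column carries up to 5e-7 rounding error
        if abs(row.p_coil - float(pc)) > 1.1e-6:
            raise SequenceFormatError("p_coil column inconsistent with p_dimer+p_trimer")
        rows.append(row)
    return rows
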