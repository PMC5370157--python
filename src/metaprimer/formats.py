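"""Readers and writers for the plain-text formats the pipeline touches.

Supported formats: FASTA and FASTQ reads, gapped aligned FASTA reference
databases, mothur-dialect taxonomy tables (``id<TAB>Rank1;Rank2;...;``) and a
simple primer list (``name  sequence  orientation`` per line, whitespace
separated, with ``(A/C)`` alternatives and/or IUPAC codes in the sequence).

All sequences are uppercased and RNA ``U`` is normalised to ``T`` on read.
Both ``-`` and ``.`` are accepted as gap characters in aligned input;
internally only ``-`` is used (the ``.`` symbol has a different meaning in
match-type strings).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "IUPAC",
    "SeqRecord",
    "TaxonomyRecord",
    "PrimerInput",
    "read_sequences",
    "read_alignment",
    "read_taxonomy",
    "parse_primers",
    "write_fasta",
    "write_taxonomy",
]

#: IUPAC nucleotide codes mapped to the set of bases each stands for.
IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_VALID_SEQ = re.compile(r"^[ACGTRYSWKMBDHVN]+$")


class FormatError(ValueError):
    """Raised for any malformed on-disk input."""


@dataclass(frozen=True)
class SeqRecord:
    """A named nucleotide sequence, optionally with per-base qualities.

    Qualities are parsed from FASTQ but never used by the method itself;
    they are carried only so round trips do not lose information.
    """

    id: str
    seq: str
    qual: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SeqRecord id must be non-empty")
        if not self.seq:
            raise ValueError(f"SeqRecord {self.id!r}: empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(f"SeqRecord {self.id!r}: quality length mismatch")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class TaxonomyRecord:
    """A sequence id with its ordered lineage, domain first."""

    seq_id: str
    lineage: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.lineage:
            raise ValueError(f"taxonomy for {self.seq_id!r} has empty lineage")
        if any(not r for r in self.lineage):
            raise ValueError(f"taxonomy for {self.seq_id!r} has an empty rank label")


@dataclass(frozen=True)
class PrimerInput:
    """A named, oriented, possibly degenerate primer as written by the user."""

    name: str
    raw_seq: str
    orientation: str  # "F" or "R"

    def __post_init__(self) -> None:
        if self.orientation not in ("F", "R"):
            raise ValueError(f"primer {self.name!r}: orientation must be F or R")


def _normalise(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_sequences(path: str | Path, format: str | None = None) -> list[SeqRecord]:
    """Read a FASTA or FASTQ file into a list of :class:`SeqRecord`.

    The format is inferred from the extension when not given
    (``.fastq``/``.fq`` -> fastq, otherwise fasta).  Record order is
    preserved; duplicate ids and invalid base symbols are errors.
    """
    path = Path(path)
    if format is None:
        format = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    if format not in ("fasta", "fastq"):
        raise FormatError(f"unknown sequence format {format!r}")
    records: list[SeqRecord] = []
    seen: set[str] = set()
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), format)):
            seq = _normalise(str(rec.seq))
            if not seq or not _VALID_SEQ.match(seq):
                raise FormatError(
                    f"{path}: record {i} ({rec.id!r}) has invalid or empty sequence"
                )
            if rec.id in seen:
                raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            qual = None
            if "phred_quality" in rec.letter_annotations:
                qual = tuple(rec.letter_annotations["phred_quality"])
            records.append(SeqRecord(rec.id, seq, qual))
    except FormatError:
        raise
    except ValueError as exc:  # Biopython parse failure
        raise FormatError(f"{path}: record {len(records)}: {exc}") from exc
    return records


def read_alignment(path: str | Path) -> list[tuple[str, str]]:
    """Read a gapped aligned-FASTA file as ``(id, gapped_seq)`` rows.

    ``-`` and ``.`` are both accepted as gaps ('.' is rewritten to '-').
    All rows must share one length; otherwise the offending id is reported.
    """
    path = Path(path)
    rows: list[tuple[str, str]] = []
    width: int | None = None
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        gapped = _normalise(str(rec.seq)).replace(".", "-")
        ungapped = gapped.replace("-", "")
        if ungapped and not _VALID_SEQ.match(ungapped):
            raise FormatError(f"{path}: row {rec.id!r} has invalid base symbols")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate row id {rec.id!r}")
        seen.add(rec.id)
        if width is None:
            width = len(gapped)
        elif len(gapped) != width:
            raise FormatError(
                f"{path}: row {rec.id!r} has length {len(gapped)}, expected {width}"
            )
        rows.append((rec.id, gapped))
    if not rows:
        raise FormatError(f"{path}: empty alignment")
    return rows


_BOOT = re.compile(r"\(\d+(?:\.\d+)?\)")


def read_taxonomy(path: str | Path) -> list[TaxonomyRecord]:
    """Read a mothur-style taxonomy table: ``id<TAB>Rank1;Rank2;...;``.

    Per-rank bootstrap confidences like ``Bacteria(100)`` are stripped;
    a trailing ``;`` is allowed; blank lines are skipped.
    """
    path = Path(path)
    out: list[TaxonomyRecord] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split(None, 1)
            if len(parts) != 2 or not parts[1].strip():
                raise FormatError(f"{path}:{ln}: expected 'id<TAB>lineage'")
            seq_id, lineage_str = parts[0].strip(), parts[1].strip()
            lineage_str = _BOOT.sub("", lineage_str)
            ranks = tuple(r.strip() for r in lineage_str.split(";") if r.strip())
            if not ranks:
                raise FormatError(f"{path}:{ln}: id {seq_id!r} has no lineage")
            out.append(TaxonomyRecord(seq_id, ranks))
    return out


_ALT = re.compile(r"\(([^()]*)\)")


def parse_primer_positions(raw_seq: str) -> list[list[str]]:
    """Split a primer written with ``(A/C)`` alternatives and IUPAC codes into
    per-position alternative lists (written order for parenthesised groups,
    alphabetical for IUPAC codes)."""
    positions: list[list[str]] = []
    i = 0
    s = raw_seq.strip().upper().replace("U", "T")
    if not s:
        raise FormatError("empty primer sequence")
    while i < len(s):
        ch = s[i]
        if ch == "(":
            m = _ALT.match(s, i)
            if not m:
                raise FormatError(f"unbalanced parenthesis in primer {raw_seq!r}")
            alts = [a.strip() for a in m.group(1).split("/")]
            if not alts or any(not a for a in alts):
                raise FormatError(f"empty alternative in primer {raw_seq!r}")
            for a in alts:
                if not _VALID_SEQ.match(a):
                    raise FormatError(f"invalid base in alternative {a!r} of {raw_seq!r}")
            positions.append(alts)
            i = m.end()
        elif ch in IUPAC:
            positions.append(sorted(IUPAC[ch]))
            i += 1
        else:
            raise FormatError(f"invalid base symbol {ch!r} in primer {raw_seq!r}")
    return positions


def parse_primers(path: str | Path) -> list[PrimerInput]:
    """Read a primer list file: one ``name sequence orientation`` per line."""
    path = Path(path)
    out: list[PrimerInput] = []
    seen: set[str] = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise FormatError(
                    f"{path}:{ln}: expected 'name sequence orientation', got {line!r}"
                )
            name, raw_seq, orientation = parts
            if name in seen:
                raise FormatError(f"{path}:{ln}: duplicate primer name {name!r}")
            seen.add(name)
            try:
                positions = parse_primer_positions(raw_seq)
            except FormatError as exc:
                raise FormatError(f"{path}:{ln}: {exc}") from exc
            if not positions:
                raise FormatError(f"{path}:{ln}: primer {name!r} parses to nothing")
            if orientation not in ("F", "R"):
                raise FormatError(f"{path}:{ln}: orientation must be F or R")
            out.append(PrimerInput(name, raw_seq.strip().upper().replace("U", "T"), orientation))
    return out


def write_fasta(records: Iterable[SeqRecord | tuple[str, str]], path: str | Path,
                width: int = 70) -> None:
    """Write records (SeqRecord or (id, seq) pairs) as FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            rid, seq = (rec.id, rec.seq) if isinstance(rec, SeqRecord) else rec
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_taxonomy(records: Iterable[TaxonomyRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{rec.seq_id}\t{';'.join(rec.lineage)};\n")
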