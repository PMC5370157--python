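"""Reference-database tooling.

Holds the gapped reference alignment shared by all pipeline stages, builds the
representative set used for prescreening, maps an anchor (marker) sequence's
ungapped positions to alignment columns, and extends an ungapped reference
database with terminal primer regions (the 8F / 1492R regions commonly absent
from curated SSU databases because most entries were amplified with that pair).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from metaprimer.formats import SeqRecord, TaxonomyRecord, read_alignment, read_taxonomy
from metaprimer.pairwise import global_identity

__all__ = [
    "ReferenceAlignment",
    "AnchorMap",
    "build_representatives",
    "map_anchor",
    "extend_database",
    "DEFAULT_FWD_EXTENSION",
    "DEFAULT_REV_EXTENSION",
]

# Standard bacterial 16S terminal primers 8F and 1492R, used as default
# database extensions (overridable).
DEFAULT_FWD_EXTENSION = "AGAGTTTGATCCTGGCTCAG"
DEFAULT_REV_EXTENSION = "GGTTACCTTGTTACGACTT"

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReferenceAlignment:
    """Gapped reference sequences sharing one fixed column space.

    ``rows`` keeps file order; every row id except the appended anchor must
    have a taxonomy entry when a taxonomy is attached.
    """

    rows: list[tuple[str, str]]
    width: int
    taxonomy: dict[str, TaxonomyRecord] = field(default_factory=dict)
    anchor_id: str | None = None
    _row_map: dict[str, str] = field(default_factory=dict, repr=False)
    _ungapped: dict[str, str] = field(default_factory=dict, repr=False)
    _kmer_cache: dict[int, dict[str, frozenset]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for rid, gapped in self.rows:
            if len(gapped) != self.width:
                raise ValueError(f"row {rid!r} has length {len(gapped)} != width {self.width}")
        self._row_map = dict(self.rows)
        if len(self._row_map) != len(self.rows):
            raise ValueError("duplicate row ids in alignment")
        if self.anchor_id is not None and self.anchor_id not in self._row_map:
            raise ValueError(f"anchor id {self.anchor_id!r} not among alignment rows")
        if self.taxonomy:
            for rid, _ in self.rows:
                if rid != self.anchor_id and rid not in self.taxonomy:
                    raise ValueError(f"row {rid!r} has no taxonomy entry")

    @classmethod
    def load(cls, aln_path: str | Path, tax_path: str | Path | None = None,
             anchor_id: str | None = None) -> "ReferenceAlignment":
        rows = read_alignment(aln_path)
        taxonomy: dict[str, TaxonomyRecord] = {}
        if tax_path is not None:
            taxonomy = {t.seq_id: t for t in read_taxonomy(tax_path)}
        return cls(rows, len(rows[0][1]), taxonomy, anchor_id)

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def row(self, rid: str) -> str:
        return self._row_map[rid]

    def ungapped(self, rid: str) -> str:
        if rid not in self._ungapped:
            self._ungapped[rid] = self._row_map[rid].replace("-", "")
        return self._ungapped[rid]

    def template_ids(self) -> list[str]:
        """Row ids usable as alignment templates (all rows, anchor included)."""
        return self.ids

    def kmer_sets(self, k: int) -> dict[str, frozenset]:
        """Cached distinct-k-mer sets of each row's ungapped sequence."""
        if k not in self._kmer_cache:
            cache = {}
            for rid, _ in self.rows:
                seq = self.ungapped(rid)
                cache[rid] = frozenset(seq[i:i + k] for i in range(len(seq) - k + 1))
            self._kmer_cache[k] = cache
        return self._kmer_cache[k]


@dataclass(frozen=True)
class AnchorMap:
    """Bidirectional map between the anchor's ungapped positions (1-based)
    and alignment columns (1-based)."""

    cols: tuple[int, ...]  # cols[p-1] = alignment column of anchor position p
    pos_of_col: dict[int, int]

    def __post_init__(self) -> None:
        if not self.cols:
            raise ValueError("anchor map is empty")
        if any(b <= a for a, b in zip(self.cols, self.cols[1:])):
            raise ValueError("anchor columns not strictly increasing")

    def __len__(self) -> int:
        return len(self.cols)

    def col_of_pos(self, pos: int) -> int:
        if not 1 <= pos <= len(self.cols):
            raise KeyError(f"anchor position {pos} out of range 1..{len(self.cols)}")
        return self.cols[pos - 1]


def map_anchor(aln: ReferenceAlignment, anchor_id: str) -> AnchorMap:
    """Enumerate the anchor row's non-gap columns so every anchor base gets a
    unique alignment column."""
    if anchor_id not in aln._row_map:
        raise KeyError(f"anchor id {anchor_id!r} not found in alignment")
    gapped = aln.row(anchor_id)
    cols = tuple(c for c, ch in enumerate(gapped, start=1) if ch != "-")
    if not cols:
        raise ValueError(f"anchor row {anchor_id!r} is all gaps")
    pos_of_col = {c: p for p, c in enumerate(cols, start=1)}
    return AnchorMap(cols, pos_of_col)


def build_representatives(refs: list[SeqRecord], identity: float = 0.75) -> list[SeqRecord]:
    """Greedy incremental clustering of ungapped references at a global
    identity threshold; returns the representatives.

    Sequences are taken longest-first (ties by id).  A sequence joins the
    first existing representative with identity >= threshold, else becomes a
    new representative.  Representatives are returned in creation order.
    """
    if not 0 < identity <= 1:
        raise ValueError("identity must be in (0, 1]")
    ordered = sorted(refs, key=lambda r: (-len(r.seq), r.id))
    reps: list[SeqRecord] = []
    for rec in ordered:
        if "-" in rec.seq:
            raise ValueError(f"reference {rec.id!r} is gapped; ungapped input required")
        for rep in reps:
            if global_identity(rec.seq, rep.seq) >= identity:
                break
        else:
            reps.append(rec)
    return reps


def extend_database(refs: list[SeqRecord],
                    fwd_ext: str = DEFAULT_FWD_EXTENSION,
                    rev_ext: str = DEFAULT_REV_EXTENSION) -> list[SeqRecord]:
    """Attach ``fwd_ext`` to the 5' end and the reverse complement of
    ``rev_ext`` to the 3' end of every ungapped reference sequence."""
    if not fwd_ext or not rev_ext:
        raise ValueError("extension primers must be non-empty")
    fwd = fwd_ext.upper().replace("U", "T")
    rev_rc = _revcomp(rev_ext.upper().replace("U", "T"))
    return [SeqRecord(r.id, fwd + r.seq + rev_rc) for r in refs]
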