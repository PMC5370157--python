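"""Template-based alignment engine.

Three responsibilities:

* a 0–100 k-mer search score measuring how well a read matches its best
  reference template (used twice per read, forward and reverse-complement, to
  orient it and to attribute it to the SSU or LSU gene);
* read orientation and gene attribution against the SSU (and optionally LSU)
  reference databases, with an acceptance cutoff (30 recommended);
* NAST-style projection: a pairwise read-vs-template alignment is pushed
  through the template's gap pattern into the fixed column space of the
  reference multiple alignment, so coordinates are comparable across reads.
  Read insertions relative to the template that do not fit into available gap
  columns are recorded and omitted from the projected row, never fatal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from metaprimer.formats import SeqRecord
from metaprimer.pairwise import OP_DIAG, OP_LEFT, OP_UP, align_ops
from metaprimer.refdb import ReferenceAlignment

__all__ = ["OrientedRead", "ProjectedRead", "kmer_search", "orient_and_assign",
           "nast_project", "DEFAULT_SEARCH_K", "DEFAULT_SEARCH_CUTOFF"]

DEFAULT_SEARCH_K = 8
DEFAULT_SEARCH_CUTOFF = 30.0

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class OrientedRead:
    """A read plus its chosen strand, gene attribution and search scores.

    ``scores`` maps gene name -> (forward score, reverse score).  ``gene`` is
    ``None`` when no score reached the cutoff, in which case the read is not
    considered part of an rRNA gene and ``accepted`` is False.
    """

    read: SeqRecord
    strand: str  # '+' or '-'
    gene: str | None  # 'SSU' | 'LSU' | None
    scores: dict[str, tuple[float, float]]
    template_id: str | None
    accepted: bool

    @property
    def oriented_seq(self) -> str:
        return self.read.seq if self.strand == "+" else _revcomp(self.read.seq)


@dataclass(frozen=True)
class ProjectedRead:
    """A read projected into reference alignment columns.

    ``rejected`` holds insertions relative to the template that exceeded the
    gap columns available between template positions, as (1-based position in
    the oriented read, base).  Degapping ``gapped`` and re-inserting those
    bases at their recorded positions reproduces the oriented read exactly.
    """

    read_id: str
    gapped: str
    start_col: int  # 1-based, inclusive
    end_col: int
    template_id: str
    strand: str
    rejected: tuple[tuple[int, str], ...] = ()

    def reconstruct(self) -> str:
        bases = [ch for ch in self.gapped if ch != "-"]
        for pos, base in self.rejected:  # positions recorded ascending
            bases.insert(pos - 1, base)
        return "".join(bases)


def _query_kmers(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def kmer_search(query: str, templates: ReferenceAlignment,
                k: int = DEFAULT_SEARCH_K) -> tuple[str, float]:
    """Best template and search score for a query sequence.

    Score = 100 x (query's distinct k-mers found in the template's ungapped
    sequence) / (query's distinct k-mers).  Ties go to the smaller template
    id.
    """
    if len(query) < k:
        raise ValueError(f"query shorter than k={k}")
    qset = _query_kmers(query, k)
    tsets = templates.kmer_sets(k)
    best_id, best_score = None, -1.0
    for tid in sorted(tsets):
        score = 100.0 * len(qset & tsets[tid]) / len(qset)
        if score > best_score:
            best_id, best_score = tid, score
    return best_id, best_score


def orient_and_assign(read: SeqRecord, ssu: ReferenceAlignment,
                      lsu: ReferenceAlignment | None = None,
                      cutoff: float = DEFAULT_SEARCH_CUTOFF,
                      k: int = DEFAULT_SEARCH_K) -> OrientedRead:
    """Orient a read and attribute it to SSU (or LSU, when given).

    Computes the search score of the read and of its reverse complement
    against each database (two scores per gene; four in metatranscriptome
    mode).  The global maximum fixes strand, gene and template; the read is
    accepted only if that maximum reaches the cutoff.  Ties prefer SSU over
    LSU and '+' over '-'.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    rc = _revcomp(read.seq)
    genes = [("SSU", ssu)] + ([("LSU", lsu)] if lsu is not None else [])
    scores: dict[str, tuple[float, float]] = {}
    candidates = []  # (score, gene_rank, strand_rank, gene, strand, template)
    for rank, (gene, aln) in enumerate(genes):
        tid_f, sc_f = kmer_search(read.seq, aln, k)
        tid_r, sc_r = kmer_search(rc, aln, k)
        scores[gene] = (sc_f, sc_r)
        candidates.append((sc_f, rank, 0, gene, "+", tid_f))
        candidates.append((sc_r, rank, 1, gene, "-", tid_r))
    best = max(candidates, key=lambda c: (c[0], -c[1], -c[2]))
    score, _, _, gene, strand, template = best
    if score >= cutoff:
        return OrientedRead(read, strand, gene, scores, template, True)
    return OrientedRead(read, strand, None, scores, template, False)


def nast_project(oread: OrientedRead, templates: ReferenceAlignment) -> ProjectedRead:
    """Project an accepted, oriented read into the reference column space.

    The oriented read is aligned to its best template's ungapped sequence
    (free end gaps on the template side), then pushed through the template's
    gap pattern: read bases aligned to template bases land in those bases'
    columns; insertions fill gap columns between the flanking template
    positions (left-aligned after the previous placed base, right-aligned
    before the first); insertions that do not fit are recorded as rejected.
    """
    if not oread.accepted:
        raise ValueError(f"read {oread.read.id!r} was not accepted; cannot project")
    gapped_t = templates.row(oread.template_id)
    ungapped_t = templates.ungapped(oread.template_id)
    # 1-based alignment column of each template position
    tcols = [c for c, ch in enumerate(gapped_t, start=1) if ch != "-"]
    width = templates.width
    seq = oread.oriented_seq
    # Overlap alignment: template overhangs are free (a read is a fragment)
    # and read overhangs are free too (a read may straddle the gene boundary
    # and carry non-rRNA tails, which must not be smeared over the template).
    ops = align_ops(seq, ungapped_t, free_a_ends=True, free_b_ends=True)

    out = ["-"] * width
    rejected: list[tuple[int, str]] = []
    pending: list[tuple[int, str]] = []  # (1-based read pos, base) insertions
    prev_col = 0  # column of last consumed template position (0 = before start)
    i = j = 0  # read / template indices (0-based)

    def flush(next_col: int) -> None:
        """Place pending insertion bases into gap columns strictly between
        prev_col and next_col; overflow is rejected (keep the bases nearest
        the placed neighbour: first ones after a previous base, last ones
        before a following base)."""
        nonlocal pending
        if not pending:
            return
        avail = list(range(prev_col + 1, next_col))
        if prev_col == 0:
            # leading insertions: right-align against the first placed base
            keep = pending[-len(avail):] if avail else []
            drop = pending[:len(pending) - len(keep)]
            cols = avail[-len(keep):] if keep else []
        else:
            keep = pending[:len(avail)]
            drop = pending[len(keep):]
            cols = avail[:len(keep)]
        for (pos, base), col in zip(keep, cols):
            out[col - 1] = base
        rejected.extend(drop)
        pending = []

    for op in ops:
        if op == OP_DIAG:
            col = tcols[j]
            flush(col)
            out[col - 1] = seq[i]
            prev_col = col
            i += 1
            j += 1
        elif op == OP_UP:
            pending.append((i + 1, seq[i]))
            i += 1
        else:  # OP_LEFT: template consumed, read gapped (deletion or overhang)
            col = tcols[j]
            flush(col)
            prev_col = col
            j += 1
    flush(width + 1)
    rejected.sort()

    placed = [c + 1 for c, ch in enumerate(out) if ch != "-"]
    if not placed:
        raise ValueError(f"read {oread.read.id!r}: no base could be projected")
    return ProjectedRead(oread.read.id, "".join(out), placed[0], placed[-1],
                         oread.template_id, oread.strand, tuple(rejected))
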