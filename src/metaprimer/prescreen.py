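"""Cheap shared-k-mer similarity screen.

Reduces a shotgun metagenome to a draft set of rRNA-like reads before the main
program.  Only about 0.2% of metagenome reads derive from SSU rRNA genes, so a
fast filter against a small representative set pays for itself; the screen is
an internal k-mer filter rather than an external BLASTn dependency (HMM-based
tools can fill the same role).  Metatranscriptome and amplicon inputs skip
this stage entirely — rRNA already dominates them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from metaprimer.formats import SeqRecord

__all__ = ["ScreenHit", "screen_reads", "write_hits", "DEFAULT_K", "DEFAULT_MIN_SHARED"]

DEFAULT_K = 11
DEFAULT_MIN_SHARED = 0.10

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _kmers(seq: str, k: int) -> frozenset:
    return frozenset(seq[i:i + k] for i in range(len(seq) - k + 1))


@dataclass(frozen=True)
class ScreenHit:
    read_id: str
    rep_id: str
    strand: str  # '+' or '-'
    fraction: float


def screen_reads(reads: list[SeqRecord], representatives: list[SeqRecord],
                 k: int = DEFAULT_K, min_shared: float = DEFAULT_MIN_SHARED,
                 ) -> tuple[list[SeqRecord], list[ScreenHit]]:
    """Keep each read whose best shared-k-mer fraction against any
    representative, over either strand, reaches ``min_shared``.

    The fraction is |read k-mers ∩ representative k-mers| / |read k-mers|,
    using distinct k-mers.  Returns the kept reads (input order preserved) and
    one best-hit record per kept read.  Ties prefer the '+' strand, then the
    lexicographically first representative id.
    """
    if not representatives:
        raise ValueError("representative set is empty; screen undefined")
    if k < 6:
        raise ValueError("word size k must be >= 6")
    rep_sets = [(rep.id, _kmers(rep.seq, k)) for rep in
                sorted(representatives, key=lambda r: r.id)]
    kept: list[SeqRecord] = []
    hits: list[ScreenHit] = []
    for read in reads:
        best: ScreenHit | None = None
        for strand, seq in (("+", read.seq), ("-", _revcomp(read.seq))):
            q = _kmers(seq, k)
            if not q:
                continue
            for rep_id, rset in rep_sets:
                frac = len(q & rset) / len(q)
                if best is None or frac > best.fraction:
                    best = ScreenHit(read.id, rep_id, strand, frac)
        if best is not None and best.fraction >= min_shared:
            kept.append(read)
            hits.append(best)
    return kept, hits


def write_hits(hits: list[ScreenHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\trep_id\tstrand\tshared_fraction\n")
        for h in hits:
            fh.write(f"{h.read_id}\t{h.rep_id}\t{h.strand}\t{h.fraction:.4f}\n")
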