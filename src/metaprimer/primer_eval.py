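"""Degenerate primer expansion, anchoring and per-site match typing.

The evaluation is reference-anchored: every primer is located once on a
full-length anchor sequence co-aligned with the reads, giving it a fixed
alignment-column interval.  For each projected read, the binding site is the
read material in those columns, extracted with a few pad bases on each side
(to absorb base slips introduced by the multiple alignment), and re-aligned
against each non-degenerate variant of the primer.

Per primer position the match type is one of:

* ``=``   identical base;
* ``A``   (uppercase read base) substitution;
* ``a``   (lowercase read base(s)) insertion, written between the two primer
          positions it falls between;
* ``d``   deletion (primer base absent from the read);
* ``.``   missing fragment (primer position outside the read's span).

A site counts as covered ("matched degree") when it is complete and has no
mismatch, or exactly one mismatch that is not in the four primer positions
nearest the 3' end — a mismatch there disproportionately hurts PCR
efficiency.  Indels count one mismatch per event; an event counts in the
last-4 window if it touches any of those positions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
from Bio.Seq import Seq

from metaprimer.aligner import ProjectedRead
from metaprimer.formats import IUPAC, FormatError, PrimerInput, parse_primer_positions
from metaprimer.pairwise import OP_DIAG, OP_LEFT, OP_UP, align_ops
from metaprimer.refdb import AnchorMap

__all__ = ["PrimerSpec", "BindingSite", "SiteEvaluation", "expand_degenerate",
           "revcomp", "anchor_primer", "extract_binding_site", "evaluate_site",
           "select_best_variant", "evaluate_read_site", "counts_from_match_string",
           "position_mismatch_types", "DEFAULT_PAD", "DEFAULT_DROP_IDENTITY"]

DEFAULT_PAD = 4           # pad bases each side of the binding site (3..5)
DEFAULT_DROP_IDENTITY = 0.5  # sites re-aligning below this identity are dropped


def revcomp(seq: str) -> str:
    """Reverse complement with full IUPAC complementation (e.g. V <-> B)."""
    s = seq.upper().replace("U", "T")
    for ch in s:
        if ch not in IUPAC:
            raise FormatError(f"invalid base symbol {ch!r}")
    return str(Seq(s).reverse_complement())


def expand_degenerate(raw_seq: str) -> list[str]:
    """Cartesian expansion of a degenerate primer into non-degenerate
    variants, deterministic order, duplicates removed."""
    positions = parse_primer_positions(raw_seq)
    seen: set[str] = set()
    out: list[str] = []
    for combo in itertools.product(*positions):
        v = "".join(combo)
        if v not in seen:
            seen.add(v)
            out.append(v)
    return out


@dataclass(frozen=True)
class PrimerSpec:
    """An anchored primer: its variants and fixed anchor-position interval.

    ``anchor_cols[j]`` is the alignment column of primer base ``j`` in primer
    5'->3' order (descending columns for R-orientation primers, whose
    plus-strand footprint runs the other way).
    """

    input: PrimerInput
    variants: tuple[str, ...]
    anchor_interval: tuple[int, int]  # 1-based ungapped anchor positions
    anchor_cols: tuple[int, ...]

    @property
    def name(self) -> str:
        return self.input.name

    @property
    def orientation(self) -> str:
        return self.input.orientation

    def __len__(self) -> int:
        return len(self.anchor_cols)


def _best_hamming_placement(needle: str, haystack: str) -> tuple[int, int]:
    """(mismatches, 0-based start) of the best ungapped placement; leftmost on
    ties."""
    n, h = len(needle), len(haystack)
    if n > h:
        return n + 1, 0
    exact = haystack.find(needle)
    if exact >= 0:
        return 0, exact
    a = np.frombuffer(needle.encode(), dtype=np.uint8)
    b = np.frombuffer(haystack.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(b, n)
    mism = (windows != a).sum(axis=1)
    best = int(mism.argmin())
    return int(mism[best]), best


def anchor_primer(pinput: PrimerInput, anchor_seq: str, anchor_map: AnchorMap,
                  max_mismatch: int = 2) -> PrimerSpec:
    """Locate a primer on the anchor sequence and fix its column interval.

    For F primers the variants themselves are placed on the anchor; for R
    primers their reverse complements are (the plus-strand footprint).  At
    least one variant must place with <= ``max_mismatch`` mismatches.
    """
    variants = tuple(expand_degenerate(pinput.raw_seq))
    place_seqs = variants if pinput.orientation == "F" else tuple(
        revcomp(v) for v in variants)
    best = None  # (mismatches, start, variant_index)
    for vi, seq in enumerate(place_seqs):
        mism, start = _best_hamming_placement(seq, anchor_seq)
        if best is None or (mism, start, vi) < best:
            best = (mism, start, vi)
    if best is None or best[0] > max_mismatch:
        raise ValueError(
            f"primer {pinput.name!r} cannot be placed on the anchor sequence "
            f"(best placement has {best[0] if best else '?'} mismatches)")
    mism, start, _ = best
    L = len(variants[0])
    interval = (start + 1, start + L)
    plus_cols = [anchor_map.col_of_pos(p) for p in range(interval[0], interval[1] + 1)]
    cols = tuple(plus_cols) if pinput.orientation == "F" else tuple(reversed(plus_cols))
    return PrimerSpec(pinput, variants, interval, cols)


@dataclass(frozen=True)
class BindingSite:
    """The plus-strand read material at one primer's anchored columns."""

    read_id: str
    primer_name: str
    orientation: str
    site_seq: str                # plus-strand read bases in the padded window
    covered: tuple[bool, ...]    # per primer position (5'->3' of the primer)
    span_pos: tuple[int, int]    # covered anchor positions, plus-strand order

    @property
    def completeness(self) -> float:
        return sum(self.covered) / len(self.covered)


def extract_binding_site(proj: ProjectedRead, primer: PrimerSpec,
                         anchor_map: AnchorMap,
                         pad: int = DEFAULT_PAD) -> BindingSite | None:
    """Extract the padded binding site of one primer from a projected read.

    Primer positions whose columns fall outside the read's aligned span are
    missing.  A site with no covered position is not evaluated at all
    (returns None).
    """
    if not 3 <= pad <= 5:
        raise ValueError("pad must be 3..5")
    lo_pos = max(1, min(primer.anchor_interval) - pad)
    hi_pos = min(len(anchor_map), max(primer.anchor_interval) + pad)
    lo_col, hi_col = anchor_map.col_of_pos(lo_pos), anchor_map.col_of_pos(hi_pos)
    covered = tuple(proj.start_col <= c <= proj.end_col for c in primer.anchor_cols)
    if not any(covered):
        return None
    window = proj.gapped[lo_col - 1:hi_col]
    site_seq = window.replace("-", "")
    cov_pos = [min(primer.anchor_interval) + i if primer.orientation == "F"
               else max(primer.anchor_interval) - i
               for i, c in enumerate(covered) if c]
    return BindingSite(proj.read_id, primer.name, primer.orientation,
                       site_seq, covered, (min(cov_pos), max(cov_pos)))


@dataclass(frozen=True)
class SiteEvaluation:
    """One read x one primer (for one chosen variant)."""

    read_id: str
    primer_name: str
    variant: str
    match_string: str
    span_pos: tuple[int, int]
    n_mismatch_total: int
    n_mismatch_last4: int
    completeness: float
    degree: str  # 'matched' | 'mismatched'
    lineage: tuple[str, ...] = ()

    @property
    def score(self) -> tuple[int, int]:
        """The best-variant selection key (lower is better)."""
        return (self.n_mismatch_total, self.n_mismatch_last4)


def counts_from_match_string(ms: str, primer_len: int
                             ) -> tuple[int, int, float, dict[str, int]]:
    """Recount (n_mismatch_total, n_mismatch_last4, completeness, per-type
    event counts) from a match-type string.

    Mismatch events: each substitution (uppercase base), each maximal run of
    ``d`` (one deletion event) and each maximal run of lowercase bases (one
    insertion event).  The last-4 window is the ``primer_len - 3 ..
    primer_len`` primer positions; an indel event counts there if it includes
    or is adjacent to any window position.
    """
    pos = 0  # primer positions consumed so far
    subs: list[int] = []
    dels: list[list[int]] = []
    ins: list[int] = []  # primer position each insertion run follows
    missing = 0
    prev: str | None = None
    for ch in ms:
        if ch == "=":
            pos += 1
        elif ch == ".":
            pos += 1
            missing += 1
        elif ch == "d":
            pos += 1
            if prev == "d":
                dels[-1].append(pos)
            else:
                dels.append([pos])
        elif ch.islower():
            if prev is None or not prev.islower():
                ins.append(pos)
        elif ch.isupper():
            pos += 1
            subs.append(pos)
        else:
            raise ValueError(f"invalid match-string symbol {ch!r}")
        prev = ch
    if pos != primer_len:
        raise ValueError(f"match string covers {pos} positions, expected {primer_len}")
    window = set(range(max(1, primer_len - 3), primer_len + 1))
    n_total = len(subs) + len(dels) + len(ins)
    n_last4 = sum(1 for p in subs if p in window)
    n_last4 += sum(1 for run in dels if any(p in window for p in run))
    n_last4 += sum(1 for p in ins if p in window or (p + 1) in window)
    completeness = (primer_len - missing) / primer_len
    events = {"substitution": len(subs), "insertion": len(ins),
              "deletion": len(dels), "missing": missing}
    return n_total, n_last4, completeness, events


def position_mismatch_types(ms: str) -> list[tuple[int, str]]:
    """Per-event (primer position, type) pairs for positional tallies.

    Deletion events are assigned their first position; insertion events the
    position after the gap they fill (clamped to the primer length).
    """
    out: list[tuple[int, str]] = []
    pos = 0
    prev: str | None = None
    n_positions = sum(1 for ch in ms if ch in "=.d" or ch.isupper())
    for ch in ms:
        if ch == "=":
            pos += 1
        elif ch == ".":
            pos += 1
            out.append((pos, "missing"))
        elif ch == "d":
            pos += 1
            if prev != "d":
                out.append((pos, "deletion"))
        elif ch.islower():
            if prev is None or not prev.islower():
                out.append((min(pos + 1, n_positions), "insertion"))
        else:
            pos += 1
            out.append((pos, "substitution"))
        prev = ch
    return out


def _walk_alignment(core: str, site: str) -> tuple[list[str], dict[int, str], int]:
    """Align a covered primer segment against a (transformed) site and emit
    per-position tokens, insertions keyed by the preceding segment index, and
    the identity count."""
    ops = align_ops(core, site, free_b_ends=True)
    tokens: list[str] = []
    inserts: dict[int, str] = {}
    matches = 0
    i = j = 0
    started = False
    for op in ops:
        if op == OP_DIAG:
            if core[i] == site[j]:
                tokens.append("=")
                matches += 1
            else:
                base = site[j]
                tokens.append(base if base in "ACGT" else "N")
            started = True
            i += 1
            j += 1
        elif op == OP_UP:
            tokens.append("d")
            started = True
            i += 1
        else:  # OP_LEFT: site base unmatched
            if started and i < len(core):
                base = site[j].lower()
                if base not in "acgt":
                    base = "n"
                inserts[i] = inserts.get(i, "") + base
            # else: flank absorption, not part of the primer comparison
            j += 1
    return tokens, inserts, matches


def evaluate_site(site: BindingSite, variant: str,
                  drop_identity: float = DEFAULT_DROP_IDENTITY
                  ) -> SiteEvaluation | None:
    """Evaluate one non-degenerate variant against one extracted site.

    The variant's covered segment is re-aligned to the padded site (for R
    primers, to the reverse complement of the plus-strand site, so the primer
    3' end is well defined).  Sites whose re-alignment identity over covered
    positions falls below ``drop_identity`` are dropped (returns None).
    """
    L = len(site.covered)
    if len(variant) != L:
        raise ValueError("variant length does not match primer length")
    s = site.site_seq if site.orientation == "F" else revcomp(site.site_seq)
    cov_idx = [j for j, c in enumerate(site.covered) if c]
    j0, j1 = cov_idx[0], cov_idx[-1]
    core = variant[j0:j1 + 1]
    tokens, inserts, matches = _walk_alignment(core, s)
    n_cov = j1 - j0 + 1
    if matches / n_cov < drop_identity:
        return None

    parts: list[str] = []
    for j in range(L):
        if j < j0 or j > j1:
            parts.append(".")
        else:
            k = j - j0
            parts.append(tokens[k])
            if (k + 1) in inserts and j < j1:
                parts.append(inserts[k + 1])
    ms = "".join(parts)
    n_total, n_last4, completeness, _ = counts_from_match_string(ms, L)
    degree = "matched" if completeness == 1.0 and (
        n_total == 0 or (n_total == 1 and n_last4 == 0)) else "mismatched"
    return SiteEvaluation(site.read_id, site.primer_name, variant, ms,
                          site.span_pos, n_total, n_last4, completeness, degree)


def select_best_variant(evals: list[SiteEvaluation]) -> SiteEvaluation:
    """Best variant by (total mismatches, last-4 mismatches, input order)."""
    if not evals:
        raise ValueError("no variant evaluations to select from")
    best_i = min(range(len(evals)),
                 key=lambda i: (evals[i].n_mismatch_total,
                                evals[i].n_mismatch_last4, i))
    return evals[best_i]


def evaluate_read_site(site: BindingSite, primer: PrimerSpec,
                       lineage: tuple[str, ...] = (),
                       drop_identity: float = DEFAULT_DROP_IDENTITY
                       ) -> SiteEvaluation | None:
    """Evaluate every variant on a site and keep the best; None when all
    variants re-align too poorly (dropped site)."""
    per_variant = [ev for v in primer.variants
                   if (ev := evaluate_site(site, v, drop_identity)) is not None]
    if not per_variant:
        return None
    best = select_best_variant(per_variant)
    return replace(best, lineage=lineage)
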