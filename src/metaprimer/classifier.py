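"""k-mer naive-Bayes taxonomy classifier with bootstrap confidence.

A Wang-style classifier: each lowest-rank taxon (genus) gets per-8-mer
presence probabilities P(kmer | genus) = (count + 0.5) / (N_genus + 1), where
``count`` is the number of that genus's reference sequences containing the
k-mer.  A query is assigned to the genus maximising the joint log-probability
of its distinct k-mers; confidence comes from bootstrap resampling of
ceil(m/8) of the query's m k-mers, reporting the percent of resamples agreeing
at each rank of the winning lineage.

A read passes the gate when it classifies into Bacteria, Archaea or Eukarya
and its domain-rank bootstrap reaches the cutoff (60 by default; 50 for reads
shorter than 250 bases).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np

from metaprimer.refdb import ReferenceAlignment

__all__ = ["TaxAssignment", "KmerNaiveBayes", "train_classifier",
           "classify_bootstrap", "DEFAULT_BOOTSTRAP_CUTOFF", "SHORT_READ_CUTOFF",
           "SHORT_READ_LENGTH", "ACCEPTED_DOMAINS"]

DEFAULT_BOOTSTRAP_CUTOFF = 60
SHORT_READ_CUTOFF = 50
SHORT_READ_LENGTH = 250
ACCEPTED_DOMAINS = frozenset({"Bacteria", "Archaea", "Eukarya", "Eukaryota"})

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _ch in enumerate("ACGT"):
    _BASE_CODE[ord(_ch)] = _i


@dataclass(frozen=True)
class TaxAssignment:
    read_id: str
    lineage: tuple[str, ...]
    bootstrap: tuple[int, ...]  # one value per rank, 0..100
    passed: bool
    cutoff_used: int

    def __post_init__(self) -> None:
        if len(self.bootstrap) != len(self.lineage):
            raise ValueError("bootstrap list must have one value per rank")


def _kmer_indices(seq: str, k: int) -> np.ndarray:
    """Distinct k-mer indices (base-4) of a sequence; windows containing
    non-ACGT symbols are skipped.  Sorted for determinism."""
    codes = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (windows >= 0).all(axis=1)
    pow4 = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    idx = (windows[valid] * pow4).sum(axis=1)
    return np.unique(idx)


class KmerNaiveBayes:
    """Trained model: per-genus k-mer log-probabilities and lineages."""

    def __init__(self, k: int, lineages: list[tuple[str, ...]], logp: np.ndarray):
        self.k = k
        self.lineages = lineages  # one per class, genus = last rank
        self.logp = logp  # shape (n_classes, 4**k), float32
        self.n_ranks = len(lineages[0])

    @property
    def genera(self) -> list[str]:
        return [lin[-1] for lin in self.lineages]


def train_classifier(refs: ReferenceAlignment, k: int = 8) -> KmerNaiveBayes:
    """Train on every taxonomy-bearing row of a reference alignment.

    Classes are full lineages (distinguishing same-named genera under
    different parents).  The anchor row, which carries no taxonomy, is
    excluded; any other row without taxonomy is an error.
    """
    members: dict[tuple[str, ...], list[str]] = {}
    for rid, _ in refs.rows:
        if rid == refs.anchor_id:
            continue
        if rid not in refs.taxonomy:
            raise ValueError(f"reference {rid!r} has no taxonomy; cannot train")
        members.setdefault(refs.taxonomy[rid].lineage, []).append(rid)
    if not members:
        raise ValueError("no taxonomy-bearing references to train on")
    ranks = {len(lin) for lin in members}
    if len(ranks) != 1:
        raise ValueError("all training lineages must have the same number of ranks")
    lineages = sorted(members)
    counts = np.zeros((len(lineages), 4 ** k), dtype=np.float32)
    sizes = np.zeros(len(lineages), dtype=np.float32)
    for ci, lin in enumerate(lineages):
        for rid in members[lin]:
            idx = _kmer_indices(refs.ungapped(rid), k)
            counts[ci, idx] += 1.0
            sizes[ci] += 1.0
    logp = np.log((counts + 0.5) / (sizes[:, None] + 1.0))
    return KmerNaiveBayes(k, lineages, logp)


def classify_bootstrap(model: KmerNaiveBayes, read_id: str, seq: str,
                       cutoff: int = DEFAULT_BOOTSTRAP_CUTOFF,
                       n_boot: int = 100, seed: int = 0) -> TaxAssignment:
    """Classify one sequence with bootstrap confidence.

    Reads shorter than 250 bases automatically use the lower cutoff of 50
    (never raising a user-supplied lower one).  Deterministic for a fixed
    seed.
    """
    if len(seq) < model.k:
        raise ValueError(f"read {read_id!r} shorter than k={model.k}")
    idx = _kmer_indices(seq, model.k)
    if idx.size == 0:
        raise ValueError(f"read {read_id!r} has no valid k-mers")
    S = model.logp[:, idx]  # (classes, m)
    best = int(S.sum(axis=1).argmax())
    lineage = model.lineages[best]

    m = idx.size
    s = ceil(m / 8)
    rng = np.random.default_rng(seed)
    samples = rng.integers(0, m, size=(n_boot, s))
    boot_scores = S[:, samples].sum(axis=2)  # (classes, n_boot)
    # argmax with random (seeded) tie-break: a read whose k-mers are absent
    # from every class scores all classes equally, and a deterministic
    # tie-break would fabricate full bootstrap support for one class
    winners = np.empty(n_boot, dtype=np.int64)
    for b in range(n_boot):
        col = boot_scores[:, b]
        tied = np.flatnonzero(col >= col.max() - 1e-9)
        winners[b] = tied[0] if tied.size == 1 else rng.choice(tied)

    bootstrap = []
    for r in range(model.n_ranks):
        agree = sum(1 for w in winners if model.lineages[w][r] == lineage[r])
        bootstrap.append(round(100 * agree / n_boot))

    eff_cutoff = min(cutoff, SHORT_READ_CUTOFF) if len(seq) < SHORT_READ_LENGTH else cutoff
    domain = lineage[0]
    passed = domain in ACCEPTED_DOMAINS and bootstrap[0] >= eff_cutoff
    return TaxAssignment(read_id, lineage, tuple(bootstrap), passed, eff_cutoff)
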