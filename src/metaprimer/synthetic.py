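"""Synthetic mock-community generator.

Stands in for a read simulator like MetaSim so the whole pipeline is testable
without downloads.  Two layers:

* :func:`make_reference_world` builds a self-consistent gapped reference
  alignment: a random master sequence in a fixed column space, per-domain
  ancestors (domain-specific substitutions plus domain-specific gap blocks,
  imitating expansion segments), and per-genus reference sequences derived
  from their domain ancestor.  Universal primer regions (the F515/R806
  binding sites) are embedded unmutated in every sequence, imitating real
  conserved regions, and the bacterial ancestor doubles as the full-length
  anchor (a synthetic stand-in for the E. coli J01695 reference).
* :func:`generate_mock_genomes` / :func:`simulate_reads` embed those rRNA
  genes in random genomic background and draw fixed-length shotgun reads at a
  target fold coverage with an exact (error-free) or uniform-substitution
  error model, with complete per-interval and per-read truth tables.

The background is i.i.d. uniform ACGT; real genomic structure (repeats, GC
skew, operon copy number variation) is deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np

from metaprimer.formats import SeqRecord, TaxonomyRecord
from metaprimer.refdb import ReferenceAlignment

__all__ = ["ReferenceWorld", "CommunityMember", "CommunitySpec", "GenomeFeature",
           "ReadTruth", "make_reference_world", "default_mock_spec",
           "flip_site_base", "generate_mock_genomes", "simulate_reads",
           "F_SITE_SEQ", "R_SITE_SEQ"]

# Plus-strand binding regions embedded in every synthetic rRNA gene:
# the A-variant of F515 and the plus-strand footprint (reverse complement)
# of the A-variant of R806.
F_SITE_SEQ = "GTGCCAGCAGCCGCGGTAA"
R_SITE_SEQ = "ATTAGATACCCTGGTAGTCC"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_GENE_CODE = {"SSU": 0, "LSU": 1}


@dataclass
class ReferenceWorld:
    """A generated reference alignment plus the truth needed to test against it."""

    alignment: ReferenceAlignment
    anchor_id: str
    genes: dict[str, SeqRecord]            # genus -> ungapped rRNA gene
    lineages: dict[str, tuple[str, ...]]   # genus -> lineage
    ref_id_of_genus: dict[str, str]
    f_site: tuple[int, int] | None         # 1-based anchor positions
    r_site: tuple[int, int] | None
    gene: str = "SSU"


@dataclass(frozen=True)
class CommunityMember:
    name: str
    lineage: tuple[str, ...]
    genome_length: int
    rrna: tuple[SeqRecord, ...]
    abundance: float = 1.0


@dataclass
class CommunitySpec:
    members: list[CommunityMember]
    read_length: int = 400
    coverage: float = 6.0
    error_model: str = "exact"     # 'exact' | 'uniform'
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(m.abundance <= 0 for m in self.members):
            raise ValueError("abundances must be positive")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.members and self.read_length > min(m.genome_length for m in self.members):
            raise ValueError("read_length exceeds the shortest genome")
        if self.error_model not in ("exact", "uniform"):
            raise ValueError("error_model must be 'exact' or 'uniform'")


@dataclass(frozen=True)
class GenomeFeature:
    genome_id: str
    start: int  # 1-based inclusive
    end: int
    feature: str  # rRNA gene id or 'background'
    taxon: str


@dataclass(frozen=True)
class ReadTruth:
    read_id: str
    genome_id: str
    start: int
    end: int
    strand: str
    rrna_overlap: float
    rrna_id: str | None
    taxon: str


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float,
            mutable: np.ndarray) -> np.ndarray:
    """Substitute bases i.i.d. at ``rate`` on positions where ``mutable``."""
    out = seq.copy()
    hit = np.flatnonzero(mutable & (rng.random(seq.size) < rate))
    if hit.size:
        # shift each hit base by 1..3 within ACGT so it always changes
        cur = np.array([{65: 0, 67: 1, 71: 2, 84: 3}[b] for b in out[hit]])
        out[hit] = _BASES[(cur + rng.integers(1, 4, size=hit.size)) % 4]
    return out


def make_reference_world(seed: int = 0, n_bacteria: int = 9, n_archaea: int = 2,
                         n_eukarya: int = 2, width: int = 1600,
                         domain_rate: float = 0.20, genus_rate: float = 0.06,
                         include_primer_sites: bool = True,
                         gene: str = "SSU") -> ReferenceWorld:
    """Generate a gapped reference alignment with taxonomy and anchor.

    Domain divergence ~2*``domain_rate`` and within-domain genus divergence
    ~2*``genus_rate`` roughly mirror real SSU identity structure (cross-domain
    ~75-80%, congeneric ~90%).  Same seed, same parameters -> byte-identical
    output.
    """
    rng = np.random.default_rng([seed, _GENE_CODE.get(gene, 7)])
    master = _random_seq(rng, width)

    # Domain-specific gap blocks (expansion-segment stand-ins).
    b1 = (width // 8, width // 8 + 40)           # absent in Archaea
    b2 = (int(0.44 * width), int(0.44 * width) + 50)  # absent in Eukarya
    b3 = (width - 100, width)                    # present only in Eukarya
    occupancy = {
        "Bacteria": np.ones(width, bool),
        "Archaea": np.ones(width, bool),
        "Eukarya": np.ones(width, bool),
    }
    occupancy["Bacteria"][b3[0]:b3[1]] = False
    occupancy["Archaea"][b1[0]:b1[1]] = False
    occupancy["Archaea"][b3[0]:b3[1]] = False
    occupancy["Eukarya"][b2[0]:b2[1]] = False

    conserved = np.zeros(width, bool)
    f_cols = r_cols = None
    if include_primer_sites:
        f0 = int(0.31 * width)
        r0 = int(0.49 * width)
        f_cols = (f0, f0 + len(F_SITE_SEQ))
        r_cols = (r0, r0 + len(R_SITE_SEQ))
        master[f_cols[0]:f_cols[1]] = np.frombuffer(F_SITE_SEQ.encode(), np.uint8)
        master[r_cols[0]:r_cols[1]] = np.frombuffer(R_SITE_SEQ.encode(), np.uint8)
        conserved[f_cols[0]:f_cols[1]] = True
        conserved[r_cols[0]:r_cols[1]] = True

    domain_seqs = {}
    for dom in ("Bacteria", "Archaea", "Eukarya"):
        domain_seqs[dom] = _mutate(rng, master, domain_rate,
                                   occupancy[dom] & ~conserved)

    counts = {"Bacteria": n_bacteria, "Archaea": n_archaea, "Eukarya": n_eukarya}
    rows: list[tuple[str, str]] = []
    taxonomy: dict[str, TaxonomyRecord] = {}
    genes: dict[str, SeqRecord] = {}
    lineages: dict[str, tuple[str, ...]] = {}
    ref_of: dict[str, str] = {}
    for dom in ("Bacteria", "Archaea", "Eukarya"):
        occ = occupancy[dom]
        n_phyla = 2 if counts[dom] > 2 else 1
        for i in range(counts[dom]):
            genus = f"Genus_{dom[:3]}{i + 1}"
            phylum = f"{dom[:4]}_phyl{i % n_phyla + 1}"
            lineage = (dom, phylum, genus)
            chars = _mutate(rng, domain_seqs[dom], genus_rate, occ & ~conserved)
            gapped = np.full(width, ord("-"), np.uint8)
            gapped[occ] = chars[occ]
            rid = f"ref_{genus}"
            rows.append((rid, gapped.tobytes().decode()))
            taxonomy[rid] = TaxonomyRecord(rid, lineage)
            genes[genus] = SeqRecord(f"rrna_{genus}", chars[occ].tobytes().decode())
            lineages[genus] = lineage
            ref_of[genus] = rid

    # Anchor: the full-length bacterial ancestor, co-aligned and appended.
    # A synthetic stand-in for a real full-length reference like E. coli J01695.
    anchor_id = f"anchor_{gene.lower()}_synthetic"
    occ_b = occupancy["Bacteria"]
    anchor_gapped = np.full(width, ord("-"), np.uint8)
    anchor_gapped[occ_b] = domain_seqs["Bacteria"][occ_b]
    rows.append((anchor_id, anchor_gapped.tobytes().decode()))

    aln = ReferenceAlignment(rows, width, taxonomy, anchor_id)

    def _anchor_pos(col0: int) -> int:  # 0-based column -> 1-based anchor pos
        return int(occ_b[:col0 + 1].sum())

    f_site = (_anchor_pos(f_cols[0]), _anchor_pos(f_cols[1] - 1)) if f_cols else None
    r_site = (_anchor_pos(r_cols[0]), _anchor_pos(r_cols[1] - 1)) if r_cols else None
    return ReferenceWorld(aln, anchor_id, genes, lineages, ref_of,
                          f_site, r_site, gene)


def flip_site_base(world: ReferenceWorld, genus: str, anchor_pos: int) -> ReferenceWorld:
    """Return a copy of the world with one genus's base at the given anchor
    position substituted (A<->C, G<->T), e.g. to engineer a primer
    3'-terminal mismatch into that genus only."""
    from metaprimer.refdb import map_anchor

    amap = map_anchor(world.alignment, world.anchor_id)
    col = amap.col_of_pos(anchor_pos)
    rid = world.ref_id_of_genus[genus]
    flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
    rows = []
    for row_id, gapped in world.alignment.rows:
        if row_id == rid:
            base = gapped[col - 1]
            if base not in flip:
                raise ValueError(f"{genus}: no base at anchor position {anchor_pos}")
            gapped = gapped[:col - 1] + flip[base] + gapped[col:]
        rows.append((row_id, gapped))
    aln = ReferenceAlignment(rows, world.alignment.width,
                             dict(world.alignment.taxonomy), world.anchor_id)
    genes = dict(world.genes)
    genes[genus] = SeqRecord(genes[genus].id, aln.ungapped(rid))
    return ReferenceWorld(aln, world.anchor_id, genes, dict(world.lineages),
                          dict(world.ref_id_of_genus), world.f_site,
                          world.r_site, world.gene)


def default_mock_spec(world: ReferenceWorld, genome_length: int = 10000,
                      read_length: int = 400, coverage: float = 6.0,
                      error_model: str = "exact", error_rate: float = 0.0,
                      seed: int = 0) -> CommunitySpec:
    """The default mock community: every genus of the generated world (13
    organisms with the default world: 9 Bacteria, 2 Archaea, 2 Eukarya), one
    rRNA operon per genome, even abundance, 400-base reads at 6-fold
    coverage, exact error model."""
    members = [
        CommunityMember(genus, world.lineages[genus], genome_length,
                        (world.genes[genus],), 1.0)
        for genus in sorted(world.genes)
    ]
    return CommunitySpec(members, read_length, coverage, error_model,
                         error_rate, seed)


def generate_mock_genomes(spec: CommunitySpec
                          ) -> tuple[list[SeqRecord], list[GenomeFeature]]:
    """Embed each member's rRNA gene(s) in random background at recorded
    coordinates; returns genomes plus an interval truth table covering every
    genome position."""
    rng = np.random.default_rng([spec.seed, 1])
    genomes: list[SeqRecord] = []
    truth: list[GenomeFeature] = []
    for member in spec.members:
        total_rrna = sum(len(g) for g in member.rrna)
        if total_rrna > member.genome_length:
            raise ValueError(f"{member.name}: rRNA longer than genome")
        bg_len = member.genome_length - total_rrna
        bg = _random_seq(rng, bg_len).tobytes().decode()
        # choose non-overlapping insertion offsets within the background
        offsets = sorted(rng.integers(0, bg_len + 1, size=len(member.rrna)).tolist())
        gid = f"genome_{member.name}"
        taxon = ";".join(member.lineage)
        parts: list[str] = []
        cursor = 0   # background consumed
        out_pos = 0  # genome position built so far
        for off, rrna in zip(offsets, member.rrna):
            seg = bg[cursor:off]
            if seg:
                truth.append(GenomeFeature(gid, out_pos + 1, out_pos + len(seg),
                                           "background", taxon))
                parts.append(seg)
                out_pos += len(seg)
            truth.append(GenomeFeature(gid, out_pos + 1, out_pos + len(rrna.seq),
                                       rrna.id, taxon))
            parts.append(rrna.seq)
            out_pos += len(rrna.seq)
            cursor = off
        seg = bg[cursor:]
        if seg:
            truth.append(GenomeFeature(gid, out_pos + 1, out_pos + len(seg),
                                       "background", taxon))
            parts.append(seg)
        genomes.append(SeqRecord(gid, "".join(parts)))
    return genomes, truth


_RC = str.maketrans("ACGT", "TGCA")


def simulate_reads(genomes: list[SeqRecord], spec: CommunitySpec,
                   truth: list[GenomeFeature] | None = None
                   ) -> tuple[list[SeqRecord], list[ReadTruth]]:
    """Draw fixed-length reads uniformly, random strand, per-genome read count
    ceil(coverage * scale * L / read_length) where scale is the member's
    abundance relative to the mean abundance."""
    rng = np.random.default_rng([spec.seed, 2])
    mean_ab = sum(m.abundance for m in spec.members) / len(spec.members)
    rrna_intervals: dict[str, list[tuple[int, int, str]]] = {}
    for feat in truth or []:
        if feat.feature != "background":
            rrna_intervals.setdefault(feat.genome_id, []).append(
                (feat.start, feat.end, feat.feature))
    reads: list[SeqRecord] = []
    rtruth: list[ReadTruth] = []
    for member, genome in zip(spec.members, genomes):
        L = len(genome.seq)
        rl = spec.read_length
        n = ceil(spec.coverage * (member.abundance / mean_ab) * L / rl)
        starts = rng.integers(0, L - rl + 1, size=n)
        strands = rng.random(n) < 0.5
        taxon = ";".join(member.lineage)
        for ri, (s0, minus) in enumerate(zip(starts, strands)):
            s0 = int(s0)
            seq = genome.seq[s0:s0 + rl]
            if spec.error_model == "uniform" and spec.error_rate > 0:
                arr = np.frombuffer(seq.encode(), np.uint8).copy()
                hit = np.flatnonzero(rng.random(rl) < spec.error_rate)
                if hit.size:
                    cur = np.array([{65: 0, 67: 1, 71: 2, 84: 3}[b] for b in arr[hit]])
                    arr[hit] = _BASES[(cur + rng.integers(1, 4, size=hit.size)) % 4]
                seq = arr.tobytes().decode()
            strand = "-" if minus else "+"
            if minus:
                seq = seq.translate(_RC)[::-1]
            rid = f"{genome.id}_r{ri}"
            overlap = 0
            rrna_id = None
            for a, b, fid in rrna_intervals.get(genome.id, []):
                ov = min(b, s0 + rl) - max(a, s0 + 1) + 1
                if ov > overlap:
                    overlap, rrna_id = ov, fid
            reads.append(SeqRecord(rid, seq))
            rtruth.append(ReadTruth(rid, genome.id, s0 + 1, s0 + rl, strand,
                                    overlap / rl, rrna_id, taxon))
    return reads, rtruth
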