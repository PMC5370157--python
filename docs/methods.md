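# Methods

## Overview

`metaprimer` estimates, per taxon, how well a degenerate SSU PCR primer would
anneal in a specific environment, using PCR-free shotgun reads as the sample
of binding sites.  The computation is reference-anchored: all reads are
projected into the fixed column space of a gapped reference multiple
alignment, and every primer is located once on a co-aligned full-length
anchor sequence, so a primer's binding site has the same column interval in
every read.  This anchoring is what rejects spurious local primer hits that a
local-alignment search would accept anywhere in a read.

## Stage I — mining and placement

**Prescreen (metagenomes only).**  A read is kept when the fraction of its
distinct k-mers (k = 11) shared with any representative reference sequence,
over either strand, reaches 0.10.  Representatives come from greedy
longest-first clustering of the reference collection at 75% global identity.
On the synthetic benchmark this keeps ≥ 95% of reads with ≥ 50% rRNA overlap
and < 1% of background reads.  Metatranscriptomes and amplicon sets skip the
screen — rRNA already dominates them.  The screen is internal (no external
BLAST binary); an HMM- or BLAST-based filter can substitute upstream.

**Search score, orientation, gene attribution.**  The search score of a read
against a database is `100 · |K(read) ∩ K(best template)| / |K(read)|` over
distinct 8-mers of ungapped template sequences.  It is computed for the read
and its reverse complement (twice more against the LSU database in
metatranscriptome mode); the global maximum fixes strand, gene and template,
with ties preferring SSU and the plus strand, then the smaller template id.
Reads whose maximum is below the cutoff (default 30 on the 0–100 scale) are
not considered rRNA.  The score formula is this package's own definition,
built to land on the same 0–100 scale as the cutoffs it is used with.

**Classification.**  A Wang-style naive-Bayes classifier over 8-mers:
classes are the lowest-rank taxa (full lineages), with
`P(kmer | genus) = (count + 0.5) / (N_genus + 1)` where `count` is the number
of the genus's reference sequences containing the k-mer.  Confidence is the
percent of 100 bootstrap resamples (⌈m/8⌉ of the read's m distinct k-mers,
with replacement) agreeing at each rank of the winning lineage.  Resample
winners break score ties *randomly* (seeded): a read with no database k-mers
scores all classes equally, and a deterministic tie-break would fabricate
full support for the alphabetically first genus.  A read passes when its
domain is Bacteria/Archaea/Eukarya and the domain-rank bootstrap reaches the
cutoff — 60 by default, 50 for reads shorter than 250 bases (the lower value
is never raised above a user-supplied cutoff).  Gating is at domain rank;
all ranks are reported.  At desk-scale databases (tens of genera) a random
read still sneaks past the gate a few percent of the time by chance k-mer
overlap; the chance rate shrinks as the database grows.

**NAST projection.**  The oriented read is aligned to its best template's
ungapped sequence by affine-gap Needleman–Wunsch (match +1, mismatch −1, gap
open −2, gap extend −1; traceback ties prefer diagonal, then up, then left,
so output is deterministic) with **free end gaps on both sequences** — the
template overhangs a fragment read, and a read that straddles the gene
boundary carries a non-rRNA tail that must hang off rather than smear across
template columns as spread mismatches.  The pairwise alignment is then pushed
through the template's gap pattern: bases aligned to template positions land
in those columns; insertions fill the gap columns between the flanking
template positions; insertions that do not fit (including unaligned read
tails) are recorded as *rejected insertions* (read position, base) and
omitted.  Degapping the projection and re-inserting the rejected bases
reconstructs the oriented read exactly — an invariant the tests enforce on
every projected read.

## Stage II — primer evaluation

A degenerate primer (IUPAC codes and/or `(A/C)` alternatives) expands to the
cartesian product of its per-position alternatives, in written order for
parenthesised groups and alphabetical order for IUPAC codes.  Each primer is
placed on the anchor sequence (for R-orientation primers, the reverse
complement — the plus-strand footprint — is placed) by exact then best
ungapped Hamming search; at least one variant must place with ≤ 2
mismatches, otherwise the run aborts before any read is processed.

For each projected read, the binding site is the read material in the
anchored columns extended by `pad` anchor positions per side (default 4,
range 3–5); the pads absorb base slips introduced by the multiple alignment,
including terminal indels.  Primer positions whose columns fall outside the
read's aligned span are *missing*; a site with no covered position produces
no record.  The covered segment of each variant is re-aligned to the site
(for R primers, to the site's reverse complement, so the primer 3' end is
well defined) with free site ends, and per primer position a symbol is
emitted: `=`, uppercase read base (substitution), lowercase read base(s)
(insertion, written between the positions it falls between), `d` (deletion),
`.` (missing).  Sites whose re-alignment identity over covered positions is
below 50% are dropped and logged as poorly aligned.

Counting rules (fixed here because "mismatch base numbers" alone does not
define indel weighting): substitutions count per base; insertions and
deletions count one per maximal event; the last-4 window is the four primer
positions nearest the 3' end, and an indel event counts there when it
includes or is adjacent to a window position.  Completeness is covered
positions / primer length.  Degree is *matched* iff completeness is 1 and
there are zero mismatches, or exactly one mismatch with none in the last-4
window.  The degenerate primer is represented by its best variant —
lexicographic minimum of (total mismatches, last-4 mismatches, input order) —
which can only improve as variants are added.

**Outputs.**  Per primer: a `.Match_type` TSV (one row per read: match
string, site span in anchor coordinates, counts, degree, completeness,
lineage, selection score) and a `.Stat` file of six tables — matched vs
mismatched counts (complete sites only), the exact completeness
distribution, mismatch-type totals, match-string frequencies, per-position
mismatch counts by type (insertions assigned to the following position), and
coverage per taxon per rank.  Coverage uses only complete sites; tables 3–5
use every record with a covered position (documented choice; the layout is
ours, the field lists follow the output format the method defines).  No
abundance floor is applied, so rare taxa always appear.  Community
composition against an expectation uses Pearson's chi-squared goodness of
fit with df = categories − 1 (scipy).

## The synthetic generator

`make_reference_world` builds a self-consistent reference: a random master
sequence over a fixed column space (default 1600 columns), three domain
ancestors derived by substitution (rate 0.20) plus domain-specific gap
blocks imitating expansion segments, and per-genus references derived from
their domain ancestor (rate 0.06).  These rates put cross-domain identity
near 70–80% and congeneric identity near 90%, roughly the real SSU identity
structure; the F515/R806 binding regions are embedded unmutated in every
sequence, imitating genuinely conserved regions, and the bacterial ancestor
doubles as the full-length co-aligned anchor (a synthetic stand-in for a
real reference such as E. coli J01695).  The default mock community holds
one genome per genus — 9 Bacteria, 2 Archaea, 2 Eukarya — each a 10 kb
uniform-ACGT background with one embedded rRNA operon, sequenced as
400-base reads at 6-fold per-genome coverage (scaled by relative abundance)
with an exact or uniform-substitution error model, and complete interval and
per-read truth tables.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: sequencing error profiles (homopolymer, quality-decay),
chimeras, rRNA operon copy-number variation, real secondary-structure-driven
conservation patterns, intra-genus diversity, and the scale of real
databases (thousands of genera; classifier specificity and bootstrap
calibration improve with database size).

## Numerical and design choices

- k = 8 for search scoring and classification; k = 11 / min-shared 0.10 for
  the prescreen; all tunable.
- Search cutoff 30, bootstrap cutoff 60 (50 under 250 bp), pad 4,
  poor-alignment drop at 50% covered-position identity, anchor placement
  tolerance 2 mismatches.
- Alignment scoring as above; representative clustering uses linear gap −2
  and identity = matches / alignment length; clustering order is descending
  length, ties by id, for deterministic output.
- Degenerate variant order is the written/alphabetical expansion order and
  breaks selection ties, so outputs are reproducible byte for byte; all
  randomness (bootstrap resampling, simulation) flows from explicit seeds.
- Degenerate inputs: empty read files yield empty, valid outputs; a primer
  that cannot anchor aborts the run; reads shorter than k are parse-time
  errors; `U` is normalised to `T` and both `.` and `-` are read as gaps.
- Problem sizes used by the shipped checks: a 1,950-read mock community for
  recovery and coverage, 1,000 randomized sites for match-typing
  consistency, 500 sites for variant dominance, 1,000 reads for projection
  conservation — sizes at which every stochastic margin in the suite is
  comfortably stable.

## Known limitations

- The search score is a k-mer containment measure, not an alignment score;
  very short or low-complexity reads can score high against a template they
  do not align to (the later projection and 50% identity drop catch these).
- Primer evaluation assumes the anchor truly contains each primer's binding
  site; a primer targeting a region absent from the anchor cannot be
  anchored (the terminal-region database extension exists for exactly the
  8F/1492R case).
- LSU support mirrors SSU (swap reference, taxonomy and anchor); no
  LSU-specific presets are shipped.
- Thermodynamic scoring (ΔG, melting temperature) is out of scope; the
  mismatch-position rule is a deliberate, documented proxy for PCR
  efficiency.
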