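"""Search scoring, orientation, and NAST projection into reference columns."""

import numpy as np
import pytest

from metaprimer.aligner import kmer_search, nast_project, orient_and_assign
from metaprimer.formats import SeqRecord
from metaprimer.refdb import ReferenceAlignment

_RC = str.maketrans("ACGT", "TGCA")


def _revcomp(s):
    return s.translate(_RC)[::-1]


class TestKmerSearch:
    def test_identical_query_scores_100(self, world):
        tid = world.alignment.ids[0]
        seq = world.alignment.ungapped(tid)
        best, score = kmer_search(seq, world.alignment)
        assert score == 100.0

    def test_disjoint_query_scores_0(self, world):
        best, score = kmer_search("ATATATATATATATATATAT", world.alignment)
        assert score == 0.0

    def test_query_shorter_than_k_rejected(self, world):
        with pytest.raises(ValueError):
            kmer_search("ACGT", world.alignment, k=8)

    def test_matches_set_intersection_oracle(self, world):
        rng = np.random.default_rng(4)
        tids = world.alignment.ids
        for trial in range(10):
            tid = tids[int(rng.integers(len(tids)))]
            full = world.alignment.ungapped(tid)
            s0 = int(rng.integers(0, len(full) - 150))
            arr = list(full[s0:s0 + 150])
            for p in rng.choice(150, size=10, replace=False):
                arr[p] = "ACGT"[int(rng.integers(4))]
            q = "".join(arr)
            got = kmer_search(q, world.alignment, k=8)
            qset = {q[i:i + 8] for i in range(len(q) - 7)}
            scores = {}
            for t in tids:
                ts = world.alignment.ungapped(t)
                tset = {ts[i:i + 8] for i in range(len(ts) - 7)}
                scores[t] = 100.0 * len(qset & tset) / len(qset)
            best = min(t for t in scores if scores[t] == max(scores.values()))
            assert got == (best, scores[best])


class TestOrientAndAssign:
    def test_forward_fragment_accepted(self, world):
        tid = world.alignment.ids[0]
        read = SeqRecord("r", world.alignment.ungapped(tid)[200:600])
        o = orient_and_assign(read, world.alignment)
        assert (o.strand, o.gene, o.accepted) == ("+", "SSU", True)

    def test_strand_symmetry(self, world):
        tid = world.alignment.ids[3]
        read = SeqRecord("r", world.alignment.ungapped(tid)[100:500])
        fwd = orient_and_assign(read, world.alignment)
        rev = orient_and_assign(SeqRecord("r", _revcomp(read.seq)), world.alignment)
        assert rev.strand == "-" and fwd.strand == "+"
        assert rev.template_id == fwd.template_id
        assert rev.scores["SSU"] == fwd.scores["SSU"][::-1]

    def test_shuffled_read_rejected_at_cutoff_30(self, world):
        rng = np.random.default_rng(12)
        tid = world.alignment.ids[0]
        arr = np.array(list(world.alignment.ungapped(tid)[:400]))
        rng.shuffle(arr)
        read = SeqRecord("r", "".join(arr))
        o = orient_and_assign(read, world.alignment, cutoff=30)
        assert not o.accepted and o.gene is None
        assert max(o.scores["SSU"]) < 30  # both scores below the cutoff

    def test_score_monotone_in_matching_extension(self, world):
        tid = world.alignment.ids[0]
        full = world.alignment.ungapped(tid)
        prev = -1.0
        for length in (50, 100, 200, 400):
            _, score = kmer_search(full[:length], world.alignment)
            assert score >= prev
            prev = score

    def test_lsu_attribution_with_four_scores(self, world):
        from metaprimer.synthetic import make_reference_world
        lsu_world = make_reference_world(seed=11, gene="LSU", width=2000,
                                         include_primer_sites=False)
        lsu_seq = lsu_world.alignment.ungapped(lsu_world.alignment.ids[0])
        read = SeqRecord("r", lsu_seq[300:700])
        o = orient_and_assign(read, world.alignment, lsu_world.alignment)
        assert o.gene == "LSU" and o.accepted
        assert set(o.scores) == {"SSU", "LSU"}


class TestNastProject:
    def test_read_equal_to_template_reproduces_row(self, world):
        tid = world.alignment.ids[0]
        read = SeqRecord("r", world.alignment.ungapped(tid))
        o = orient_and_assign(read, world.alignment)
        p = nast_project(o, world.alignment)
        assert p.gapped == world.alignment.row(tid)
        assert p.rejected == ()

    def test_internal_deletion_adds_gap_in_span(self, world):
        tid = world.alignment.ids[0]
        full = world.alignment.ungapped(tid)
        read = SeqRecord("r", full[:700] + full[701:])  # drop base 701
        o = orient_and_assign(read, world.alignment)
        p = nast_project(o, world.alignment)
        span = p.gapped[p.start_col - 1:p.end_col]
        tspan = world.alignment.row(tid)[p.start_col - 1:p.end_col]
        assert span.count("-") == tspan.count("-") + 1
        assert p.reconstruct() == read.seq

    def test_unaccepted_read_rejected(self, world):
        read = SeqRecord("r", "ATAT" * 100)
        o = orient_and_assign(read, world.alignment)
        with pytest.raises(ValueError):
            nast_project(o, world.alignment)

    def test_conservation_on_simulated_reads(self, world, rrna_reads):
        reads, _ = rrna_reads
        for read in reads[:120]:
            o = orient_and_assign(read, world.alignment)
            p = nast_project(o, world.alignment)
            assert p.reconstruct() == o.oriented_seq
            assert set(p.gapped[:p.start_col - 1]) <= {"-"}
            assert set(p.gapped[p.end_col:]) <= {"-"}

    def test_column_identity_tracks_substitution_rate(self, world):
        # reads carrying 2% substitutions should show ~98% identity to their
        # template over shared columns
        rng = np.random.default_rng(21)
        tid = world.alignment.ids[1]
        full = world.alignment.ungapped(tid)
        trow = world.alignment.row(tid)
        total = ident = 0
        for trial in range(40):
            s0 = int(rng.integers(0, len(full) - 400))
            arr = list(full[s0:s0 + 400])
            for pos in np.flatnonzero(rng.random(400) < 0.02):
                cur = arr[pos]
                arr[pos] = "ACGT"[("ACGT".index(cur) + int(rng.integers(1, 4))) % 4]
            o = orient_and_assign(SeqRecord(f"r{trial}", "".join(arr)),
                                  world.alignment)
            p = nast_project(o, world.alignment)
            for c in range(p.start_col - 1, p.end_col):
                if p.gapped[c] != "-" and trow[c] != "-":
                    total += 1
                    ident += p.gapped[c] == trow[c]
        assert abs(ident / total - 0.98) < 0.02
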