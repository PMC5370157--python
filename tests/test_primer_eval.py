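"""Degenerate expansion, anchoring, binding-site extraction and match typing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metaprimer.formats import FormatError, PrimerInput
from metaprimer.primer_eval import (
    BindingSite,
    anchor_primer,
    counts_from_match_string,
    evaluate_site,
    expand_degenerate,
    extract_binding_site,
    revcomp,
    select_best_variant,
)
from metaprimer.refdb import map_anchor

_F515 = "GTGCCAGC(A/C)GCCGCGGTAA"
_R806 = "GGACTACC(A/C/G)GGGTATCTAAT"


class TestExpandDegenerate:
    def test_two_fold_alternative(self):
        variants = expand_degenerate(_F515)
        assert len(variants) == 2
        assert {v[8] for v in variants} == {"A", "C"}
        assert all(v[:8] == "GTGCCAGC" and v[9:] == "GCCGCGGTAA" for v in variants)

    def test_three_fold_alternative(self):
        assert len(expand_degenerate(_R806)) == 3

    def test_iupac_equivalence(self):
        assert expand_degenerate("GGACTACCVGGGTATCTAAT") == \
            expand_degenerate(_R806)

    def test_plain_sequence_is_identity(self):
        assert expand_degenerate("ACGT") == ["ACGT"]

    def test_invalid_symbol_rejected(self):
        with pytest.raises(FormatError):
            expand_degenerate("ACQT")


class TestRevcomp:
    @pytest.mark.parametrize("seq,expected", [
        ("ACGT", "ACGT"),  # palindrome
        ("GGAC", "GTCC"),
        ("VACG", "CGTB"),  # IUPAC V <-> B
    ])
    def test_known_values(self, seq, expected):
        assert revcomp(seq) == expected

    @settings(max_examples=50, deadline=None)
    @given(st.text(alphabet="ACGTRYSWKMBDHVN", min_size=1, max_size=40))
    def test_involution(self, seq):
        assert revcomp(revcomp(seq)) == seq

    def test_invalid_symbol_rejected(self):
        with pytest.raises(FormatError):
            revcomp("AC-T")


class TestAnchorPrimer:
    def test_exact_substring_interval(self, world):
        amap = map_anchor(world.alignment, world.anchor_id)
        anchor = world.alignment.ungapped(world.anchor_id)
        sub = anchor[9:28]
        spec = anchor_primer(PrimerInput("P", sub, "F"), anchor, amap)
        assert spec.anchor_interval == (10, 28)

    def test_f515_interval_matches_substring_search(self, world):
        # independent oracle: exact substring search of the A-variant
        amap = map_anchor(world.alignment, world.anchor_id)
        anchor = world.alignment.ungapped(world.anchor_id)
        spec = anchor_primer(PrimerInput("F515", _F515, "F"), anchor, amap)
        a_variant = expand_degenerate(_F515)[0]
        start = anchor.find(a_variant)
        assert start >= 0
        assert spec.anchor_interval == (start + 1, start + len(a_variant))
        assert spec.anchor_cols == tuple(
            amap.col_of_pos(p) for p in range(start + 1, start + 20))

    def test_r_primer_interval_covers_plus_strand_footprint(self, world):
        amap = map_anchor(world.alignment, world.anchor_id)
        anchor = world.alignment.ungapped(world.anchor_id)
        spec = anchor_primer(PrimerInput("R806", _R806, "R"), anchor, amap)
        footprint = revcomp(expand_degenerate(_R806)[0])
        start = anchor.find(footprint)
        assert spec.anchor_interval == (start + 1, start + len(footprint))
        # primer coordinates run 3'->5' on the plus strand
        assert spec.anchor_cols[0] > spec.anchor_cols[-1]

    def test_unplaceable_primer_rejected(self, world):
        amap = map_anchor(world.alignment, world.anchor_id)
        anchor = world.alignment.ungapped(world.anchor_id)
        with pytest.raises(ValueError, match="BAD"):
            anchor_primer(PrimerInput("BAD", "ATATATATATATATATAT", "F"),
                          anchor, amap)


def _site(seq, L, covered=None, orientation="F"):
    covered = covered if covered is not None else (True,) * L
    return BindingSite("r", "P", orientation, seq, covered, (1, L))


class TestEvaluateSite:
    def test_perfect_match(self):
        ev = evaluate_site(_site("ACGGT", 5), "ACGGT")
        assert ev.match_string == "====="
        assert ev.degree == "matched" and ev.n_mismatch_total == 0

    def test_substitution_in_last4_breaks_degree(self):
        ev = evaluate_site(_site("ACGAT", 5), "ACGGT")
        assert ev.match_string == "===A="
        assert (ev.n_mismatch_total, ev.n_mismatch_last4) == (1, 1)
        assert ev.degree == "mismatched"

    def test_single_mismatch_outside_last4_is_matched(self):
        ev = evaluate_site(_site("AAGGTTTTT", 9), "ACGGTTTTT")
        assert ev.match_string == "=A======="
        assert (ev.n_mismatch_total, ev.n_mismatch_last4) == (1, 0)
        assert ev.degree == "matched"

    def test_deletion_marked_d(self):
        ev = evaluate_site(_site("ACGGTACG", 9), "ACGGTACGG")
        assert "d" in ev.match_string
        assert ev.n_mismatch_total == 1

    def test_insertion_marked_lowercase(self):
        ev = evaluate_site(_site("ACGTTACGGT", 9), "ACGTACGGT")
        assert any(ch.islower() and ch != "d" for ch in ev.match_string)
        assert ev.n_mismatch_total == 1

    def test_missing_positions_marked_dot(self):
        covered = (True,) * 4 + (False,) * 5
        ev = evaluate_site(_site("ACGT", 9, covered), "ACGTACGGT")
        assert ev.match_string == "====....."
        assert ev.completeness == pytest.approx(4 / 9)
        assert ev.degree == "mismatched"

    def test_poorly_aligned_site_dropped(self):
        assert evaluate_site(_site("TTTTTTTTTT", 10), "ACGCAGCGCA") is None

    def test_orientation_consistency(self):
        # F primer on plus-strand site == its revcomp as R primer on same site
        rng = np.random.default_rng(13)
        for _ in range(25):
            primer = "".join(rng.choice(list("ACGT"), 18))
            arr = list("AAAA" + primer + "GGGG")
            for p in rng.choice(len(arr), size=2, replace=False):
                arr[p] = "ACGT"[int(rng.integers(4))]
            site_seq = "".join(arr)
            f = evaluate_site(_site(site_seq, 18, orientation="F"), primer)
            r = evaluate_site(_site(revcomp(site_seq), 18, orientation="R"), primer)
            assert (f is None) == (r is None)
            if f is not None:
                assert (f.n_mismatch_total, f.n_mismatch_last4,
                        f.completeness) == (r.n_mismatch_total,
                                            r.n_mismatch_last4, r.completeness)


class TestCountsFromMatchString:
    @pytest.mark.parametrize("ms,L,expected", [
        ("=====", 5, (0, 0, 1.0)),
        ("===A=", 5, (1, 1, 1.0)),
        ("==dd=", 5, (1, 1, 1.0)),          # one deletion event touching last4
        ("==a==g===", 7, (2, 1, 1.0)),      # two insertion events, one in last4
        ("..===", 5, (0, 0, 0.6)),
        ("=Ad=a=", 5, (3, 3, 1.0)),
    ])
    def test_event_counting(self, ms, L, expected):
        n_total, n_last4, completeness, _ = counts_from_match_string(ms, L)
        assert (n_total, n_last4, completeness) == expected

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            counts_from_match_string("====", 5)


class TestSelectBestVariant:
    def test_exact_variant_wins(self):
        site = _site("ACGGC", 5)
        evals = [evaluate_site(site, v) for v in ("ACGGT", "ACGGC")]
        best = select_best_variant(evals)
        assert best.variant == "ACGGC" and best.degree == "matched"

    def test_last4_breaks_tie(self):
        site = _site("ACGTACGGT", 9)
        ev_end = evaluate_site(site, "ACGTACGGA")   # mismatch at 3' end
        ev_front = evaluate_site(site, "TCGTACGGT")  # mismatch at 5' end
        best = select_best_variant([ev_end, ev_front])
        assert best.variant == "TCGTACGGT"

    def test_adding_variants_never_worsens(self):
        rng = np.random.default_rng(17)
        site_seq = "".join(rng.choice(list("ACGT"), 20))
        site = _site(site_seq[2:18], 16)
        variants = []
        prev = None
        for _ in range(6):
            v = list(site_seq[2:18])
            for p in rng.choice(16, size=int(rng.integers(0, 3)), replace=False):
                v[p] = "ACGT"[int(rng.integers(4))]
            variants.append("".join(v))
            evals = [e for v2 in variants
                     if (e := evaluate_site(site, v2)) is not None]
            if not evals:
                continue
            best = select_best_variant(evals)
            if prev is not None:
                assert best.score <= prev
            prev = best.score

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_best_variant([])


class TestExtractBindingSite:
    def test_full_overlap_complete(self, world, primer_inputs, pipeline_result):
        amap = map_anchor(world.alignment, world.anchor_id)
        primer = pipeline_result.primers["F515"]
        # a projected read spanning the whole gene
        from metaprimer.aligner import orient_and_assign, nast_project
        from metaprimer.formats import SeqRecord
        rid = world.alignment.ids[0]
        read = SeqRecord("r", world.alignment.ungapped(rid))
        proj = nast_project(orient_and_assign(read, world.alignment),
                            world.alignment)
        site = extract_binding_site(proj, primer, amap)
        assert site.completeness == 1.0
        assert all(site.covered)

    def test_partial_overlap_counts_covered(self, world, pipeline_result):
        amap = map_anchor(world.alignment, world.anchor_id)
        primer = pipeline_result.primers["F515"]
        from metaprimer.aligner import orient_and_assign, nast_project
        from metaprimer.formats import SeqRecord
        rid = world.alignment.ids[0]
        full = world.alignment.ungapped(rid)
        # read ending 4 primer positions into the site
        end_pos = world.f_site[0] + 3  # anchor pos == genus pos here (checked below)
        read = SeqRecord("r", full[:end_pos])
        proj = nast_project(orient_and_assign(read, world.alignment),
                            world.alignment)
        site = extract_binding_site(proj, primer, amap)
        assert site is not None
        assert sum(site.covered) == 4
        assert site.covered[:4] == (True,) * 4

    def test_no_overlap_gives_none(self, world, pipeline_result):
        amap = map_anchor(world.alignment, world.anchor_id)
        primer = pipeline_result.primers["F515"]
        from metaprimer.aligner import orient_and_assign, nast_project
        from metaprimer.formats import SeqRecord
        rid = world.alignment.ids[0]
        read = SeqRecord("r", world.alignment.ungapped(rid)[:300])
        proj = nast_project(orient_and_assign(read, world.alignment),
                            world.alignment)
        assert extract_binding_site(proj, primer, amap) is None
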