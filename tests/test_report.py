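"""Match-type file round trip, .Stat tables, composition goodness of fit."""

import numpy as np
import pytest
from scipy.special import gammaincc

from metaprimer.primer_eval import (
    SiteEvaluation,
    counts_from_match_string,
    evaluate_site,
    BindingSite,
)
from metaprimer.report import (
    compare_composition,
    compute_stat_tables,
    read_match_type,
    write_match_type,
)


def _eval(read_id, ms, L, lineage=("Bacteria", "P1", "G1")):
    n_total, n_last4, completeness, _ = counts_from_match_string(ms, L)
    degree = "matched" if completeness == 1.0 and (
        n_total == 0 or (n_total == 1 and n_last4 == 0)) else "mismatched"
    return SiteEvaluation(read_id, "P", "A" * L, ms, (1, L), n_total,
                          n_last4, completeness, degree, lineage)


def _random_evals(rng, n, L=8):
    lineages = [("Bacteria", "P1", "G1"), ("Bacteria", "P2", "G2"),
                ("Archaea", "P3", "G3")]
    out = []
    for i in range(n):
        ms = []
        for p in range(L):
            r = rng.random()
            if r < 0.6:
                ms.append("=")
            elif r < 0.7:
                ms.append("ACGT"[int(rng.integers(4))])
            elif r < 0.8:
                ms.append("d")
            elif r < 0.9:
                ms.append(".")
            else:
                ms.append("=" + "acgt"[int(rng.integers(4))])
        out.append(_eval(f"r{i}", "".join(ms), L,
                         lineages[int(rng.integers(3))]))
    return out


def test_match_type_round_trip(tmp_path):
    rng = np.random.default_rng(1)
    evals = _random_evals(rng, 20)
    path = tmp_path / "P.Match_type"
    write_match_type(evals, path)
    back = read_match_type(path)
    assert sorted(back, key=lambda e: e.read_id) == \
        sorted(evals, key=lambda e: e.read_id)


def test_empty_match_type_is_header_only(tmp_path):
    path = tmp_path / "P.Match_type"
    write_match_type([], path)
    assert len(path.read_text().splitlines()) == 1
    assert read_match_type(path) == []


def test_table1_counts_complete_evaluations():
    evals = [_eval(f"r{i}", "========", 8) for i in range(3)]
    evals += [_eval(f"m{i}", "=======A", 8) for i in range(2)]
    stat = compute_stat_tables(evals)
    t1 = dict(zip(stat.table1["degree"], stat.table1["count"]))
    assert t1 == {"matched": 3, "mismatched": 2}
    assert stat.table1["count"].sum() == sum(e.completeness == 1 for e in evals)


def test_incomplete_sites_excluded_from_coverage_table():
    evals = [_eval("a", "========", 8), _eval("b", "===.....", 8)]
    stat = compute_stat_tables(evals)
    assert set(stat.table2["completeness"]) == {1.0, 3 / 8}
    assert stat.table6[stat.table6["rank"] == 3]["complete"].sum() == 1


def test_tables_match_brute_force_recount():
    rng = np.random.default_rng(23)
    evals = _random_evals(rng, 200)
    stat = compute_stat_tables(evals, tax_ranks=3, primer_len=8)

    complete = [e for e in evals if e.completeness == 1.0]
    t1 = dict(zip(stat.table1["degree"], stat.table1["count"]))
    assert t1["matched"] == sum(e.degree == "matched" for e in complete)
    assert t1["mismatched"] == sum(e.degree == "mismatched" for e in complete)

    from collections import Counter
    comp = Counter(e.completeness for e in evals)
    assert dict(zip(stat.table2["completeness"], stat.table2["count"])) == dict(comp)

    totals = Counter()
    for e in evals:
        totals.update(counts_from_match_string(e.match_string, 8)[3])
    assert dict(zip(stat.table3["mismatch_type"], stat.table3["count"])) == dict(totals)

    ms_common = Counter(e.match_string for e in evals).most_common()
    top = stat.table4.iloc[0]
    assert ms_common[0][1] == top["count"]

    # table5 column sums equal the event totals
    for typ in ("substitution", "insertion", "deletion", "missing"):
        assert stat.table5[typ].sum() == totals[typ]

    # table6: per-taxon recount at genus rank
    g = stat.table6[stat.table6["rank"] == 3]
    for _, row in g.iterrows():
        members = [e for e in complete if ";".join(e.lineage) == row["taxon"]]
        assert row["complete"] == len(members)
        assert row["matched"] == sum(e.degree == "matched" for e in members)
        assert row["coverage_pct"] == pytest.approx(
            100 * row["matched"] / row["complete"])
    # complete evaluations partition across taxa at every rank
    for rank in (1, 2, 3):
        sub = stat.table6[stat.table6["rank"] == rank]
        assert sub["complete"].sum() == len(complete)


class TestCompareComposition:
    def test_proportional_observation_gives_zero(self):
        chi2, p = compare_composition({"a": 30, "b": 10}, {"a": 0.75, "b": 0.25})
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_closed_form_two_categories(self):
        chi2, _ = compare_composition({"a": 10, "b": 0}, {"a": 0.5, "b": 0.5})
        assert chi2 == pytest.approx(10.0)

    def test_p_value_matches_chi2_upper_tail(self):
        obs = {"a": 12, "b": 7, "c": 21}
        exp = {"a": 0.3, "b": 0.3, "c": 0.4}
        chi2, p = compare_composition(obs, exp)
        # independent upper-tail evaluation via the regularised gamma function
        assert p == pytest.approx(float(gammaincc(1.0, chi2 / 2)), rel=1e-10)

    def test_zero_expected_with_observation_rejected(self):
        with pytest.raises(ValueError):
            compare_composition({"a": 1, "b": 1}, {"a": 1.0, "b": 0.0})
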