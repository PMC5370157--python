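"""Per-primer outputs: the .Match_type file, the six-table .Stat summary,
and the community-composition goodness-of-fit comparison.

The .Stat file summarises one primer's site evaluations in six tables:
matched/mismatched counts, the completeness distribution, the most frequent
mismatch type, the most common match-type string, per-position mismatch counts
by type, and taxon coverage at each taxonomy rank.  Taxon coverage uses only
complete sites (completeness == 1); tables 3–5 include every record with at
least one covered position.  No abundance floor is applied, so rare taxa
always appear in table 6.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from metaprimer.primer_eval import (
    SiteEvaluation,
    counts_from_match_string,
    position_mismatch_types,
)

__all__ = ["StatReport", "write_match_type", "read_match_type",
           "compute_stat_tables", "write_stat", "compare_composition",
           "write_krona_text"]

_MATCH_TYPE_COLUMNS = ["read_id", "primer", "variant", "match_type",
                       "site_start", "site_end", "mismatch_total",
                       "mismatch_last4", "degree", "completeness",
                       "taxonomy", "score"]


def write_match_type(evals: list[SiteEvaluation], path: str | Path) -> None:
    """Write the per-read match-type table (TSV, one row per read, sorted by
    read id)."""
    primers = {e.primer_name for e in evals}
    if len(primers) > 1:
        raise ValueError(f"evaluations mix primers: {sorted(primers)}")
    with open(path, "w") as fh:
        fh.write("\t".join(_MATCH_TYPE_COLUMNS) + "\n")
        for e in sorted(evals, key=lambda e: e.read_id):
            fh.write("\t".join([
                e.read_id, e.primer_name, e.variant, e.match_string,
                str(e.span_pos[0]), str(e.span_pos[1]),
                str(e.n_mismatch_total), str(e.n_mismatch_last4),
                e.degree, repr(e.completeness),
                ";".join(e.lineage) + (";" if e.lineage else ""),
                f"{e.score[0]}:{e.score[1]}",
            ]) + "\n")


def read_match_type(path: str | Path) -> list[SiteEvaluation]:
    """Parse a .Match_type file back into SiteEvaluation records."""
    out: list[SiteEvaluation] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _MATCH_TYPE_COLUMNS:
            raise ValueError(f"{path}: unexpected match-type header")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            lineage = tuple(r for r in f[10].split(";") if r)
            out.append(SiteEvaluation(
                read_id=f[0], primer_name=f[1], variant=f[2], match_string=f[3],
                span_pos=(int(f[4]), int(f[5])), n_mismatch_total=int(f[6]),
                n_mismatch_last4=int(f[7]), degree=f[8],
                completeness=float(f[9]), lineage=lineage))
    return out


@dataclass
class StatReport:
    """The six aggregate tables summarising one primer's evaluations."""

    primer: str
    table1: pd.DataFrame  # matched vs mismatched counts (complete sites)
    table2: pd.DataFrame  # completeness distribution (all sites)
    table3: pd.DataFrame  # mismatch-type totals, most frequent flagged
    table4: pd.DataFrame  # match-type string counts, most common first
    table5: pd.DataFrame  # per-position mismatch counts by type
    table6: pd.DataFrame  # coverage per taxon per rank (complete sites only)


def compute_stat_tables(evals: list[SiteEvaluation], tax_ranks: int = 3,
                        primer_len: int | None = None) -> StatReport:
    """Build the six-table summary from one primer's site evaluations."""
    primers = {e.primer_name for e in evals}
    if len(primers) > 1:
        raise ValueError(f"evaluations mix primers: {sorted(primers)}")
    primer = primers.pop() if primers else ""
    if primer_len is None:
        primer_len = (sum(1 for ch in evals[0].match_string
                          if ch in "=.d" or ch.isupper()) if evals else 0)

    complete = [e for e in evals if e.completeness == 1.0]

    t1 = pd.DataFrame({
        "degree": ["matched", "mismatched"],
        "count": [sum(e.degree == "matched" for e in complete),
                  sum(e.degree == "mismatched" for e in complete)],
    })

    comp_counts = Counter(e.completeness for e in evals)
    t2 = pd.DataFrame(
        sorted(comp_counts.items(), key=lambda kv: -kv[0]),
        columns=["completeness", "count"])

    type_totals = Counter({"substitution": 0, "insertion": 0,
                           "deletion": 0, "missing": 0})
    for e in evals:
        _, _, _, events = counts_from_match_string(e.match_string, primer_len)
        type_totals.update(events)
    t3 = pd.DataFrame({"mismatch_type": list(type_totals),
                       "count": list(type_totals.values())})
    t3["most_frequent"] = t3["count"] == t3["count"].max() if len(evals) else False

    ms_counts = Counter(e.match_string for e in evals)
    t4 = pd.DataFrame(
        sorted(ms_counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["match_type", "count"])

    pos_counts = {t: Counter() for t in ("substitution", "insertion",
                                         "deletion", "missing")}
    for e in evals:
        for pos, typ in position_mismatch_types(e.match_string):
            pos_counts[typ][pos] += 1
    t5 = pd.DataFrame({
        "position": range(1, primer_len + 1),
        **{t: [pos_counts[t].get(p, 0) for p in range(1, primer_len + 1)]
           for t in pos_counts},
    })

    rows = []
    for rank in range(tax_ranks):
        groups: dict[tuple[str, ...], list[SiteEvaluation]] = {}
        for e in complete:
            if len(e.lineage) > rank:
                groups.setdefault(e.lineage[:rank + 1], []).append(e)
        for taxon, members in sorted(groups.items()):
            matched = sum(e.degree == "matched" for e in members)
            rows.append({
                "rank": rank + 1, "taxon": ";".join(taxon),
                "complete": len(members), "matched": matched,
                "coverage_pct": 100.0 * matched / len(members),
            })
    t6 = pd.DataFrame(rows, columns=["rank", "taxon", "complete", "matched",
                                     "coverage_pct"])

    return StatReport(primer, t1, t2, t3, t4, t5, t6)


_TABLE_TITLES = [
    ("table1", "Table 1: Match and mismatch sequence count"),
    ("table2", "Table 2: Distribution of completeness"),
    ("table3", "Table 3: Most frequent mismatch type"),
    ("table4", "Table 4: Most common match type"),
    ("table5", "Table 5: Count of each mismatch in every position"),
    ("table6", "Table 6: Coverage over taxonomy levels"),
]


def write_stat(report: StatReport, path: str | Path) -> None:
    """Write the six tables as a sectioned TSV."""
    with open(path, "w") as fh:
        fh.write(f"# Primer: {report.primer}\n")
        for attr, title in _TABLE_TITLES:
            fh.write(f"\n# {title}\n")
            getattr(report, attr).to_csv(fh, sep="\t", index=False)


def compare_composition(observed: dict[str, int],
                        expected: dict[str, float]) -> tuple[float, float]:
    """Pearson chi-squared goodness of fit of observed taxon counts against
    expected proportions (df = categories - 1); returns (chi2, p)."""
    if set(observed) != set(expected):
        raise ValueError("observed and expected must cover the same taxa")
    taxa = sorted(observed)
    obs = [observed[t] for t in taxa]
    total = sum(obs)
    if total <= 0:
        raise ValueError("observed total must be positive")
    props = [expected[t] for t in taxa]
    psum = sum(props)
    for t, p, o in zip(taxa, props, obs):
        if p <= 0 and o > 0:
            raise ValueError(f"taxon {t!r} observed but has expected proportion 0")
    exp = [total * p / psum for p in props]
    chi2, pval = stats.chisquare(obs, f_exp=exp)
    return float(chi2), float(pval)


def write_krona_text(counts: dict[tuple[str, ...], int], path: str | Path) -> None:
    """Krona-compatible text export: count<TAB>rank1<TAB>rank2..."""
    with open(path, "w") as fh:
        for lineage, n in sorted(counts.items()):
            fh.write(str(n) + "\t" + "\t".join(lineage) + "\n")
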