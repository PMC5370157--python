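"""Match typing in isolation: what the per-site symbols mean.

Evaluates a degenerate primer against a few hand-built binding sites and
prints the match strings.  Symbols: '=' identical base, uppercase read base =
substitution, lowercase read base = insertion, 'd' = primer base deleted from
the read, '.' = primer position missing from the read.  A site counts as
covered ("matched") when it is complete and has no mismatch, or one mismatch
outside the four 3'-terminal positions.
"""

from metaprimer import expand_degenerate
from metaprimer.primer_eval import BindingSite, evaluate_site, select_best_variant

PRIMER = "GTGCCAGC(A/C)GCCGCGGTAA"  # F515
variants = expand_degenerate(PRIMER)
print(f"{PRIMER} expands to {len(variants)} variants: {variants}\n")

sites = {
    "perfect (A variant)":       "GTGCCAGCAGCCGCGGTAA",
    "perfect (C variant)":       "GTGCCAGCCGCCGCGGTAA",
    "substitution at 5' end":    "TTGCCAGCAGCCGCGGTAA",
    "substitution at 3' end":    "GTGCCAGCAGCCGCGGTAT",
    "internal deletion":         "GTGCCAGCAGCCGCGTAA",  # one G of the GG pair lost
    "internal insertion":        "GTGCCAGCAAGCCGCGGTAA",
}

L = len(variants[0])
for label, seq in sites.items():
    site = BindingSite("read", "F515", "F", seq, (True,) * L, (1, L))
    evals = [e for v in variants if (e := evaluate_site(site, v)) is not None]
    best = select_best_variant(evals)
    print(f"{label:26s} {best.match_string:22s} "
          f"mm={best.n_mismatch_total} last4={best.n_mismatch_last4} "
          f"-> {best.degree}")

print("\nOnly 'matched' complete sites count toward a taxon's primer coverage.")
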