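"""Two-stage pipeline orchestration.

Stage I: orient every read (forward vs reverse-complement search scores
against the SSU — and in metatranscriptome mode also the LSU — reference
database), classify accepted SSU reads with the bootstrap naive-Bayes
classifier, and project passing reads into the reference column space.

Stage II: for every anchored primer, extract each projected read's padded
binding site, evaluate all non-degenerate variants, and keep the best.

Every drop is counted by reason, so input count == accepted + sum(drops).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from metaprimer.aligner import OrientedRead, ProjectedRead, nast_project, orient_and_assign
from metaprimer.classifier import (
    DEFAULT_BOOTSTRAP_CUTOFF,
    TaxAssignment,
    classify_bootstrap,
    train_classifier,
)
from metaprimer.formats import PrimerInput, SeqRecord
from metaprimer.primer_eval import (
    DEFAULT_DROP_IDENTITY,
    DEFAULT_PAD,
    PrimerSpec,
    SiteEvaluation,
    anchor_primer,
    evaluate_read_site,
    extract_binding_site,
)
from metaprimer.refdb import ReferenceAlignment, map_anchor

__all__ = ["PipelineResult", "run_main"]


@dataclass
class PipelineResult:
    assignments: list[TaxAssignment] = field(default_factory=list)
    lsu_assignments: list[TaxAssignment] = field(default_factory=list)
    projections: dict[str, ProjectedRead] = field(default_factory=dict)
    oriented: dict[str, OrientedRead] = field(default_factory=dict)
    evaluations: dict[str, list[SiteEvaluation]] = field(default_factory=dict)
    primers: dict[str, PrimerSpec] = field(default_factory=dict)
    drops: Counter = field(default_factory=Counter)
    site_drops: dict[str, Counter] = field(default_factory=dict)
    n_input: int = 0

    @property
    def n_ssu(self) -> int:
        return len(self.assignments)

    def log_lines(self) -> list[str]:
        lines = [f"input reads: {self.n_input}",
                 f"SSU reads classified: {len(self.assignments)}",
                 f"LSU reads classified: {len(self.lsu_assignments)}"]
        for reason, n in sorted(self.drops.items()):
            lines.append(f"dropped ({reason}): {n}")
        for primer, ctr in sorted(self.site_drops.items()):
            for reason, n in sorted(ctr.items()):
                lines.append(f"{primer}: sites dropped ({reason}): {n}")
            lines.append(f"{primer}: sites evaluated: {len(self.evaluations[primer])}")
        return lines


def run_main(reads: list[SeqRecord], ssu: ReferenceAlignment,
             primer_inputs: list[PrimerInput], *,
             mode: str = "metagenome",
             lsu: ReferenceAlignment | None = None,
             search_cutoff: float = 30.0,
             bootstrap_cutoff: int = DEFAULT_BOOTSTRAP_CUTOFF,
             pad: int = DEFAULT_PAD,
             drop_identity: float = DEFAULT_DROP_IDENTITY,
             seed: int = 0,
             search_k: int = 8,
             classify_k: int = 8,
             n_boot: int = 100) -> PipelineResult:
    """Run Stage I + Stage II over a read set.

    ``ssu`` must carry taxonomy and an appended anchor row.  In
    metatranscriptome mode an LSU reference may be supplied; LSU-attributed
    reads are then classified against it (four search scores per read decide
    the attribution).  Primers that cannot be anchored raise before any read
    is processed.
    """
    if mode not in ("metagenome", "metatranscriptome"):
        raise ValueError("mode must be 'metagenome' or 'metatranscriptome'")
    if mode == "metagenome" and lsu is not None:
        raise ValueError("an LSU reference is only used in metatranscriptome mode")
    if ssu.anchor_id is None:
        raise ValueError("SSU reference alignment has no anchor row")

    amap = map_anchor(ssu, ssu.anchor_id)
    anchor_seq = ssu.ungapped(ssu.anchor_id)
    primers = {p.name: anchor_primer(p, anchor_seq, amap) for p in primer_inputs}

    model = train_classifier(ssu, k=classify_k)
    lsu_model = None
    if lsu is not None and lsu.taxonomy:
        lsu_model = train_classifier(lsu, k=classify_k)

    result = PipelineResult(primers=primers, n_input=len(reads))
    result.evaluations = {name: [] for name in primers}
    result.site_drops = {name: Counter() for name in primers}
    seed_rng = np.random.default_rng(seed)

    for read in reads:
        read_seed = int(seed_rng.integers(0, 2**31))
        oread = orient_and_assign(read, ssu, lsu, cutoff=search_cutoff, k=search_k)
        result.oriented[read.id] = oread
        if not oread.accepted:
            result.drops["low_search_score"] += 1
            continue
        if oread.gene == "LSU":
            if lsu_model is not None:
                assign = classify_bootstrap(lsu_model, read.id, oread.oriented_seq,
                                            cutoff=bootstrap_cutoff,
                                            n_boot=n_boot, seed=read_seed)
                if assign.passed:
                    result.lsu_assignments.append(assign)
                else:
                    result.drops["lsu_low_bootstrap"] += 1
            else:
                result.drops["lsu_unclassified"] += 1
            continue
        assign = classify_bootstrap(model, read.id, oread.oriented_seq,
                                    cutoff=bootstrap_cutoff,
                                    n_boot=n_boot, seed=read_seed)
        if not assign.passed:
            result.drops["low_bootstrap"] += 1
            continue
        result.assignments.append(assign)
        proj = nast_project(oread, ssu)
        result.projections[read.id] = proj
        for name, primer in primers.items():
            site = extract_binding_site(proj, primer, amap, pad=pad)
            if site is None:
                result.site_drops[name]["no_overlap"] += 1
                continue
            ev = evaluate_read_site(site, primer, assign.lineage, drop_identity)
            if ev is None:
                result.site_drops[name]["poor_alignment"] += 1
                continue
            result.evaluations[name].append(ev)
    return result
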