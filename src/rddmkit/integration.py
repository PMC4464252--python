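"""The RdDM candidate-gene cascade.

A gene is nominated when all four predicates hold:

1. it belongs to the supplied metabolic gene set;
2. a consensus red-light hypo-DMR overlaps its promoter or gene body;
3. at least one perfect-unique sRNA passes the AGO4 filter (24 nt, 5' A/G/U),
   maps wholly inside that DMR, is present under FR or normal, and is absent
   (pooled count 0 by default) under R;
4. the gene is differentially expressed with higher expression under red
   light than far-red light.

Candidates carry their supporting evidence and a deterministic composite
rank score; the score substitutes for the manual shortlisting step a curator
would otherwise perform.
"""
from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import annotation as ann_mod
from . import methylome, srnaome

#: DMR-gene association modes
REGIONS = ("promoter", "gene_body")


@dataclass
class CandidateGene:
    """A gene passing the full cascade, with its supporting evidence."""

    gene_id: str
    chrom: str
    dmr_start: int
    dmr_end: int
    dmr_context: str
    level_diff: float
    region: str
    srna_sequences: list[str]
    srna_starts: list[int]
    fr_pooled_count: int
    log2fc: float
    p: float
    score: float = field(default=0.0)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class RecoveryMetrics:
    precision: float
    recall: float
    f1: float


def rank_score(log2fc: float, level_diff: float, fr_pooled_count: float) -> float:
    """Composite rank: |log2 FC| x DMR level difference x log10(1 + sRNA support).

    Monotone in each factor and zero when any evidence axis vanishes.
    """
    return abs(log2fc) * max(0.0, level_diff) * math.log10(1.0 + max(0.0, fr_pooled_count))


def nominate_candidates(
    annotation: ann_mod.GenomeAnnotation,
    metabolic_genes,
    consensus_dmrs: pd.DataFrame,
    srnas: pd.DataFrame,
    srna_samples: dict[str, str],
    de: pd.DataFrame,
    min_count: int = 1,
    require_expression: bool = True,
    regions: tuple[str, ...] = REGIONS,
) -> list[CandidateGene]:
    """Run the four-predicate cascade and return ranked candidates.

    ``consensus_dmrs`` come from :func:`rddmkit.methylome.consensus_hypo_dmrs`,
    ``srnas`` must already be perfect-unique filtered, and ``de`` is the
    gene-indexed union table from :func:`rddmkit.transcriptome.de_union`
    (oriented red over far-red).  Deterministic: candidates sorted by
    descending score, then gene id.
    """
    for r in regions:
        if r not in REGIONS:
            raise ValueError(f"unknown region mode {r!r}")
    known = set(annotation.chromosomes)
    if len(consensus_dmrs) and not set(consensus_dmrs["chrom"]) <= known:
        raise ann_mod.AnnotationError("consensus DMRs on chromosomes absent from the annotation")
    if len(srnas) and not set(srnas["chrom"]) <= known:
        raise ann_mod.AnnotationError("sRNAs on chromosomes absent from the annotation")
    metabolic = set(metabolic_genes)
    if consensus_dmrs.empty or srnas.empty or not metabolic:
        return []

    ago4 = srnaome.ago4_filter(srnas)
    if ago4.empty:
        return []
    ago4_len = ago4["sequence"].str.len().to_numpy(np.int64)
    ago4_start = ago4["start"].to_numpy(np.int64)
    ago4_end = ago4_start + ago4_len
    present = (
        srnaome.condition_presence(ago4, srna_samples, "FR", min_count)
        | srnaome.condition_presence(ago4, srna_samples, "normal", min_count)
    ).to_numpy()
    absent_r = (~srnaome.condition_presence(ago4, srna_samples, "R", min_count)).to_numpy()
    usable = present & absent_r
    fr_counts = srnaome.pooled_condition_counts(ago4, srna_samples, "FR").to_numpy()

    gene_frames = {"promoter": annotation.promoters, "gene_body": annotation.gene_bodies()}
    candidates: dict[str, CandidateGene] = {}
    for region in regions:
        frame = gene_frames[region]
        sub = frame[frame["gene_id"].isin(metabolic)].reset_index(drop=True)
        if sub.empty:
            continue
        pairs = ann_mod.overlap(consensus_dmrs, sub)
        for dmr_idx, gene_idx in zip(pairs["index_a"], pairs["index_b"]):
            dmr = consensus_dmrs.loc[dmr_idx]
            gene_id = sub.loc[gene_idx, "gene_id"]
            inside = (
                usable
                & (ago4["chrom"] == dmr["chrom"]).to_numpy()
                & (ago4_start >= dmr["start"])
                & (ago4_end <= dmr["end"])
            )
            if not inside.any():
                continue
            if require_expression:
                if gene_id not in de.index:
                    continue
                row = de.loc[gene_id]
                if not (bool(row["de"]) and row["log2fc"] > 0):
                    continue
                log2fc, pval = float(row["log2fc"]), float(row["p"])
            else:
                log2fc, pval = float("nan"), float("nan")
                if gene_id in de.index:
                    log2fc = float(de.loc[gene_id, "log2fc"])
                    pval = float(de.loc[gene_id, "p"])
            hit = ago4[inside].sort_values(["start", "sequence"], kind="stable")
            fr_pool = int(fr_counts[inside].sum())
            fc_factor = 0.0 if (require_expression is False and math.isnan(log2fc)) else log2fc
            cand = CandidateGene(
                gene_id=str(gene_id),
                chrom=str(dmr["chrom"]),
                dmr_start=int(dmr["start"]),
                dmr_end=int(dmr["end"]),
                dmr_context=str(dmr["context"]),
                level_diff=float(dmr["level_diff"]),
                region=region,
                srna_sequences=list(hit["sequence"]),
                srna_starts=[int(x) for x in hit["start"]],
                fr_pooled_count=fr_pool,
                log2fc=log2fc,
                p=pval,
                score=rank_score(fc_factor, float(dmr["level_diff"]), fr_pool),
            )
            prev = candidates.get(cand.gene_id)
            # keep the best-supported DMR per gene (highest score, then
            # level difference, promoter before gene body)
            key = (cand.score, cand.level_diff, cand.region == "promoter", -cand.dmr_start)
            if prev is None or key > (prev.score, prev.level_diff, prev.region == "promoter", -prev.dmr_start):
                candidates[cand.gene_id] = cand
    ranked = sorted(candidates.values(), key=lambda c: (-c.score, c.gene_id))
    return ranked


def evaluate_recovery(candidates, planted_truth) -> RecoveryMetrics:
    """Precision / recall / F1 of nominated gene ids against planted truth."""
    truth = {getattr(c, "gene_id", c) for c in planted_truth}
    if not truth:
        raise ValueError("empty planted truth")
    found = {getattr(c, "gene_id", c) for c in candidates}
    tp = len(found & truth)
    precision = tp / len(found) if found else 0.0
    recall = tp / len(truth)
    f1 = 0.0 if tp == 0 else 2 * precision * recall / (precision + recall)
    return RecoveryMetrics(precision, recall, f1)


def gene_report(
    gene_id: str,
    annotation: ann_mod.GenomeAnnotation,
    cytosines: methylome.CytosineTable,
    srnas: pd.DataFrame,
    srna_samples: dict[str, str],
    expression,
    candidate: CandidateGene | None = None,
) -> dict:
    """Self-contained per-gene evidence bundle (JSON-serializable).

    Holds per-sample expression, per-condition/context weighted methylation
    over the candidate DMR (or the promoter when no candidate is given), and
    the sRNA records anchored in that interval with per-sample counts.  All
    values are computed with the same module functions the pipeline uses, so
    the report never drifts from the underlying tracks.
    """
    from .transcriptome import normalize

    genes = annotation.genes.set_index("gene_id")
    if gene_id not in genes.index:
        raise KeyError(f"unknown gene {gene_id!r}")
    gene = genes.loc[gene_id]
    if candidate is not None:
        interval = (candidate.chrom, candidate.dmr_start, candidate.dmr_end)
    else:
        prom = annotation.promoters.set_index("gene_id").loc[gene_id]
        interval = (prom["chrom"], int(prom["start"]), int(prom["end"]))
    chrom, start, end = interval

    cpm = normalize(expression)
    expr = {
        "counts": {s: int(expression.counts.loc[gene_id, s]) for s in expression.counts.columns},
        "cpm": {s: float(cpm.loc[gene_id, s]) for s in cpm.columns},
    }
    meth = {
        cond: {
            ctx: _nan_to_none(
                methylome.region_weighted_methylation(cytosines, cond, chrom, start, end, ctx)
            )
            for ctx in methylome.CONTEXTS
        }
        for cond in cytosines.conditions
    }
    lens = srnas["sequence"].str.len().to_numpy(np.int64)
    inside = (
        (srnas["chrom"] == chrom).to_numpy()
        & (srnas["start"].to_numpy(np.int64) >= start)
        & (srnas["start"].to_numpy(np.int64) + lens <= end)
    )
    srna_rows = [
        {
            "sequence": r["sequence"],
            "start": int(r["start"]),
            "strand": r["strand"],
            "counts": {s: int(r[f"count_{s}"]) for s in srna_samples},
        }
        for _, r in srnas[inside].sort_values(["start", "sequence"]).iterrows()
    ]
    report = {
        "gene_id": gene_id,
        "chrom": str(gene["chrom"]),
        "start": int(gene["start"]),
        "end": int(gene["end"]),
        "strand": str(gene["strand"]),
        "interval": {"chrom": str(chrom), "start": int(start), "end": int(end)},
        "expression": expr,
        "methylation": meth,
        "srnas": srna_rows,
        "candidate": candidate.to_dict() if candidate is not None else None,
    }
    return report


def _nan_to_none(x: float):
    return None if (isinstance(x, float) and math.isnan(x)) else float(x)
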