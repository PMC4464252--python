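"""Methylation levels, DMC/DMR discovery, consensus intervals and metagene
profiles.

The callers implement the rule set used throughout the package: differentially
methylated cytosines (DMCs) by a two-sided Fisher exact test on replicate-
pooled counts with a minimum depth of 3 in both conditions, an absolute
methylation-ratio difference of at least 0.33 and p <= 0.05; differentially
methylated regions (DMRs) as maximal runs of >= 3 same-direction, same-context
DMCs with consecutive gaps <= 300 bp, re-tested by Fisher on counts pooled
over *all* cytosines of the context inside the span.

Methylation of a region is always the *weighted* level: summed methylated
reads over summed total reads, never a mean of per-site ratios.  Undefined
levels (zero coverage) are NaN, never 0 — a level of 0 is a meaningful
observation.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import fisher_exact_two_sided

logger = logging.getLogger(__name__)

CONTEXTS: tuple[str, ...] = ("CG", "CHG", "CHH")

#: sentinel for undefined methylation levels (no covered cytosines)
MISSING: float = float("nan")

DMC_COLUMNS = [
    "chrom", "pos", "strand", "context",
    "m_a", "u_a", "m_b", "u_b", "level_a", "level_b", "diff", "direction", "p",
]
DMR_COLUMNS = [
    "chrom", "start", "end", "context", "direction",
    "n_dmcs", "level_a", "level_b", "p",
]


@dataclass(eq=False)
class CytosineTable:
    """Per-cytosine methylated/unmethylated counts for a set of samples.

    ``data`` columns: ``chrom``, ``pos`` (0-based), ``strand``, ``context``
    plus ``meth_<sample>`` / ``unmeth_<sample>`` count columns.  ``samples``
    maps sample name -> condition.
    """

    data: pd.DataFrame
    samples: dict[str, str]

    def __post_init__(self) -> None:
        for s in self.samples:
            for col in (f"meth_{s}", f"unmeth_{s}"):
                if col not in self.data.columns:
                    raise ValueError(f"missing count column {col!r}")
                if (self.data[col] < 0).any():
                    raise ValueError(f"negative counts in {col!r}")
        bad = ~self.data["context"].isin(CONTEXTS)
        if bad.any():
            raise ValueError(f"unknown context values: {set(self.data.loc[bad, 'context'])}")
        self.data = self.data.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for cond in self.samples.values():
            if cond not in seen:
                seen.append(cond)
        return seen

    def condition_samples(self, condition: str) -> list[str]:
        names = [s for s, c in self.samples.items() if c == condition]
        if not names:
            raise ValueError(f"condition {condition!r} not present in table")
        return names

    def pooled(self, condition: str) -> tuple[np.ndarray, np.ndarray]:
        """Counts summed over the replicates of one condition."""
        names = self.condition_samples(condition)
        m = sum(self.data[f"meth_{s}"].to_numpy(np.int64) for s in names)
        u = sum(self.data[f"unmeth_{s}"].to_numpy(np.int64) for s in names)
        return m, u

    def context_arrays(self, context: str, condition: str):
        """Per-chromosome (positions, meth, unmeth) sorted arrays for one
        context, pooled over a condition's replicates."""
        m, u = self.pooled(condition)
        sel = (self.data["context"] == context).to_numpy()
        sub = self.data.loc[sel, ["chrom", "pos"]]
        out = {}
        for chrom, grp in sub.groupby("chrom", sort=False):
            idx = grp.index.to_numpy()
            out[chrom] = (grp["pos"].to_numpy(np.int64), m[idx], u[idx])
        return out


def methylation_level(m, u):
    """Per-site level m / (m + u); NaN where depth is zero."""
    m = np.asarray(m, dtype=float)
    u = np.asarray(u, dtype=float)
    depth = m + u
    with np.errstate(invalid="ignore", divide="ignore"):
        lvl = np.where(depth > 0, m / np.where(depth > 0, depth, 1.0), MISSING)
    if lvl.ndim == 0:
        return float(lvl)
    return lvl


def weighted_level(m, u) -> float:
    """Count-weighted methylation of a set of sites: sum(m) / sum(m + u).

    This is *not* the mean of per-site ratios: deeply covered sites dominate.
    NaN when the set is empty or entirely uncovered.
    """
    m_sum = float(np.sum(m))
    total = m_sum + float(np.sum(u))
    if total <= 0:
        return MISSING
    return m_sum / total


def region_weighted_methylation(
    table: CytosineTable,
    condition: str,
    chrom: str,
    start: int,
    end: int,
    context: str | None = None,
) -> float:
    """Weighted methylation of ``[start, end)`` on ``chrom`` for a condition."""
    m, u = table.pooled(condition)
    sel = (
        (table.data["chrom"] == chrom).to_numpy()
        & (table.data["pos"].to_numpy() >= start)
        & (table.data["pos"].to_numpy() < end)
    )
    if context is not None:
        sel &= (table.data["context"] == context).to_numpy()
    return weighted_level(m[sel], u[sel])


def call_dmcs(
    table: CytosineTable,
    cond_a: str,
    cond_b: str,
    p_thresh: float = 0.05,
    min_depth: int = 3,
    min_diff: float = 0.33,
) -> pd.DataFrame:
    """Differentially methylated cytosines between two conditions.

    Replicates are pooled per condition; a site is a DMC when pooled depth is
    >= ``min_depth`` in *both* conditions, the absolute difference of pooled
    methylation ratios is >= ``min_diff`` and the two-sided Fisher exact p is
    <= ``p_thresh``.  Direction is ``hypo`` when condition ``cond_a`` is the
    less methylated one.
    """
    m_a, u_a = table.pooled(cond_a)
    m_b, u_b = table.pooled(cond_b)
    d_a, d_b = m_a + u_a, m_b + u_b
    depth_ok = (d_a >= min_depth) & (d_b >= min_depth)
    with np.errstate(invalid="ignore", divide="ignore"):
        la = np.where(d_a > 0, m_a / np.maximum(d_a, 1), np.nan)
        lb = np.where(d_b > 0, m_b / np.maximum(d_b, 1), np.nan)
    diff = la - lb
    cand = depth_ok & (np.abs(diff) >= min_diff)
    idx = np.flatnonzero(cand)
    pvals = np.empty(idx.size)
    for i, j in enumerate(idx):
        pvals[i] = fisher_exact_two_sided(m_a[j], u_a[j], m_b[j], u_b[j])
    keep = pvals <= p_thresh
    idx = idx[keep]
    sub = table.data.iloc[idx]
    out = pd.DataFrame(
        {
            "chrom": sub["chrom"].to_numpy(),
            "pos": sub["pos"].to_numpy(),
            "strand": sub["strand"].to_numpy(),
            "context": sub["context"].to_numpy(),
            "m_a": m_a[idx], "u_a": u_a[idx], "m_b": m_b[idx], "u_b": u_b[idx],
            "level_a": la[idx], "level_b": lb[idx], "diff": diff[idx],
            "direction": np.where(diff[idx] < 0, "hypo", "hyper"),
            "p": pvals[keep],
        }
    )
    return out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def call_dmrs(
    dmcs: pd.DataFrame,
    table: CytosineTable,
    cond_a: str,
    cond_b: str,
    min_dmcs: int = 3,
    max_gap: int = 300,
    p_thresh: float = 0.05,
) -> pd.DataFrame:
    """Merge DMCs into differentially methylated regions.

    Maximal runs of same-chromosome, same-context, same-direction DMCs with
    consecutive distances <= ``max_gap`` and length >= ``min_dmcs`` become
    DMRs spanning first to last member DMC (half-open).  Each DMR is re-tested
    by a Fisher exact test on counts pooled over *all* cytosines of that
    context inside the span; regions with p > ``p_thresh`` are dropped.
    """
    if dmcs.empty:
        return pd.DataFrame(columns=DMR_COLUMNS)
    ctx_cache = {
        ctx: (table.context_arrays(ctx, cond_a), table.context_arrays(ctx, cond_b))
        for ctx in dmcs["context"].unique()
    }
    rows: list[tuple] = []
    for (chrom, context, direction), grp in dmcs.groupby(
        ["chrom", "context", "direction"], sort=True
    ):
        pos = np.sort(grp["pos"].to_numpy(np.int64))
        breaks = np.flatnonzero(np.diff(pos) > max_gap) + 1
        for run in np.split(pos, breaks):
            if run.size < min_dmcs:
                continue
            start, end = int(run[0]), int(run[-1]) + 1
            per_a, per_b = ctx_cache[context]
            ma = ua = mb = ub = 0
            if chrom in per_a:
                p_arr, m_arr, u_arr = per_a[chrom]
                i0, i1 = np.searchsorted(p_arr, [start, end])
                ma, ua = int(m_arr[i0:i1].sum()), int(u_arr[i0:i1].sum())
                p_arr, m_arr, u_arr = per_b[chrom]
                i0, i1 = np.searchsorted(p_arr, [start, end])
                mb, ub = int(m_arr[i0:i1].sum()), int(u_arr[i0:i1].sum())
            p = fisher_exact_two_sided(ma, ua, mb, ub)
            if p > p_thresh:
                continue
            rows.append(
                (chrom, start, end, context, direction, int(run.size),
                 weighted_level(ma, ua), weighted_level(mb, ub), p)
            )
    out = pd.DataFrame(rows, columns=DMR_COLUMNS)
    return out.sort_values(["chrom", "start", "context"], kind="stable").reset_index(drop=True)


def consensus_hypo_dmrs(dmrs_a: pd.DataFrame, dmrs_b: pd.DataFrame) -> pd.DataFrame:
    """Consensus of two hypo-DMR sets: intersections of overlapping pairs.

    Both inputs must be hypo-directed with respect to the same focal
    condition (e.g. R-vs-normal and R-vs-FR hypo calls).  One output region
    per overlapping same-context pair, spanning the interval intersection;
    ``level_diff`` is the mean comparator-minus-focal level difference of the
    two parents.
    """
    from . import annotation as ann_mod

    for name, d in (("a", dmrs_a), ("b", dmrs_b)):
        if len(d) and not (d["direction"] == "hypo").all():
            raise ValueError(f"dmrs_{name} contains non-hypo regions")
    cols = ["chrom", "start", "end", "context", "level_diff"]
    if dmrs_a.empty or dmrs_b.empty:
        return pd.DataFrame(columns=cols)
    rows: list[tuple] = []
    for context in sorted(set(dmrs_a["context"]) & set(dmrs_b["context"])):
        sub_a = dmrs_a[dmrs_a["context"] == context]
        sub_b = dmrs_b[dmrs_b["context"] == context]
        pairs = ann_mod.overlap(sub_a, sub_b)
        for pa, pb in zip(pairs["index_a"], pairs["index_b"]):
            ra, rb = sub_a.loc[pa], sub_b.loc[pb]
            diff_a = ra["level_b"] - ra["level_a"]
            diff_b = rb["level_b"] - rb["level_a"]
            rows.append(
                (ra["chrom"], int(max(ra["start"], rb["start"])),
                 int(min(ra["end"], rb["end"])), context, (diff_a + diff_b) / 2.0)
            )
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values(["chrom", "start", "context"], kind="stable").reset_index(drop=True)


def characterize_dmrs(dmrs: pd.DataFrame, annotation) -> pd.Series:
    """Composition of a DMR set over {promoter, gene_body, TE, intergenic}.

    Each DMR is assigned by its midpoint under the annotation precedence;
    exon/intron hits roll up to ``gene_body``.  Fractions sum to 1; an empty
    input yields an empty Series (no NaNs).
    """
    from . import annotation as ann_mod

    if dmrs.empty:
        return pd.Series(dtype=float)
    mid = ((dmrs["start"].to_numpy(np.int64) + dmrs["end"].to_numpy(np.int64)) // 2)
    labels = ann_mod.assign_regions(annotation, dmrs["chrom"].to_numpy(object), mid)
    labels = np.where(np.isin(labels, ("exon", "intron")), "gene_body", labels)
    counts = pd.Series(labels).value_counts()
    return (counts / counts.sum()).sort_index()


@dataclass(frozen=True)
class DMRSetOverlap:
    """Per-side overlap bookkeeping for two DMR sets.

    ``overlapping_a`` counts regions of A overlapping >= 1 region of B (each
    counted once, however many partners it has), and symmetrically for B —
    so the two overlap counts may differ.
    """

    unique_a: int
    unique_b: int
    overlapping_a: int
    overlapping_b: int


def dmr_set_overlap(dmrs_a: pd.DataFrame, dmrs_b: pd.DataFrame) -> DMRSetOverlap:
    """Counts of DMRs unique to / overlapping between two sets (>= 1 bp)."""
    from . import annotation as ann_mod

    if dmrs_a.empty or dmrs_b.empty:
        return DMRSetOverlap(len(dmrs_a), len(dmrs_b), 0, 0)
    pairs = ann_mod.overlap(dmrs_a, dmrs_b)
    n_over_a = pairs["index_a"].nunique()
    n_over_b = pairs["index_b"].nunique()
    return DMRSetOverlap(len(dmrs_a) - n_over_a, len(dmrs_b) - n_over_b, n_over_a, n_over_b)


@dataclass
class MetageneProfile:
    """Weighted methylation over 60 ordered bins: 20 upstream-flank, 20
    gene-body (per-gene scaled), 20 downstream-flank, 5'->3' orientation."""

    values: np.ndarray
    meth: np.ndarray
    total: np.ndarray
    context: str
    condition: str
    flank: int
    bins: int
    n_genes: int
    n_skipped: int


def metagene_profile(
    annotation,
    table: CytosineTable,
    context: str,
    condition: str,
    flank: int = 2000,
    bins: int = 20,
) -> MetageneProfile:
    """Metagene weighted-methylation profile across all genes.

    Every gene body is divided into ``bins`` equal bins (width = length /
    bins), and each flank of ``flank`` bp into ``bins`` equal bins; counts of
    all cytosines of ``context`` falling in a bin are pooled across genes and
    converted to a weighted level per bin.  Genes shorter than ``bins`` bp are
    skipped with a warning; orientation follows the gene strand (bin 0 is the
    distal 5' flank).
    """
    per_chrom = table.context_arrays(context, condition)
    n_bins = 3 * bins
    meth = np.zeros(n_bins, dtype=np.int64)
    total = np.zeros(n_bins, dtype=np.int64)
    n_genes = n_skipped = 0
    for gene in annotation.genes.itertuples():
        length = gene.end - gene.start
        if length < bins:
            n_skipped += 1
            continue
        if gene.chrom not in per_chrom:
            n_genes += 1
            continue
        pos, m, u = per_chrom[gene.chrom]
        i0, i1 = np.searchsorted(pos, [gene.start - flank, gene.end + flank])
        if i1 > i0:
            x = pos[i0:i1]
            b = np.empty(x.size, dtype=np.int64)
            left = x < gene.start
            right = x >= gene.end
            mid = ~(left | right)
            b[left] = (x[left] - (gene.start - flank)) * bins // flank
            b[mid] = bins + (x[mid] - gene.start) * bins // length
            b[right] = 2 * bins + (x[right] - gene.end) * bins // flank
            if gene.strand == "-":
                b = n_bins - 1 - b
            np.add.at(meth, b, m[i0:i1])
            np.add.at(total, b, m[i0:i1] + u[i0:i1])
        n_genes += 1
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} genes shorter than {bins} bp", stacklevel=2)
    if n_genes == 0:
        raise ValueError("no genes left after length filtering")
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(total > 0, meth / np.maximum(total, 1), MISSING)
    return MetageneProfile(values, meth, total, context, condition, flank, bins, n_genes, n_skipped)
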