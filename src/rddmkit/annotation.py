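"""Genome annotation model, coordinate conventions, and region assignment.

All coordinates are 0-based half-open in memory; on-disk dialects that use
1-based positions (the per-cytosine report) are converted at the I/O boundary
(:mod:`rddmkit.io`).

Every base of the genome maps to exactly one *leaf* region label under a
fixed, configurable precedence::

    promoter > exon > intron > TE > intergenic

with the containment hierarchy ``genic = promoter + gene_body`` and
``gene_body = exon + intron``.  Promoters are derived strand-aware upstream
intervals of configurable width (default 2 kb), clipped at chromosome bounds.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import intervals as iv

logger = logging.getLogger(__name__)

#: leaf labels, in assignment precedence order (intergenic is the fallback)
PRECEDENCE: tuple[str, ...] = ("promoter", "exon", "intron", "TE")
LEAF_LABELS: tuple[str, ...] = PRECEDENCE + ("intergenic",)

#: containment hierarchy used for roll-ups (child -> parent)
LABEL_PARENT: dict[str, str] = {
    "exon": "gene_body",
    "intron": "gene_body",
    "gene_body": "genic",
    "promoter": "genic",
}


class AnnotationError(ValueError):
    """Raised for inconsistent annotations or out-of-range coordinates."""


@dataclass(eq=False)
class GenomeAnnotation:
    """Genes, exons, transposable elements and derived promoters.

    Parameters
    ----------
    chromosomes
        Mapping chromosome name -> length in bp.
    genes
        DataFrame with columns ``gene_id, chrom, start, end, strand``.
    exons
        DataFrame with columns ``gene_id, chrom, start, end``; every exon
        must lie within its gene and exons of a gene must not overlap.
        Genes with no exon rows are treated as single-exon genes spanning
        the whole body.
    tes
        DataFrame with columns ``chrom, start, end``.
    promoters
        Derived by :func:`derive_promoters`; ``None`` until then.
    """

    chromosomes: dict[str, int]
    genes: pd.DataFrame
    exons: pd.DataFrame
    tes: pd.DataFrame
    promoters: pd.DataFrame | None = None
    promoter_span: int | None = None
    _region_index: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.genes = (
            self.genes.sort_values(["chrom", "start", "gene_id"], kind="stable")
            .reset_index(drop=True)
        )
        self.exons = self.exons.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        self.tes = self.tes.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        self._validate()

    # -- validation ---------------------------------------------------------
    def _validate(self) -> None:
        for row in self.genes.itertuples():
            if row.chrom not in self.chromosomes:
                raise AnnotationError(f"gene {row.gene_id!r} on unknown chromosome {row.chrom!r}")
            if not (0 <= row.start < row.end <= self.chromosomes[row.chrom]):
                raise AnnotationError(f"gene {row.gene_id!r} outside chromosome bounds")
            if row.strand not in ("+", "-"):
                raise AnnotationError(f"gene {row.gene_id!r} has invalid strand {row.strand!r}")
        bounds = self.genes.set_index("gene_id")[["start", "end"]]
        for gid, grp in self.exons.groupby("gene_id", sort=False):
            if gid not in bounds.index:
                raise AnnotationError(f"exon references unknown gene {gid!r}")
            gs, ge = bounds.loc[gid]
            ex = grp.sort_values("start")
            if (ex["start"] < gs).any() or (ex["end"] > ge).any():
                raise AnnotationError(f"exon of gene {gid!r} outside gene body")
            if (ex["start"].to_numpy()[1:] < ex["end"].to_numpy()[:-1]).any():
                raise AnnotationError(f"overlapping exons in gene {gid!r}")
        for chrom, grp in self.genes.groupby("chrom", sort=False):
            s = grp["start"].to_numpy()
            e = grp["end"].to_numpy()
            if (s[1:] < e[:-1]).any():
                logger.warning("overlapping genes on %s; interval associations keep all pairs", chrom)

    # -- derived features ---------------------------------------------------
    def exon_table(self) -> pd.DataFrame:
        """Exons, with whole-body exons filled in for genes lacking exon rows."""
        have = set(self.exons["gene_id"])
        missing = self.genes[~self.genes["gene_id"].isin(have)]
        if missing.empty:
            return self.exons
        filler = missing[["gene_id", "chrom", "start", "end"]]
        return (
            pd.concat([self.exons, filler], ignore_index=True)
            .sort_values(["chrom", "start"], kind="stable")
            .reset_index(drop=True)
        )

    def introns(self) -> pd.DataFrame:
        """Gaps between consecutive exons within each gene."""
        rows: list[tuple] = []
        for gid, grp in self.exon_table().groupby("gene_id", sort=False):
            ex = grp.sort_values("start")
            starts = ex["start"].to_numpy()
            ends = ex["end"].to_numpy()
            chrom = ex["chrom"].iloc[0]
            for s, e in zip(ends[:-1], starts[1:]):
                if e > s:
                    rows.append((gid, chrom, int(s), int(e)))
        return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])

    def gene_bodies(self) -> pd.DataFrame:
        return self.genes[["gene_id", "chrom", "start", "end", "strand"]].copy()

    # -- region index -------------------------------------------------------
    def _feature_sets(self) -> dict[str, dict[str, iv.IntervalSet]]:
        """Per-chromosome merged interval sets for each non-intergenic label."""
        if self.promoters is None:
            raise AnnotationError("promoters not derived; call derive_promoters() first")
        out: dict[str, dict[str, iv.IntervalSet]] = {}
        tables = {
            "promoter": self.promoters,
            "exon": self.exon_table(),
            "intron": self.introns(),
            "TE": self.tes,
        }
        for label, tab in tables.items():
            per: dict[str, iv.IntervalSet] = {}
            if len(tab):
                for chrom, grp in tab.groupby("chrom", sort=False):
                    per[chrom] = iv.merge(grp["start"].to_numpy(), grp["end"].to_numpy())
            out[label] = per
        return out

    def region_index(self) -> dict[str, dict[str, iv.IntervalSet]]:
        if self._region_index is None:
            self._region_index = self._feature_sets()
        return self._region_index


def derive_promoters(annotation: GenomeAnnotation, promoter_span: int = 2000) -> GenomeAnnotation:
    """Attach a strand-aware upstream promoter interval to every gene.

    For a + strand gene the promoter ends at the gene start; for a - strand
    gene it begins at the gene end.  Width is ``promoter_span``, truncated at
    chromosome bounds.
    """
    if promoter_span <= 0:
        raise ValueError("promoter_span must be positive")
    rows = []
    for row in annotation.genes.itertuples():
        clen = annotation.chromosomes[row.chrom]
        if row.strand == "+":
            start, end = max(0, row.start - promoter_span), row.start
        else:
            start, end = row.end, min(clen, row.end + promoter_span)
        rows.append((row.gene_id, row.chrom, int(start), int(end), row.strand))
    proms = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    return replace(annotation, promoters=proms, promoter_span=promoter_span, _region_index=None)


def assign_regions(
    annotation: GenomeAnnotation,
    chroms,
    positions,
    precedence: tuple[str, ...] = PRECEDENCE,
) -> np.ndarray:
    """Leaf region label for each (chromosome, position) point.

    Deterministic under ``precedence``: the first matching label wins and
    points matching nothing are ``intergenic``.
    """
    chroms = np.asarray(chroms, dtype=object)
    positions = np.asarray(positions, dtype=np.int64)
    labels = np.full(positions.shape, "intergenic", dtype=object)
    index = annotation.region_index()
    for chrom in pd.unique(chroms):
        if chrom not in annotation.chromosomes:
            raise AnnotationError(f"unknown chromosome {chrom!r}")
        sel = chroms == chrom
        pos = positions[sel]
        if pos.size and (pos.min() < 0 or pos.max() >= annotation.chromosomes[chrom]):
            raise AnnotationError(f"position outside chromosome {chrom!r}")
        sub = labels[sel]
        # apply lowest-precedence first so later labels overwrite
        for label in reversed(precedence):
            iset = index[label].get(chrom)
            if iset is not None:
                sub[iv.contains(iset, pos)] = label
        labels[sel] = sub
    return labels


def assign_region(annotation: GenomeAnnotation, chrom: str, position: int, **kw) -> str:
    """Single-point convenience wrapper around :func:`assign_regions`."""
    return assign_regions(annotation, [chrom], [position], **kw)[0]


def region_base_counts(annotation: GenomeAnnotation) -> dict[str, int]:
    """Bases of the genome claimed by each leaf label under the precedence.

    The counts partition the genome: they sum to the total genome length.
    """
    index = annotation.region_index()
    counts = {label: 0 for label in LEAF_LABELS}
    genome = 0
    for chrom, clen in annotation.chromosomes.items():
        genome += clen
        claimed: iv.IntervalSet = (np.empty(0, np.int64), np.empty(0, np.int64))
        for label in PRECEDENCE:
            iset = index[label].get(chrom)
            if iset is None:
                continue
            fresh = iv.subtract(iset, claimed)
            counts[label] += iv.total_length(fresh)
            claimed = iv.union(claimed, iset)
        counts["intergenic"] += clen - iv.total_length(claimed)
    assert sum(counts.values()) == genome
    return counts


def overlap(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """All pairs of intervals from ``a`` and ``b`` overlapping by >= 1 bp.

    Both frames need ``chrom, start, end`` columns; the result holds the
    original index labels as ``index_a``/``index_b`` plus ``overlap`` length.
    Symmetric up to column naming.
    """
    out_a: list = []
    out_b: list = []
    out_len: list = []
    if len(a) and len(b):
        groups_b = {chrom: grp for chrom, grp in b.groupby("chrom", sort=False)}
        for chrom, ga in a.groupby("chrom", sort=False):
            gb = groups_b.get(chrom)
            if gb is None:
                continue
            ii, jj, ll = iv.overlap_pairs(
                ga["start"].to_numpy(), ga["end"].to_numpy(),
                gb["start"].to_numpy(), gb["end"].to_numpy(),
            )
            out_a.extend(ga.index[ii])
            out_b.extend(gb.index[jj])
            out_len.extend(ll.tolist())
    return pd.DataFrame({"index_a": out_a, "index_b": out_b, "overlap": out_len})
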