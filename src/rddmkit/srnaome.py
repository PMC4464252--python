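"""Small-RNA filtering, length x region characterization, AGO4 5'-preference
selection and abundance normalization.

Records are distinct sRNA sequences with their (unique) genomic mapping and
per-sample read counts.  The perfect-unique filter keeps sequences with no
mismatches, no gaps and exactly one genomic hit; region assignment anchors
each record at its strand-aware 5'-most mapped base.  In the length x region
table, counts are *distinct sequences* (not reads) and the genome dichotomy
is genic vs. intergenic — records anchored in transposable elements fold into
the intergenic column, matching the table's two-way roll-up
(Mapped = Intergenic + Genic; Genic = Promoter + G.Body; G.Body = Intron + Exon).
"""
from __future__ import annotations

import numpy as np
import pandas as pd

LENGTH_RANGE = range(20, 31)

TABLE_COLUMNS = ["mapped", "intergenic", "genic", "promoter", "gene_body", "intron", "exon"]

#: 5' bases compatible with AGO4 loading; U is stored as T on disk
AGO4_FIVE_PRIME = frozenset("AGUT")

RECORD_COLUMNS = ["sequence", "chrom", "start", "strand", "nhits", "mismatches", "gaps"]


def sample_columns(records: pd.DataFrame) -> list[str]:
    return [c for c in records.columns if c.startswith("count_")]


def filter_perfect_unique(records: pd.DataFrame) -> pd.DataFrame:
    """Keep records with perfect (0 mismatch, 0 gap) unique (1 hit) mappings."""
    keep = (
        (records["mismatches"] == 0)
        & (records["gaps"] == 0)
        & (records["nhits"] == 1)
    )
    return records[keep].reset_index(drop=True)


def five_prime_anchor(records: pd.DataFrame) -> np.ndarray:
    """Strand-aware 5'-most mapped position (0-based) of each record."""
    start = records["start"].to_numpy(np.int64)
    length = records["sequence"].str.len().to_numpy(np.int64)
    minus = (records["strand"] == "-").to_numpy()
    anchor = start.copy()
    anchor[minus] = start[minus] + length[minus] - 1
    return anchor


def characterize_length_region(
    records: pd.DataFrame,
    annotation,
    count_mode: str = "distinct",
) -> pd.DataFrame:
    """Length x region table of sRNAs (rows 20-30 nt).

    Each distinct sequence is counted once (``count_mode="distinct"``) or by
    its total read count (``"reads"``) in exactly one leaf column determined
    by its 5' anchor; hierarchy columns are sums of their children.
    """
    from . import annotation as ann_mod

    if count_mode not in ("distinct", "reads"):
        raise ValueError("count_mode must be 'distinct' or 'reads'")
    table = pd.DataFrame(0, index=list(LENGTH_RANGE), columns=TABLE_COLUMNS, dtype=np.int64)
    table.index.name = "length"
    if records.empty:
        return table
    # one row per distinct sequence, order-independent
    recs = records.sort_values(["sequence", "chrom", "start"], kind="stable").drop_duplicates("sequence")
    if count_mode == "distinct":
        weights = np.ones(len(recs), dtype=np.int64)
    else:
        totals = records[sample_columns(records)].sum(axis=1)
        per_seq = totals.groupby(records["sequence"]).sum()
        weights = per_seq.loc[recs["sequence"]].to_numpy(np.int64)
    lengths = recs["sequence"].str.len().to_numpy(np.int64)
    in_range = (lengths >= LENGTH_RANGE.start) & (lengths < LENGTH_RANGE.stop)
    recs = recs[in_range]
    weights = weights[in_range]
    lengths = lengths[in_range]
    anchors = five_prime_anchor(recs)
    labels = ann_mod.assign_regions(annotation, recs["chrom"].to_numpy(object), anchors)
    leaf_to_col = {
        "promoter": "promoter", "exon": "exon", "intron": "intron",
        "TE": "intergenic", "intergenic": "intergenic",
    }
    for length, label, w in zip(lengths, labels, weights):
        table.loc[int(length), leaf_to_col[label]] += int(w)
    table["gene_body"] = table["intron"] + table["exon"]
    table["genic"] = table["promoter"] + table["gene_body"]
    table["mapped"] = table["intergenic"] + table["genic"]
    return table


def summarize_fractions(table: pd.DataFrame) -> dict[str, float]:
    """Headline percentages of a length x region table, rounded to 2 dp.

    Returns genic share of mapped sRNAs, promoter share of genic, and the
    24-nt shares of all mapped and of promoter-anchored sRNAs.  Zero
    denominators yield NaN.
    """

    def pct(num: int, den: int) -> float:
        if den == 0:
            return float("nan")
        return round(100.0 * num / den, 2)

    mapped = int(table["mapped"].sum())
    genic = int(table["genic"].sum())
    promoter = int(table["promoter"].sum())
    return {
        "genic_fraction": pct(genic, mapped),
        "promoter_of_genic_fraction": pct(promoter, genic),
        "frac_24nt_overall": pct(int(table.loc[24, "mapped"]), mapped),
        "frac_24nt_promoter": pct(int(table.loc[24, "promoter"]), promoter),
    }


def ago4_filter(records: pd.DataFrame) -> pd.DataFrame:
    """Keep 24-nt records whose 5' base is A, G or U (T on disk).

    Idempotent; the 5' base is read from the sequence as sequenced.
    """
    seq = records["sequence"].str.upper()
    keep = (seq.str.len() == 24) & seq.str[0].isin(AGO4_FIVE_PRIME)
    return records[keep].reset_index(drop=True)


def srna_tpm(records: pd.DataFrame, sample: str) -> pd.Series:
    """Tags-per-million abundance of each record in one sample."""
    col = f"count_{sample}"
    if col not in records.columns:
        raise ValueError(f"unknown sample {sample!r}")
    counts = records[col].astype(float)
    library = counts.sum()
    if library <= 0:
        raise ValueError(f"sample {sample!r} has an empty library")
    return counts / library * 1e6


def pooled_condition_counts(
    records: pd.DataFrame, samples: dict[str, str], condition: str
) -> pd.Series:
    """Read counts summed over the replicates of one condition."""
    cols = [f"count_{s}" for s, c in samples.items() if c == condition]
    if not cols:
        raise ValueError(f"condition {condition!r} not present")
    return records[cols].sum(axis=1)


def condition_presence(
    records: pd.DataFrame,
    samples: dict[str, str],
    condition: str,
    min_count: int = 1,
) -> pd.Series:
    """Boolean presence per record: pooled condition count >= ``min_count``."""
    return pooled_condition_counts(records, samples, condition) >= min_count
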