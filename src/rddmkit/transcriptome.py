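"""Expression normalization, differential expression, k-means pattern
clustering and cluster term enrichment.

Differential expression follows the rule "at least a two-fold change with
p <= 0.001": fold-changes are ratios of pseudocounted mean counts-per-million
between conditions, and the p-value comes from a negative-binomial exact test
on replicate-pooled, library-size-adjusted counts with a common dispersion
estimated from the replicates (with dispersion 0 — e.g. unreplicated input —
the test reduces to the classical conditioned hypergeometric/Fisher test on
the 2x2 count split).  The pipeline-level DE set is the union over all
red-light vs far-red-light sample pairs.

Expression profiles are centered log2 fold-changes relative to the normal
(white light) condition over the fixed sample order FR5, FR2, FR1, normal,
R1, R2, R5; clustering is plain k-means with deterministic seeding and
size-ranked label renumbering.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control
from sklearn.cluster import KMeans

from .stats import fisher_exact_two_sided, hypergeom_sf, nb_exact_test

#: fixed left-to-right condition order for profiles and clustering
CONDITION_ORDER: tuple[str, ...] = ("FR5", "FR2", "FR1", "normal", "R1", "R2", "R5")

R_CONDITIONS: tuple[str, ...] = ("R1", "R2", "R5")
FR_CONDITIONS: tuple[str, ...] = ("FR5", "FR2", "FR1")


@dataclass(eq=False)
class ExpressionMatrix:
    """Raw gene x sample counts plus sample metadata.

    ``counts``: genes (index) x samples (columns), non-negative ints.
    ``meta``: indexed by sample with columns ``condition`` and ``replicate``.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts < 0).any().any():
            raise ValueError("negative counts")
        if set(self.counts.columns) != set(self.meta.index):
            raise ValueError("counts columns and meta index disagree")
        if self.meta["condition"].value_counts().min() < 1:
            raise ValueError("every condition needs at least one replicate")

    def condition_samples(self, condition: str) -> list[str]:
        names = list(self.meta.index[self.meta["condition"] == condition])
        if not names:
            raise ValueError(f"condition {condition!r} not present")
        return names

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.meta["condition"]))

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


def normalize(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Counts-per-million per sample (scale-invariant per sample)."""
    lib = matrix.library_sizes()
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValueError(f"zero library size for samples {bad}")
    return matrix.counts / lib * 1e6


def condition_cpm(matrix: ExpressionMatrix, condition: str) -> pd.Series:
    """Mean CPM over the replicates of one condition."""
    cpm = normalize(matrix)
    return cpm[matrix.condition_samples(condition)].mean(axis=1)


def estimate_common_dispersion(matrix: ExpressionMatrix, min_mean: float = 1.0) -> float:
    """Conditional maximum-likelihood common NB dispersion from replicates.

    Counts are scaled to the mean library size, and within every condition
    with >= 2 replicates the likelihood of the counts *conditioned on their
    sum* (which does not depend on the mean) is summed over genes; the
    returned dispersion phi maximizes that conditional likelihood.  A simple
    moment estimator would be badly biased low with two replicates — a
    one-degree-of-freedom variance sits below its expectation more often
    than not.  Returns 0.0 when no condition is replicated.
    """
    from scipy.optimize import minimize_scalar
    from scipy.special import gammaln

    lib = matrix.library_sizes()
    scale = lib.mean() / lib
    groups: list[np.ndarray] = []
    for cond in matrix.conditions:
        cols = matrix.condition_samples(cond)
        if len(cols) < 2:
            continue
        adj = np.rint(matrix.counts[cols] * scale[cols]).to_numpy(np.int64)
        keep = adj.mean(axis=1) >= min_mean
        if keep.any():
            groups.append(adj[keep])
    if not groups:
        return 0.0

    def neg_cll(log_phi: float) -> float:
        r = np.exp(-log_phi)  # NB size parameter 1/phi
        total = 0.0
        for y in groups:
            n = y.shape[1]
            s = y.sum(axis=1)
            total += float(
                np.sum(gammaln(y + r) - gammaln(r) - gammaln(y + 1.0))
                - np.sum(gammaln(s + n * r) - gammaln(n * r) - gammaln(s + 1.0))
            )
        return -total

    res = minimize_scalar(neg_cll, bounds=(np.log(1e-4), np.log(10.0)), method="bounded")
    phi = float(np.exp(res.x))
    # treat a boundary solution at the tiny end as "effectively Poisson"
    return 0.0 if phi <= 2e-4 else phi


def differential_expression(
    matrix: ExpressionMatrix,
    cond_a: str,
    cond_b: str,
    min_fc: float = 2.0,
    p_thresh: float = 0.001,
    dispersion: float | str = "estimate",
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Two-condition differential expression calls.

    A gene is DE when ``|log2 FC| >= log2(min_fc)`` and ``p <= p_thresh``.
    FC is the ratio of pseudocounted mean CPMs (``cond_a`` over ``cond_b``).
    ``dispersion`` may be a fixed NB dispersion, or ``"estimate"`` to use the
    replicate-based common estimate (0 when unreplicated, which yields the
    conditioned exact 2x2 test on pooled counts and library totals).
    """
    cols_a = matrix.condition_samples(cond_a)
    cols_b = matrix.condition_samples(cond_b)
    if dispersion == "estimate":
        phi = estimate_common_dispersion(matrix)
    else:
        phi = float(dispersion)
        if phi < 0:
            raise ValueError("dispersion must be >= 0")
    lib = matrix.library_sizes()
    y_a = matrix.counts[cols_a].sum(axis=1)
    y_b = matrix.counts[cols_b].sum(axis=1)
    n_lib_a = int(lib[cols_a].sum())
    n_lib_b = int(lib[cols_b].sum())
    cpm_a = condition_cpm(matrix, cond_a) + pseudocount
    cpm_b = condition_cpm(matrix, cond_b) + pseudocount
    log2fc = np.log2(cpm_a / cpm_b)
    if phi > 0:
        # adjust pooled counts to a common per-replicate library size
        mean_lib = float(lib.mean())
        adj_a = np.rint(y_a.to_numpy() * (len(cols_a) * mean_lib) / n_lib_a).astype(np.int64)
        adj_b = np.rint(y_b.to_numpy() * (len(cols_b) * mean_lib) / n_lib_b).astype(np.int64)
        pvals = np.array(
            [nb_exact_test(a, b, len(cols_a), len(cols_b), phi) for a, b in zip(adj_a, adj_b)]
        )
    else:
        pvals = np.array(
            [
                fisher_exact_two_sided(a, n_lib_a - a, b, n_lib_b - b)
                for a, b in zip(y_a.to_numpy(), y_b.to_numpy())
            ]
        )
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": pvals,
            "de": (np.abs(log2fc) >= np.log2(min_fc)) & (pvals <= p_thresh),
        },
        index=matrix.counts.index,
    )
    out.index.name = "gene_id"
    return out


def de_union(
    matrix: ExpressionMatrix,
    pairs: list[tuple[str, str]] | None = None,
    min_fc: float = 2.0,
    p_thresh: float = 0.001,
    dispersion: float | str = "estimate",
) -> pd.DataFrame:
    """Union of pairwise DE calls over R-vs-FR sample pairs.

    ``pairs`` defaults to all (R, FR) condition combinations, oriented so
    positive log2 fold-changes mean higher under red light.  The per-gene
    representative ``log2fc``/``p``/``pair`` come from the most significant
    DE pair (or the most significant pair overall for non-DE genes).
    """
    if pairs is None:
        pairs = [
            (r, f)
            for r, f in product(R_CONDITIONS, FR_CONDITIONS)
            if r in matrix.conditions and f in matrix.conditions
        ]
    if not pairs:
        raise ValueError("no condition pairs to test")
    if dispersion == "estimate":
        dispersion = estimate_common_dispersion(matrix)
    per_pair = {
        pair: differential_expression(
            matrix, pair[0], pair[1], min_fc=min_fc, p_thresh=p_thresh, dispersion=dispersion
        )
        for pair in pairs
    }
    genes = matrix.counts.index
    de_any = np.zeros(len(genes), dtype=bool)
    best_key = np.full(len(genes), np.inf)
    best = pd.DataFrame(
        {"log2fc": 0.0, "p": 1.0, "pair": "", "de": False}, index=genes
    )
    for pair, res in per_pair.items():
        de_any |= res["de"].to_numpy()
        # DE pairs beat non-DE pairs; ties broken by smaller p
        key = res["p"].to_numpy() + np.where(res["de"].to_numpy(), 0.0, 2.0)
        better = key < best_key
        best_key = np.where(better, key, best_key)
        best.loc[better, "log2fc"] = res.loc[better, "log2fc"]
        best.loc[better, "p"] = res.loc[better, "p"]
        best.loc[better, "pair"] = f"{pair[0]}/{pair[1]}"
    best["de"] = de_any
    best["n_pairs_de"] = sum(res["de"].astype(int) for res in per_pair.values())
    best.index.name = "gene_id"
    return best


def expression_profiles(
    matrix: ExpressionMatrix,
    genes=None,
    pseudocount: float = 0.5,
    order: tuple[str, ...] = CONDITION_ORDER,
) -> pd.DataFrame:
    """Centered log2 fold-change profile of each gene over the sample order.

    Per gene: log2((CPM_cond + pseudo) / (CPM_normal + pseudo)) for each
    condition in ``order``, then mean-centered, so every row sums to 0 and
    the uncentered normal entry is 0 by construction.
    """
    cpm_by_cond = pd.DataFrame({c: condition_cpm(matrix, c) for c in order})
    ref = cpm_by_cond["normal"] + pseudocount
    prof = np.log2(cpm_by_cond.add(pseudocount).div(ref, axis=0))
    prof = prof.sub(prof.mean(axis=1), axis=0)
    if genes is not None:
        missing = [g for g in genes if g not in prof.index]
        if missing:
            raise KeyError(f"unknown genes: {missing[:5]}")
        prof = prof.loc[list(genes)]
    prof.index.name = "gene_id"
    return prof


@dataclass
class ClusterResult:
    """k-means partition of expression profiles.

    Cluster ids run 1..k and are renumbered by descending cluster size
    (ties by original label) so labels are stable across runs with the same
    seed.
    """

    labels: pd.Series
    centroids: np.ndarray
    inertia: float

    @property
    def k(self) -> int:
        return self.centroids.shape[0]


def cluster_profiles(
    profiles: pd.DataFrame,
    k: int = 16,
    seed: int = 0,
    n_init: int = 50,
) -> ClusterResult:
    """Partition profiles into ``k`` expression-pattern clusters by k-means."""
    if len(profiles) < k:
        raise ValueError(
            f"only {len(profiles)} profiles for k={k}; use a smaller k"
        )
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(profiles.to_numpy())
    sizes = np.bincount(raw, minlength=k)
    order = np.lexsort((np.arange(k), -sizes))  # descending size, stable
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    labels = pd.Series(relabel[raw], index=profiles.index, name="cluster")
    centroids = km.cluster_centers_[order]
    return ClusterResult(labels, centroids, float(km.inertia_))


def cluster_enrichment(
    cluster_genes,
    gene_terms: dict[str, set[str]],
    universe,
    adjust: bool = False,
) -> pd.DataFrame:
    """One-sided hypergeometric term enrichment of a gene cluster.

    For every term annotating >= 1 cluster gene, the upper-tail probability
    of drawing at least the observed number of term genes when sampling the
    cluster from the universe.  Sorted by (p, term); ties in the "most
    significant" sense resolve lexicographically.  Empty cluster -> empty
    report.
    """
    universe = sorted(set(universe))
    cluster = sorted(set(cluster_genes))
    if not set(cluster) <= set(universe):
        raise ValueError("cluster genes must be contained in the universe")
    cols = ["term", "n_cluster", "n_term", "p"]
    if not cluster:
        return pd.DataFrame(columns=cols)
    term_total: dict[str, int] = {}
    for g in universe:
        for t in gene_terms.get(g, ()):
            term_total[t] = term_total.get(t, 0) + 1
    term_hits: dict[str, int] = {}
    for g in cluster:
        for t in gene_terms.get(g, ()):
            term_hits[t] = term_hits.get(t, 0) + 1
    rows = [
        (t, k_hit, term_total[t], hypergeom_sf(k_hit, len(universe), term_total[t], len(cluster)))
        for t, k_hit in term_hits.items()
    ]
    out = pd.DataFrame(rows, columns=cols).sort_values(["p", "term"], kind="stable")
    if adjust and len(out):
        out["p_bh"] = false_discovery_control(out["p"].to_numpy(), method="bh")
    return out.reset_index(drop=True)


def most_significant_term(report: pd.DataFrame) -> str | None:
    """Top term of an enrichment report (lexicographic on p ties)."""
    if report.empty:
        return None
    return str(report.iloc[0]["term"])
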