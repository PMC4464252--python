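"""End-to-end orchestration: methylome comparisons, sRNA filtering,
differential expression, clustering, and the candidate cascade, on one
dataset with one parameter set.

Thresholds default to the analysis rule set (DMC: p 0.05, depth 3, diff
0.33; DMR: 3 DMCs, 300 bp, p 0.05; DE: fold-change 2, p 0.001; k = 16;
promoter/flank 2 kb; 20 bins)."""
from __future__ import annotations

from dataclasses import asdict, dataclass, field

import pandas as pd

from . import integration, methylome, srnaome, transcriptome
from .synthetic import SimulatedDataset


@dataclass
class PipelineParams:
    dmc_p: float = 0.05
    dmc_min_depth: int = 3
    dmc_min_diff: float = 0.33
    dmr_min_dmcs: int = 3
    dmr_max_gap: int = 300
    dmr_p: float = 0.05
    de_min_fc: float = 2.0
    de_p: float = 0.001
    de_dispersion: float | str = "estimate"
    k: int = 16
    kmeans_restarts: int = 50
    promoter_span: int = 2000
    flank: int = 2000
    bins: int = 20
    srna_min_count: int = 1
    require_expression: bool = True

    def validate(self) -> None:
        for name in ("dmc_p", "dmr_p", "de_p"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if not 0 <= self.dmc_min_diff <= 1:
            raise ValueError("dmc_min_diff must be in [0, 1]")
        if self.de_min_fc < 1:
            raise ValueError("de_min_fc must be >= 1")
        for name in ("dmc_min_depth", "dmr_min_dmcs", "dmr_max_gap", "k",
                     "promoter_span", "flank", "bins", "srna_min_count"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineParams":
        import dataclasses

        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - valid
        if unknown:
            raise ValueError(f"unknown pipeline parameter keys: {sorted(unknown)}")
        params = cls(**d)
        params.validate()
        return params


@dataclass
class PipelineResult:
    dmcs_r_vs_normal: pd.DataFrame
    dmcs_r_vs_fr: pd.DataFrame
    dmrs_r_vs_normal: pd.DataFrame
    dmrs_r_vs_fr: pd.DataFrame
    consensus_hypo: pd.DataFrame
    srnas_filtered: pd.DataFrame
    length_region: pd.DataFrame
    de: pd.DataFrame
    profiles: pd.DataFrame | None
    clusters: transcriptome.ClusterResult | None
    candidates: list[integration.CandidateGene]
    recovery: integration.RecoveryMetrics | None
    params: PipelineParams = field(default_factory=PipelineParams)


def run_pipeline(
    dataset: SimulatedDataset,
    params: PipelineParams | None = None,
    seed: int = 0,
) -> PipelineResult:
    """Full analysis of one dataset; deterministic given the k-means seed."""
    params = params or PipelineParams()
    params.validate()
    cyt = dataset.cytosines

    def _compare(cond_b: str):
        dmcs = methylome.call_dmcs(
            cyt, "R", cond_b,
            p_thresh=params.dmc_p,
            min_depth=params.dmc_min_depth,
            min_diff=params.dmc_min_diff,
        )
        dmrs = methylome.call_dmrs(
            dmcs, cyt, "R", cond_b,
            min_dmcs=params.dmr_min_dmcs,
            max_gap=params.dmr_max_gap,
            p_thresh=params.dmr_p,
        )
        return dmcs, dmrs

    dmcs_rn, dmrs_rn = _compare("normal")
    dmcs_rf, dmrs_rf = _compare("FR")
    consensus = methylome.consensus_hypo_dmrs(
        dmrs_rn[dmrs_rn["direction"] == "hypo"],
        dmrs_rf[dmrs_rf["direction"] == "hypo"],
    )

    filtered = srnaome.filter_perfect_unique(dataset.srnas)
    length_region = srnaome.characterize_length_region(filtered, dataset.annotation)

    de = transcriptome.de_union(
        dataset.expression,
        min_fc=params.de_min_fc,
        p_thresh=params.de_p,
        dispersion=params.de_dispersion,
    )
    de_genes = list(de.index[de["de"]])
    profiles = clusters = None
    if de_genes:
        profiles = transcriptome.expression_profiles(dataset.expression, de_genes)
        if len(profiles) >= params.k:
            clusters = transcriptome.cluster_profiles(
                profiles, k=params.k, seed=seed, n_init=params.kmeans_restarts
            )

    candidates = integration.nominate_candidates(
        dataset.annotation,
        dataset.metabolic_genes,
        consensus,
        filtered,
        dataset.srna_samples,
        de,
        min_count=params.srna_min_count,
        require_expression=params.require_expression,
    )
    recovery = None
    if dataset.truth is not None and dataset.truth.planted_genes:
        recovery = integration.evaluate_recovery(
            [c.gene_id for c in candidates], dataset.truth.planted_genes
        )
    return PipelineResult(
        dmcs_r_vs_normal=dmcs_rn,
        dmcs_r_vs_fr=dmcs_rf,
        dmrs_r_vs_normal=dmrs_rn,
        dmrs_r_vs_fr=dmrs_rf,
        consensus_hypo=consensus,
        srnas_filtered=filtered,
        length_region=length_region,
        de=de,
        profiles=profiles,
        clusters=clusters,
        candidates=candidates,
        recovery=recovery,
        params=params,
    )
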