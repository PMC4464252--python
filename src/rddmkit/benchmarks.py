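"""Self-contained evaluation scenarios for the pipeline.

Each function builds its inputs with the synthetic generator (or the packaged
reference table), runs the relevant part of the analysis, and returns the
measured quantity.  All randomness is derived from a single base seed; the
sub-seed arithmetic keeps every derived seed well below 2**31.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import io, methylome, srnaome, transcriptome
from .pipeline import run_pipeline
from .synthetic import SimulationConfig, emit_table3_fixture, simulate


def _sub_seed(base: int, offset: int) -> int:
    return int((base * 1009 + offset) % (2**31 - 1))


def table3_fractions() -> dict[str, float]:
    """Headline percentages computed from the packaged reference table."""
    return srnaome.summarize_fractions(emit_table3_fixture())


def table3_additivity_violations() -> int:
    """Rows of the reference table violating any hierarchy identity."""
    t = emit_table3_fixture()
    bad = (
        (t["mapped"] != t["intergenic"] + t["genic"])
        | (t["genic"] != t["promoter"] + t["gene_body"])
        | (t["gene_body"] != t["intron"] + t["exon"])
    )
    return int(bad.sum())


def null_dmc_fpr(base_seed: int, n_seeds: int = 10) -> float:
    """Empirical size of the DMC Fisher test on a binomial null methylome.

    No planted effects, no overdispersion (the test's own sampling model),
    no ratio-difference filter: the fraction of depth-eligible cytosines
    with p <= 0.05.  The discrete test is conservative, so this sits at or
    below the nominal level.
    """
    rates = []
    for i in range(n_seeds):
        cfg = SimulationConfig(
            seed=_sub_seed(base_seed, i),
            n_chromosomes=1, chromosome_length=400_000, n_genes=60,
            n_planted=0, n_metabolic=10, n_srnas=50,
            meth_overdispersion=0.0,
        )
        cyt = simulate(cfg).cytosines
        m_a, u_a = cyt.pooled("R")
        m_b, u_b = cyt.pooled("normal")
        eligible = ((m_a + u_a) >= 3) & ((m_b + u_b) >= 3)
        dmcs = methylome.call_dmcs(cyt, "R", "normal", min_diff=0.0)
        rates.append(len(dmcs) / int(eligible.sum()))
    return float(np.mean(rates))


def candidate_recovery(base_seed: int, n_seeds: int = 10) -> tuple[float, float]:
    """Seed-averaged (precision, recall) of the full cascade on the default
    scenario: 20 planted RdDM targets among 500 genes."""
    precisions, recalls = [], []
    for i in range(n_seeds):
        seed = _sub_seed(base_seed, 100 + i)
        dataset = simulate(SimulationConfig(seed=seed))
        result = run_pipeline(dataset, seed=seed)
        precisions.append(result.recovery.precision)
        recalls.append(result.recovery.recall)
    return float(np.mean(precisions)), float(np.mean(recalls))


def de_benchmark(base_seed: int, n_seeds: int = 10, fc: float = 2.5) -> tuple[float, float]:
    """Seed-averaged (recall, FPR) of the union DE set for planted ``fc``-fold
    red-responsive genes at the standard thresholds (2-fold, p <= 0.001)."""
    recalls, fprs = [], []
    for i in range(n_seeds):
        seed = _sub_seed(base_seed, 200 + i)
        dataset = simulate(SimulationConfig(seed=seed, expression_fc=fc))
        de = transcriptome.de_union(dataset.expression)
        planted = set(dataset.truth.planted_genes)
        null = [g for g in de.index if g not in planted]
        recalls.append(float(de.loc[sorted(planted), "de"].mean()))
        fprs.append(float(de.loc[null, "de"].mean()))
    return float(np.mean(recalls)), float(np.mean(fprs))


def metagene_flatness(base_seed: int, level: float = 0.5) -> float:
    """Largest |bin - level| over all 60 bins x 3 contexts for a methylome
    generated uniformly at ``level`` (binomial counts, isolating the binning
    and weighting arithmetic from biological noise)."""
    cfg = SimulationConfig(
        seed=_sub_seed(base_seed, 300),
        n_planted=0, n_metabolic=10, n_srnas=50,
        context_means={"CG": level, "CHG": level, "CHH": level},
        meth_overdispersion=0.0,
    )
    dataset = simulate(cfg)
    worst = 0.0
    for context in methylome.CONTEXTS:
        prof = methylome.metagene_profile(
            dataset.annotation, dataset.cytosines, context, "normal"
        )
        worst = max(worst, float(np.nanmax(np.abs(prof.values - level))))
    return worst


def kmeans_archetype_ari(base_seed: int, n_per_cluster: int = 25) -> float:
    """Adjusted Rand index of k-means against 16 planted profile archetypes
    with coordinate noise at one fifth of the minimum archetype separation."""
    rng = np.random.default_rng(_sub_seed(base_seed, 400))
    arch = rng.normal(0.0, 1.0, size=(16, 7))
    arch -= arch.mean(axis=1, keepdims=True)
    min_dist = min(
        float(np.linalg.norm(arch[i] - arch[j]))
        for i in range(16) for j in range(i + 1, 16)
    )
    sigma = min_dist / 5.0
    profs, truth = [], []
    for a in range(16):
        for _ in range(n_per_cluster):
            profs.append(arch[a] + rng.normal(0.0, sigma, 7))
            truth.append(a)
    frame = pd.DataFrame(profs, index=[f"g{i}" for i in range(len(profs))])
    result = transcriptome.cluster_profiles(frame, k=16, seed=_sub_seed(base_seed, 401))
    return float(adjusted_rand_score(truth, result.labels.to_numpy()))


def determinism_check(base_seed: int, workdir) -> bool:
    """Simulate and analyse the same seed twice into separate directories;
    true when every emitted data file is byte-identical."""
    from pathlib import Path

    cfg = SimulationConfig(
        seed=_sub_seed(base_seed, 500),
        n_chromosomes=1, chromosome_length=400_000, n_genes=50,
        n_planted=3, n_metabolic=10, n_srnas=200,
    )
    digests = []
    for run in ("a", "b"):
        out = Path(workdir) / run
        dataset = simulate(cfg)
        paths = io.write_dataset(dataset, out)
        result = run_pipeline(dataset, seed=cfg.seed)
        result.de.to_csv(out / "de.tsv", sep="\t", float_format="%.6g")
        io.write_dmrs_bed(result.dmrs_r_vs_normal, out / "dmrs.bed")
        result.consensus_hypo.to_csv(out / "consensus.tsv", sep="\t", index=False, float_format="%.6g")
        paths.update({"de": out / "de.tsv", "dmrs": out / "dmrs.bed", "cons": out / "consensus.tsv"})
        digests.append({k: io.sha256_file(p) for k, p in sorted(paths.items())})
    return digests[0] == digests[1]
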