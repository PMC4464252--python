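"""Synthetic multi-omics data with planted RdDM-regulated genes.

The generator emulates the data regime the analysis assumes: three light
conditions (normal white light, far-red "FR", red "R") with two replicates
for methylome and sRNAome; a seven-sample expression time course (FR5, FR2,
FR1, normal, R1, R2, R5) with two replicates; CG/CHG/CHH methylation with
condition-specific promoter hypo-methylation under red light; a 24-nt
dominant sRNA length distribution with planted FR-specific AGO4-compatible
sRNAs; and negative-binomial expression counts with red-up-regulated planted
genes.

Planted RdDM target windows sit immediately upstream of the TSS.  Under
normal/FR they are CHH-hypermethylated (siRNA-maintained level, default
0.5); under R the CHH and CHG means drop by the planted hypo effect
(default 0.4, taking CHG from its 0.4 baseline to 0).  Every planted gene
also carries FR/normal-specific 24-nt sRNAs with AGO4-compatible 5' bases
embedded in its window, and a monotone red-light expression ramp.

A single integer seed fully determines every output.
"""
from __future__ import annotations

import importlib.resources
import json
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import pandas as pd

from . import annotation as ann_mod
from .methylome import CytosineTable
from .transcriptome import ExpressionMatrix

_ALPHABET = np.array(list("ACGT"))
_AGO4_STARTS = np.array(list("AGT"))

#: methylome / sRNAome conditions
METH_CONDITIONS: tuple[str, ...] = ("normal", "FR", "R")
EXPR_CONDITIONS: tuple[str, ...] = ("FR5", "FR2", "FR1", "normal", "R1", "R2", "R5")

#: day-ramp exponents applied to the planted fold-change at days 1, 2, 5
RAMP: dict[str, float] = {"1": 1 / 3, "2": 2 / 3, "5": 1.0}


class SimulationError(ValueError):
    """Raised for infeasible simulation configurations."""


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; defaults are the study conditions.

    Methylation counts are beta-binomial with context-specific means and a
    common overdispersion (the intra-class correlation of per-replicate
    methylation proportions); read depth is 1 + Poisson(depth_mean - 1).
    Expression counts are negative binomial (variance mu + phi mu^2).
    """

    seed: int = 0
    # genome
    n_chromosomes: int = 2
    chromosome_length: int = 1_800_000
    n_genes: int = 500
    gene_length_range: tuple[int, int] = (1000, 3000)
    exons_per_gene: tuple[int, int] = (1, 4)
    promoter_span: int = 2000
    te_fraction: float = 0.05
    # methylome
    meth_replicates: int = 2
    context_probs: dict = field(default_factory=lambda: {"CG": 0.25, "CHG": 0.25, "CHH": 0.5})
    context_means: dict = field(default_factory=lambda: {"CG": 0.8, "CHG": 0.4, "CHH": 0.1})
    meth_overdispersion: float = 0.1
    depth_mean: float = 10.0
    cytosine_spacing: float = 15.0
    # planted RdDM targets
    n_planted: int = 20
    planted_dmr_width: int = 1000
    planted_hypo_effect: float = 0.4
    planted_chh_target_level: float = 0.5
    n_metabolic: int = 100
    # sRNAome
    n_srnas: int = 4000
    srna_length_weights: dict | None = None  # default: reference table marginals
    srna_log_mean_count: float = np.log(10.0)
    srna_log_sd_count: float = 1.0
    imperfect_fraction: float = 0.05
    planted_srnas_per_gene: int = 3
    planted_srna_count_mean: float = 30.0
    # expression
    expr_replicates: int = 2
    expr_log_mean: float = 4.0
    expr_log_sd: float = 1.0
    nb_dispersion: float = 0.1
    expression_fc: float = 3.0

    def validate(self) -> None:
        for name, probs in (("context_probs", self.context_probs),):
            if abs(sum(probs.values()) - 1.0) > 1e-9 or min(probs.values()) < 0:
                raise SimulationError(f"{name} must be a probability distribution")
        for ctx, m in self.context_means.items():
            if not 0.0 <= m <= 1.0:
                raise SimulationError(f"context mean for {ctx} outside [0, 1]")
        if not 0.0 <= self.meth_overdispersion < 1.0:
            raise SimulationError("meth_overdispersion must be in [0, 1)")
        if not 0.0 <= self.planted_chh_target_level <= 1.0:
            raise SimulationError("planted_chh_target_level outside [0, 1]")
        if self.planted_hypo_effect > self.planted_chh_target_level + 1e-12:
            raise SimulationError("planted hypo effect exceeds the CHH window level")
        if self.planted_hypo_effect > self.context_means["CHG"] + 1e-12:
            raise SimulationError("planted hypo effect exceeds the CHG baseline")
        if self.planted_dmr_width > self.promoter_span:
            raise SimulationError("planted window wider than the promoter")
        if self.n_planted > self.n_genes or self.n_metabolic > self.n_genes:
            raise SimulationError("planted/metabolic gene counts exceed n_genes")
        if self.n_metabolic < self.n_planted:
            raise SimulationError("metabolic set smaller than the planted set")
        if self.expression_fc < 1.0:
            raise SimulationError("expression_fc must be >= 1")
        if not 0.0 <= self.imperfect_fraction < 1.0:
            raise SimulationError("imperfect_fraction must be in [0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gene_length_range"] = list(self.gene_length_range)
        d["exons_per_gene"] = list(self.exons_per_gene)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        valid = {f.name for f in fields(cls)}
        unknown = set(d) - valid
        if unknown:
            raise SimulationError(f"unknown configuration keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("gene_length_range", "exons_per_gene"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class GroundTruth:
    """Planted signal, re-derivable from the emitted files."""

    planted_genes: list[str]
    dmrs: list[dict]       # gene_id, chrom, start, end, level_diff per context
    srnas: list[dict]      # sequence, gene_id, chrom, start, present/absent conditions
    de_genes: dict         # gene_id -> true fold change (red day 5 vs normal)
    metabolic_genes: list[str]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


@dataclass
class SimulatedDataset:
    annotation: ann_mod.GenomeAnnotation
    cytosines: CytosineTable
    srnas: pd.DataFrame
    srna_samples: dict[str, str]
    expression: ExpressionMatrix
    metabolic_genes: list[str]
    truth: GroundTruth
    config: SimulationConfig


def emit_table3_fixture() -> pd.DataFrame:
    """The packaged reference length x region table of distinct sRNAs."""
    ref = importlib.resources.files("rddmkit.data") / "srna_length_region_reference.tsv"
    with importlib.resources.as_file(ref) as path:
        table = pd.read_csv(path, sep="\t", index_col="length")
    return table


def simulate(config: SimulationConfig | None = None, seed: int | None = None) -> SimulatedDataset:
    """Generate a full dataset with planted signal and ground truth."""
    config = config or SimulationConfig()
    if seed is not None:
        config = SimulationConfig.from_dict({**config.to_dict(), "seed": int(seed)})
    config.validate()
    rng = np.random.default_rng(config.seed)

    annotation = _simulate_annotation(config, rng)
    planted_genes, windows = _choose_planted(annotation, config, rng)
    cytosines, dmr_truth = _simulate_methylome(annotation, windows, config, rng)
    srnas, srna_samples, srna_truth = _simulate_srnas(annotation, windows, config, rng)
    expression, de_truth = _simulate_expression(annotation, planted_genes, config, rng)
    others = [g for g in annotation.genes["gene_id"] if g not in set(planted_genes)]
    extra = rng.choice(len(others), size=config.n_metabolic - config.n_planted, replace=False)
    metabolic = sorted(planted_genes + [others[i] for i in sorted(extra)])
    truth = GroundTruth(
        planted_genes=sorted(planted_genes),
        dmrs=dmr_truth,
        srnas=srna_truth,
        de_genes=de_truth,
        metabolic_genes=metabolic,
    )
    return SimulatedDataset(
        annotation=annotation,
        cytosines=cytosines,
        srnas=srnas,
        srna_samples=srna_samples,
        expression=expression,
        metabolic_genes=metabolic,
        truth=truth,
        config=config,
    )


# ---------------------------------------------------------------------------
# genome layout


def _simulate_annotation(config: SimulationConfig, rng: np.random.Generator) -> ann_mod.GenomeAnnotation:
    chroms = {f"chr{i + 1}": config.chromosome_length for i in range(config.n_chromosomes)}
    per_chrom = np.full(config.n_chromosomes, config.n_genes // config.n_chromosomes)
    per_chrom[: config.n_genes % config.n_chromosomes] += 1
    width = len(str(config.n_genes))
    gene_rows: list[tuple] = []
    exon_rows: list[tuple] = []
    te_rows: list[tuple] = []
    gid = 0
    lo, hi = config.gene_length_range
    for ci, (chrom, clen) in enumerate(chroms.items()):
        cursor = config.promoter_span + int(rng.integers(200, 800))
        for _ in range(per_chrom[ci]):
            glen = int(rng.integers(lo, hi + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            start, end = cursor, cursor + glen
            if end + config.promoter_span >= clen:
                raise SimulationError(
                    "chromosome_length too small for n_genes at this spacing"
                )
            gid += 1
            gene_id = f"g{gid:0{width}d}"
            gene_rows.append((gene_id, chrom, start, end, strand))
            exon_rows.extend(_make_exons(gene_id, chrom, start, end, config, rng))
            gap = config.promoter_span + int(rng.integers(1000, 2500))
            # drop a TE into some intergenic gaps
            if rng.random() < config.te_fraction * 10:
                te_len = int(rng.integers(200, min(1500, gap - config.promoter_span - 100)))
                te_start = end + config.promoter_span + int(
                    rng.integers(0, max(1, gap - config.promoter_span - te_len))
                )
                te_rows.append((chrom, te_start, te_start + te_len))
            cursor = end + gap
    annotation = ann_mod.GenomeAnnotation(
        chromosomes=chroms,
        genes=pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end", "strand"]),
        exons=pd.DataFrame(exon_rows, columns=["gene_id", "chrom", "start", "end"]),
        tes=pd.DataFrame(te_rows, columns=["chrom", "start", "end"]),
    )
    return ann_mod.derive_promoters(annotation, config.promoter_span)


def _make_exons(gene_id, chrom, start, end, config, rng) -> list[tuple]:
    k = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
    length = end - start
    if k == 1 or length < 2 * k * 50:
        return [(gene_id, chrom, start, end)]
    # alternate exon/intron segments, first and last are exons
    n_seg = 2 * k - 1
    w = rng.dirichlet(np.full(n_seg, 2.0)) * (length - n_seg * 50) + 50
    bounds = start + np.concatenate([[0], np.cumsum(w)]).astype(np.int64)
    bounds[-1] = end
    return [
        (gene_id, chrom, int(bounds[i]), int(bounds[i + 1]))
        for i in range(0, n_seg, 2)
    ]


def _choose_planted(annotation, config, rng):
    genes = annotation.genes
    idx = np.sort(rng.choice(len(genes), size=config.n_planted, replace=False))
    planted = [genes["gene_id"].iloc[i] for i in idx]
    windows: list[dict] = []
    for i in idx:
        row = genes.iloc[i]
        w = config.planted_dmr_width
        if row["strand"] == "+":
            start, end = row["start"] - w, row["start"]
        else:
            start, end = row["end"], row["end"] + w
        windows.append(
            {"gene_id": row["gene_id"], "chrom": row["chrom"], "start": int(start), "end": int(end)}
        )
    return planted, windows


# ---------------------------------------------------------------------------
# methylome


def _simulate_methylome(annotation, windows, config, rng):
    contexts = np.array(sorted(config.context_probs))
    ctx_p = np.array([config.context_probs[c] for c in contexts])
    chrom_names: list[np.ndarray] = []
    positions: list[np.ndarray] = []
    for chrom, clen in annotation.chromosomes.items():
        n_sites = int(clen / config.cytosine_spacing)
        gaps = rng.exponential(config.cytosine_spacing, size=n_sites)
        pos = np.unique(np.cumsum(gaps).astype(np.int64))
        pos = pos[pos < clen]
        chrom_names.append(np.full(pos.size, chrom, dtype=object))
        positions.append(pos)
    chrom_arr = np.concatenate(chrom_names)
    pos_arr = np.concatenate(positions)
    n = pos_arr.size
    ctx_arr = contexts[rng.choice(len(contexts), size=n, p=ctx_p)]
    strand_arr = np.where(rng.random(n) < 0.5, "+", "-")

    base_mean = np.array([config.context_means[c] for c in ctx_arr])
    in_window = np.zeros(n, dtype=bool)
    window_sets: dict[str, list] = {}
    for w in windows:
        window_sets.setdefault(w["chrom"], []).append((w["start"], w["end"]))
    from . import intervals as iv

    for chrom, pairs in window_sets.items():
        sel = chrom_arr == chrom
        iset = iv.merge([p[0] for p in pairs], [p[1] for p in pairs])
        in_window[sel] = iv.contains(iset, pos_arr[sel])

    mean_non_r = base_mean.copy()
    mean_non_r[in_window & (ctx_arr == "CHH")] = config.planted_chh_target_level
    mean_r = mean_non_r.copy()
    drop = in_window & np.isin(ctx_arr, ("CHH", "CHG"))
    mean_r[drop] = mean_r[drop] - config.planted_hypo_effect

    data = {
        "chrom": chrom_arr,
        "pos": pos_arr,
        "strand": strand_arr,
        "context": ctx_arr,
    }
    samples: dict[str, str] = {}
    for cond in METH_CONDITIONS:
        mean = mean_r if cond == "R" else mean_non_r
        for rep in range(1, config.meth_replicates + 1):
            name = f"{cond}_{rep}"
            samples[name] = cond
            depth = 1 + rng.poisson(max(config.depth_mean - 1.0, 0.0), size=n)
            p = _beta_binomial_p(mean, config.meth_overdispersion, rng)
            meth = rng.binomial(depth, p)
            data[f"meth_{name}"] = meth
            data[f"unmeth_{name}"] = depth - meth
    table = CytosineTable(pd.DataFrame(data), samples)
    dmr_truth = [
        {
            **w,
            "level_diff": {"CHH": config.planted_hypo_effect, "CHG": config.planted_hypo_effect},
        }
        for w in windows
    ]
    return table, dmr_truth


def _beta_binomial_p(mean: np.ndarray, rho: float, rng: np.random.Generator) -> np.ndarray:
    p = np.clip(mean, 0.0, 1.0).astype(float)
    if rho <= 0:
        return p
    inner = (p > 0) & (p < 1)
    if inner.any():
        a = p[inner] * (1.0 - rho) / rho
        b = (1.0 - p[inner]) * (1.0 - rho) / rho
        p = p.copy()
        p[inner] = rng.beta(a, b)
    return p


# ---------------------------------------------------------------------------
# sRNAome


def _simulate_srnas(annotation, windows, config, rng):
    lengths = np.arange(20, 31)
    if config.srna_length_weights is None:
        weights = emit_table3_fixture()["mapped"].to_numpy(float)
    else:
        weights = np.array([config.srna_length_weights.get(int(l), 0.0) for l in lengths])
    weights = weights / weights.sum()

    samples = {
        f"{cond}_{rep}": cond
        for cond in METH_CONDITIONS
        for rep in range(1, config.meth_replicates + 1)
    }
    chrom_list = list(annotation.chromosomes)
    seen: set[str] = set()
    rows: list[dict] = []

    def draw_sequence(length: int, first: str | None = None) -> str:
        while True:
            letters = _ALPHABET[rng.integers(0, 4, size=length)]
            if first is not None:
                letters[0] = first
            seq = "".join(letters)
            if seq not in seen:
                seen.add(seq)
                return seq

    n_imperfect = int(round(config.n_srnas * config.imperfect_fraction))
    for i in range(config.n_srnas):
        length = int(rng.choice(lengths, p=weights))
        chrom = chrom_list[int(rng.integers(0, len(chrom_list)))]
        start = int(rng.integers(0, annotation.chromosomes[chrom] - length))
        lam = rng.lognormal(config.srna_log_mean_count, config.srna_log_sd_count)
        counts = {f"count_{s}": int(rng.poisson(lam)) for s in samples}
        imperfect = i < n_imperfect
        rows.append(
            {
                "sequence": draw_sequence(length),
                "chrom": chrom,
                "start": start,
                "strand": "+" if rng.random() < 0.5 else "-",
                "nhits": 2 if (imperfect and rng.random() < 0.5) else 1,
                "mismatches": 0,
                "gaps": 0,
                **counts,
            }
        )
        if imperfect and rows[-1]["nhits"] == 1:
            rows[-1]["mismatches"] = 1

    srna_truth: list[dict] = []
    for w in windows:
        width = w["end"] - w["start"]
        margin = max(1, int(width * 0.2))
        lo = w["start"] + margin
        hi = max(lo + 1, w["end"] - margin - 24)
        for _ in range(config.planted_srnas_per_gene):
            start = int(rng.integers(lo, hi))
            seq = draw_sequence(24, first=str(rng.choice(_AGO4_STARTS)))
            counts = {}
            for s, cond in samples.items():
                if cond == "R":
                    counts[f"count_{s}"] = 0
                else:
                    counts[f"count_{s}"] = int(max(1, rng.poisson(config.planted_srna_count_mean)))
            rows.append(
                {
                    "sequence": seq,
                    "chrom": w["chrom"],
                    "start": start,
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "nhits": 1,
                    "mismatches": 0,
                    "gaps": 0,
                    **counts,
                }
            )
            srna_truth.append(
                {
                    "sequence": seq,
                    "gene_id": w["gene_id"],
                    "chrom": w["chrom"],
                    "start": start,
                    "present": ["normal", "FR"],
                    "absent": ["R"],
                }
            )
    records = pd.DataFrame(rows).sort_values(["chrom", "start", "sequence"], kind="stable")
    return records.reset_index(drop=True), samples, srna_truth


# ---------------------------------------------------------------------------
# expression


def _simulate_expression(annotation, planted_genes, config, rng):
    genes = list(annotation.genes["gene_id"])
    n = len(genes)
    base = rng.lognormal(config.expr_log_mean, config.expr_log_sd, size=n)
    planted_set = set(planted_genes)
    is_planted = np.array([g in planted_set for g in genes])

    sample_names: list[str] = []
    meta_rows: list[tuple] = []
    cols: dict[str, np.ndarray] = {}
    for cond in EXPR_CONDITIONS:
        mult = np.ones(n)
        if cond != "normal":
            day = cond.lstrip("RF")
            exponent = RAMP[day]
            factor = config.expression_fc ** exponent
            mult = np.where(is_planted, factor if cond.startswith("R") else 1.0 / factor, 1.0)
        for rep in range(1, config.expr_replicates + 1):
            name = f"{cond}_{rep}"
            sample_names.append(name)
            meta_rows.append((name, cond, rep))
            mu = base * mult
            if config.nb_dispersion > 0:
                shape = 1.0 / config.nb_dispersion
                lam = rng.gamma(shape, mu * config.nb_dispersion)
                cols[name] = rng.poisson(lam)
            else:
                cols[name] = rng.poisson(mu)
    counts = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
    meta = pd.DataFrame(meta_rows, columns=["sample", "condition", "replicate"]).set_index("sample")
    de_truth = {g: float(config.expression_fc) for g in sorted(planted_set)}
    return ExpressionMatrix(counts, meta), de_truth
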