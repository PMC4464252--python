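"""Readers and writers for the on-disk dialects, plus configuration and run
manifests.

Dialects
--------
* annotation: GFF3 with ``gene``, ``exon`` and ``transposable_element``
  features and ``##sequence-region`` pragmas (1-based inclusive, converted
  to 0-based half-open in memory);
* cytosine report: TSV ``chrom  pos(1-based)  strand  context`` followed by
  ``meth_<sample>`` / ``unmeth_<sample>`` count columns — the layout of a
  per-sample Bismark-style cytosine report minus the trinucleotide column,
  with samples side by side;
* sRNA records: TSV ``sequence chrom start(0-based) strand nhits mismatches
  gaps count_<sample>...``;
* expression: TSV gene x sample count matrix.

Sample columns are named ``<condition>_<replicate>``; conditions are
recovered by splitting on the last underscore.

All writers emit newline- and column-order-stable output so identical runs
produce byte-identical files.
"""
from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import GenomeAnnotation
from .methylome import CytosineTable
from .pipeline import PipelineParams
from .synthetic import GroundTruth, SimulatedDataset, SimulationConfig
from .transcriptome import ExpressionMatrix


class FormatError(ValueError):
    """Raised when an input file violates its dialect."""


def condition_of(sample: str) -> str:
    """Condition encoded in a ``<condition>_<replicate>`` sample name."""
    cond, _, rep = sample.rpartition("_")
    if not cond or not rep.isdigit():
        raise FormatError(f"sample name {sample!r} is not <condition>_<replicate>")
    return cond


# ---------------------------------------------------------------------------
# GFF3


def write_gff3(annotation: GenomeAnnotation, path) -> None:
    lines = ["##gff-version 3"]
    for chrom in sorted(annotation.chromosomes):
        lines.append(f"##sequence-region {chrom} 1 {annotation.chromosomes[chrom]}")
    for row in annotation.genes.itertuples():
        lines.append(
            f"{row.chrom}\trddmkit\tgene\t{row.start + 1}\t{row.end}\t.\t{row.strand}\t.\tID={row.gene_id}"
        )
        exons = annotation.exons[annotation.exons["gene_id"] == row.gene_id]
        for j, ex in enumerate(exons.sort_values("start").itertuples(), start=1):
            lines.append(
                f"{row.chrom}\trddmkit\texon\t{ex.start + 1}\t{ex.end}\t.\t{row.strand}\t.\t"
                f"ID={row.gene_id}.exon{j};Parent={row.gene_id}"
            )
    for i, te in enumerate(annotation.tes.itertuples(), start=1):
        lines.append(
            f"{te.chrom}\trddmkit\ttransposable_element\t{te.start + 1}\t{te.end}\t.\t.\t.\tID=te{i:05d}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path) -> GenomeAnnotation:
    path = Path(path)
    chromosomes: dict[str, int] = {}
    for line in path.read_text().splitlines():
        if line.startswith("##sequence-region"):
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(f"malformed sequence-region pragma: {line!r}")
            chromosomes[parts[1]] = int(parts[3])
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    gene_rows, exon_rows, te_rows = [], [], []
    for feat in db.features_of_type("gene"):
        gene_rows.append((feat.id, feat.seqid, feat.start - 1, feat.end, feat.strand))
    for feat in db.features_of_type("exon"):
        parents = feat.attributes.get("Parent")
        if not parents:
            raise FormatError(f"exon without Parent at {feat.seqid}:{feat.start}")
        exon_rows.append((parents[0], feat.seqid, feat.start - 1, feat.end))
    for feat in db.features_of_type("transposable_element"):
        te_rows.append((feat.seqid, feat.start - 1, feat.end))
    if not chromosomes:
        raise FormatError("GFF3 lacks ##sequence-region pragmas")
    return GenomeAnnotation(
        chromosomes=chromosomes,
        genes=pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end", "strand"]),
        exons=pd.DataFrame(exon_rows, columns=["gene_id", "chrom", "start", "end"]),
        tes=pd.DataFrame(te_rows, columns=["chrom", "start", "end"]),
    )


def write_promoters_bed(annotation: GenomeAnnotation, path) -> None:
    """Derived promoters as BED6 (name = gene id, score 0)."""
    if annotation.promoters is None:
        raise ValueError("promoters not derived")
    rows = annotation.promoters.sort_values(["chrom", "start"])
    with open(path, "w") as fh:
        for r in rows.itertuples():
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene_id}\t0\t{r.strand}\n")


# ---------------------------------------------------------------------------
# cytosine report


def write_cytosine_table(table: CytosineTable, path) -> None:
    df = table.data.copy()
    df["pos"] = df["pos"] + 1  # 1-based on disk
    cols = ["chrom", "pos", "strand", "context"]
    for s in table.samples:
        cols += [f"meth_{s}", f"unmeth_{s}"]
    df[cols].to_csv(path, sep="\t", index=False)


def read_cytosine_table(path, samples: dict[str, str] | None = None) -> CytosineTable:
    df = pd.read_csv(path, sep="\t")
    required = ["chrom", "pos", "strand", "context"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"cytosine report missing columns {missing}")
    if samples is None:
        names = [c[len("meth_"):] for c in df.columns if c.startswith("meth_")]
        samples = {s: condition_of(s) for s in names}
    df["pos"] = df["pos"].astype(np.int64) - 1
    if (df["pos"] < 0).any():
        raise FormatError("cytosine positions must be 1-based (>= 1) on disk")
    return CytosineTable(df, samples)


# ---------------------------------------------------------------------------
# sRNA records


def write_srnas(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False)


def read_srnas(path, samples: dict[str, str] | None = None):
    df = pd.read_csv(path, sep="\t")
    required = ["sequence", "chrom", "start", "strand", "nhits", "mismatches", "gaps"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"sRNA table missing columns {missing}")
    if samples is None:
        names = [c[len("count_"):] for c in df.columns if c.startswith("count_")]
        samples = {s: condition_of(s) for s in names}
    return df, samples


# ---------------------------------------------------------------------------
# expression


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.counts.to_csv(path, sep="\t")


def read_expression(path) -> ExpressionMatrix:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index.name = "gene_id"
    meta = pd.DataFrame(
        {
            "condition": [condition_of(s) for s in counts.columns],
            "replicate": [int(s.rpartition("_")[2]) for s in counts.columns],
        },
        index=counts.columns,
    )
    return ExpressionMatrix(counts, meta)


# ---------------------------------------------------------------------------
# DMRs, tables, truth


def write_dmrs_bed(dmrs: pd.DataFrame, path) -> None:
    """DMRs as BED6+3: name = context:direction, score = -log10 p, then
    member-DMC count and the two condition levels."""
    with open(path, "w") as fh:
        for r in dmrs.itertuples():
            score = 0.0 if r.p <= 0 else min(1000.0, -np.log10(r.p))
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.context}:{r.direction}\t{score:.3f}\t.\t"
                f"{r.n_dmcs}\t{r.level_a:.6g}\t{r.level_b:.6g}\n"
            )


def write_length_region_table(table: pd.DataFrame, path) -> None:
    disp = table.copy()
    disp.columns = ["Mapped", "Intergenic", "Genic", "Promoter", "G. Body", "Intron", "Exon"]
    disp.index = [f"{i} bp" for i in disp.index]
    disp.index.name = "Length"
    disp.to_csv(path, sep="\t")


def write_truth(truth: GroundTruth, path) -> None:
    Path(path).write_text(truth.to_json() + "\n")


def read_truth(path) -> GroundTruth:
    return GroundTruth.from_json(Path(path).read_text())


def write_dataset(dataset: SimulatedDataset, outdir) -> dict[str, Path]:
    """Write every component of a simulated dataset; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotation": outdir / "annotation.gff3",
        "cytosines": outdir / "cytosines.tsv",
        "srnas": outdir / "srnas.tsv",
        "expression": outdir / "expression.tsv",
        "metabolic": outdir / "metabolic_genes.txt",
        "truth": outdir / "truth.json",
    }
    write_gff3(dataset.annotation, paths["annotation"])
    write_cytosine_table(dataset.cytosines, paths["cytosines"])
    write_srnas(dataset.srnas, paths["srnas"])
    write_expression(dataset.expression, paths["expression"])
    paths["metabolic"].write_text("\n".join(dataset.metabolic_genes) + "\n")
    write_truth(dataset.truth, paths["truth"])
    return paths


# ---------------------------------------------------------------------------
# configuration and manifests


def read_config(path) -> tuple[SimulationConfig, PipelineParams]:
    """Parse a YAML config with optional ``simulation:`` and ``pipeline:``
    sections; unknown keys are rejected, an empty file gives all defaults."""
    text = Path(path).read_text()
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark is not None else ""
        raise FormatError(f"malformed config file{line}: {exc}") from exc
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise FormatError("config must be a mapping")
    unknown = set(doc) - {"simulation", "pipeline"}
    if unknown:
        raise FormatError(f"unknown top-level config sections: {sorted(unknown)}")
    try:
        sim = SimulationConfig.from_dict(doc.get("simulation") or {})
        params = PipelineParams.from_dict(doc.get("pipeline") or {})
    except (ValueError, TypeError) as exc:
        raise FormatError(str(exc)) from exc
    return sim, params


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    outdir,
    command: str,
    parameters: dict,
    seed: int | None,
    inputs: dict[str, str] | None = None,
    outputs: dict[str, Path] | None = None,
) -> Path:
    """One manifest per output directory: version, parameters actually used,
    seed, input/output checksums and a timestamp."""
    outdir = Path(outdir)
    manifest = {
        "tool": "rddmkit",
        "version": __version__,
        "command": command,
        "parameters": parameters,
        "seed": seed,
        "inputs": {k: sha256_file(v) for k, v in (inputs or {}).items()},
        "outputs": {k: sha256_file(v) for k, v in (outputs or {}).items()},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
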