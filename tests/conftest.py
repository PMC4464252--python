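import pandas as pd
import pytest

from rddmkit import annotation as ann_mod
from rddmkit.pipeline import run_pipeline
from rddmkit.synthetic import SimulationConfig, simulate


@pytest.fixture(scope="session")
def toy_annotation() -> ann_mod.GenomeAnnotation:
    """Two tiny chromosomes exercising every label and boundary case.

    chr1: geneA (+, [5000, 8000), two exons -> intron [6000, 7000)), a TE
    overlapping geneA's promoter, geneB (-, [12000, 14000), single exon).
    chr2: geneC (+, [500, 800)) whose promoter is clipped at position 0.
    """
    genes = pd.DataFrame(
        [
            ("geneA", "chr1", 5000, 8000, "+"),
            ("geneB", "chr1", 12000, 14000, "-"),
            ("geneC", "chr2", 500, 800, "+"),
        ],
        columns=["gene_id", "chrom", "start", "end", "strand"],
    )
    exons = pd.DataFrame(
        [
            ("geneA", "chr1", 5000, 6000),
            ("geneA", "chr1", 7000, 8000),
            ("geneB", "chr1", 12000, 14000),
            ("geneC", "chr2", 500, 800),
        ],
        columns=["gene_id", "chrom", "start", "end"],
    )
    tes = pd.DataFrame(
        [("chr1", 2500, 3500), ("chr1", 9000, 9800)],
        columns=["chrom", "start", "end"],
    )
    ann = ann_mod.GenomeAnnotation(
        chromosomes={"chr1": 20000, "chr2": 6000}, genes=genes, exons=exons, tes=tes
    )
    return ann_mod.derive_promoters(ann, 2000)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        seed=11,
        n_chromosomes=1,
        chromosome_length=700_000,
        n_genes=100,
        n_planted=5,
        n_metabolic=25,
        n_srnas=600,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate(small_config)


@pytest.fixture(scope="session")
def small_result(small_dataset):
    return run_pipeline(small_dataset, seed=11)
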