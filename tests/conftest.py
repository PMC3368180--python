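import pytest

from rgene_atlas.pipeline import PipelineConfig, run
from rgene_atlas.synth import GeneratorConfig, generate

SMALL_CONFIG = dict(
    n_chromosomes=3,
    chromosome_length=3_000_000,
    class_counts={"CNL": 8, "NL": 2, "CN": 1, "XN": 1},
    n_nonregular=2,
    n_background=2,
    family_sizes=(3, 2, 2),
    n_segmental_families=1,
    cluster_sizes=(4,),
    seed=7,
)


@pytest.fixture(scope="session")
def small_genome(tmp_path_factory):
    """A 16-gene synthetic genome with one cluster, three families (one
    segmental) and all four architecture classes."""
    outdir = tmp_path_factory.mktemp("small_synth")
    gen = generate(GeneratorConfig(**SMALL_CONFIG), outdir)
    return gen, outdir


@pytest.fixture(scope="session")
def small_run(small_genome, tmp_path_factory):
    gen, indir = small_genome
    outdir = tmp_path_factory.mktemp("small_report")
    cfg = PipelineConfig(
        genome_fa=str(indir / "genome.fa"),
        gff3=str(indir / "genes.gff3"),
        proteins_fa=str(indir / "proteins.fa"),
        ests_fa=str(indir / "ests.fa"),
        refs_fa=str(indir / "refs.fa"),
        outdir=str(outdir),
        seed=11,
        est_best_hit=True,
    )
    return gen, run(cfg), outdir


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """The full default study conditions: 126 regular genes in quota mode,
    20 planted families, 11 planted 200-kb clusters, fixed seed."""
    indir = tmp_path_factory.mktemp("default_synth")
    gen = generate(GeneratorConfig(seed=42), indir)
    outdir = tmp_path_factory.mktemp("default_report")
    cfg = PipelineConfig(
        genome_fa=str(indir / "genome.fa"),
        gff3=str(indir / "genes.gff3"),
        proteins_fa=str(indir / "proteins.fa"),
        ests_fa=str(indir / "ests.fa"),
        refs_fa=str(indir / "refs.fa"),
        outdir=str(outdir),
        seed=1,
    )
    return gen, run(cfg), outdir
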