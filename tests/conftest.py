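import pytest

from pante import PipelineConfig, run_pipeline, simulate_pangenome


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_sim():
    """Five genomes, two 60 kb chromosomes, 12 planted insertions, 1%
    substitutions — small enough to run the full pipeline in seconds."""
    return simulate_pangenome(
        n_genomes=5, n_chromosomes=2, chrom_len=60_000, n_insertions=12,
        mutation_rate=0.01, seed=7,
    )


@pytest.fixture(scope="session")
def small_result(small_sim, config):
    return run_pipeline(small_sim.assemblies, small_sim.copies, small_sim.library, config)


TOY_NEWICK = "((A:0.1,B:0.05):0.02,C:0.2);"


@pytest.fixture()
def toy_tree_path(tmp_path):
    path = tmp_path / "toy.nwk"
    path.write_text(TOY_NEWICK + "\n")
    return path
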