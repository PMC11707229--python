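import pytest

from quinrep.simulate import SimulationScenario, synthesize_genome_set


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A 30-genome noise-free synthetic dataset shared across unit tests."""
    scenario = SimulationScenario(seed=11, n_genomes=30)
    out = tmp_path_factory.mktemp("smallsim")
    return synthesize_genome_set(scenario, out)


@pytest.fixture(scope="session")
def small_genomes(small_dataset):
    """The annotated genomes reconstructed from the small dataset's files."""
    from quinrep.annotation import read_ga_thresholds
    from quinrep.workflow import annotate_directory

    ga = read_ga_thresholds(small_dataset.ga_thresholds_path)
    return annotate_directory(
        small_dataset.gff_dir,
        small_dataset.hits_dir,
        small_dataset.genome_ids,
        ga_thresholds=ga,
    )
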