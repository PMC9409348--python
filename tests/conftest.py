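import pytest

from sexvarscan.config import SimulationConfig
from sexvarscan.depth import DepthMatrix
from sexvarscan.simulate import generate_cohort, generate_reference
from sexvarscan.variants import filter_quality, merge_samples, read_vcf


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    """The standard test cohort: 2 x 100 kb contigs, 5M/5F, three planted
    40-variant clusters, ~200 noise records, 50 low-QUAL decoys."""
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def reference(sim_config):
    return generate_reference(sim_config)


@pytest.fixture(scope="session")
def cohort(sim_config, reference, tmp_path_factory):
    return generate_cohort(sim_config, reference, tmp_path_factory.mktemp("cohort"))


@pytest.fixture(scope="session")
def depth_matrix(cohort) -> DepthMatrix:
    samples = cohort.male_samples + cohort.female_samples
    return DepthMatrix.from_files({s: cohort.depth_paths[s] for s in samples})


def read_records(cohort, sample: str, filtered: bool, min_qual: float = 30.0):
    stream = read_vcf(cohort.vcf_paths[sample], sample=sample)
    return list(filter_quality(stream, min_qual)) if filtered else list(stream)


@pytest.fixture(scope="session")
def male_merged(cohort):
    males = cohort.male_samples
    return merge_samples({s: read_records(cohort, s, True) for s in males}, males)


@pytest.fixture(scope="session")
def female_merged_unfiltered(cohort):
    females = cohort.female_samples
    return merge_samples({s: read_records(cohort, s, False) for s in females}, females)


@pytest.fixture(scope="session")
def all_merged_filtered(cohort):
    samples = cohort.male_samples + cohort.female_samples
    return merge_samples({s: read_records(cohort, s, True) for s in samples}, samples)
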