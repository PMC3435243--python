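import pytest

from famcnv.io import Individual, Pedigree
from famcnv.pipeline import run_pipeline
from famcnv.simulate import SimulationConfig, simulate_cohort


def make_individual(iid, fid="F1", father=None, mother=None, sex="male",
                    phenotype="unknown"):
    return Individual(
        individual_id=iid, family_id=fid, father_id=father, mother_id=mother,
        sex=sex, phenotype=phenotype,
    )


@pytest.fixture
def nuclear_family():
    """Father, mother, one affected son, one unaffected daughter."""
    return Pedigree(
        [
            make_individual("dad", sex="male", phenotype="unaffected"),
            make_individual("mum", sex="female", phenotype="unaffected"),
            make_individual("son", father="dad", mother="mum", sex="male",
                            phenotype="affected"),
            make_individual("sis", father="dad", mother="mum", sex="female",
                            phenotype="unaffected"),
        ]
    )


@pytest.fixture(scope="session")
def default_bundle():
    """The default synthetic cohort (seeded study conditions)."""
    return simulate_cohort(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def default_pipeline(default_bundle):
    """Full pipeline run on the default cohort (burden stage kept small)."""
    return run_pipeline(default_bundle, n_burden_permutations=500, seed=0)
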