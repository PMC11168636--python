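import numpy as np
import pytest

from mhcmate import matechoice, synth
from mhcmate.types import AlleleSequence, IndividualGenotype


@pytest.fixture(scope="session")
def small_pool():
    """12 related alleles of 60 nt (20 codons), frame 0."""
    return synth.generate_allele_pool(
        n_alleles=12, length_nt=60, frame_offset=0, pbr_fraction=0.3,
        seed=7, divergence_codons=5,
    )


@pytest.fixture(scope="session")
def study_pool():
    """Study-shaped pool: 99 related alleles of 298 nt."""
    return synth.generate_allele_pool(
        n_alleles=99, length_nt=298, frame_offset=0, pbr_fraction=0.27,
        seed=10, divergence_codons=12,
    )


@pytest.fixture(scope="session")
def small_translations(small_pool):
    return matechoice.AlleleTranslations(
        small_pool.sequences_by_id(), small_pool.partition()
    )


@pytest.fixture(scope="session")
def study_translations(study_pool):
    return matechoice.AlleleTranslations(
        study_pool.sequences_by_id(), study_pool.partition()
    )


def make_genotype(ind, alleles, sex="unknown", pop="pop1"):
    return IndividualGenotype(
        individual_id=ind, allele_ids=frozenset(alleles),
        population_id=pop, sex=sex,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
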