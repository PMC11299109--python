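import pytest

from cohortviz import (CohortConfig, GenomeAssembly, PurityPloidy,
                       generate_cohort, purify_segments)


@pytest.fixture(scope="session")
def toy_asm():
    return GenomeAssembly("toy", [("A", 100), ("B", 50), ("C", 25)])


@pytest.fixture(scope="session")
def cohort():
    """Small deterministic synthetic cohort shared across tests."""
    return generate_cohort(CohortConfig(seed=7, n_patients=10,
                                        n_non_loh_outliers=2,
                                        n_tandem_duplicator_patients=2))


@pytest.fixture(scope="session")
def purity_ploidy(cohort):
    return {row["sample"]: PurityPloidy(row["purity"], row["ploidy"])
            for _, row in cohort.samples.iterrows()}


@pytest.fixture(scope="session")
def purified_segments(cohort, purity_ploidy):
    return purify_segments(cohort.segments, purity_ploidy)
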