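import numpy as np
import pytest

import stopext as se


@pytest.fixture
def mini_transcript() -> se.Transcript:
    """Minimal ORF (Met + stop) with a UTR holding one Phe codon then TAA."""
    return se.validate(se.Transcript(id="mini", cds="ATGTGA", utr3="TTTTAA"))


@pytest.fixture(scope="session")
def default_cohort() -> se.LabeledCohort:
    """The default planted-effect training cohort (620 variants, 1:1)."""
    return se.gen_labeled_cohort(se.CohortSpec(seed=1))


@pytest.fixture(scope="session")
def test_cohort() -> se.LabeledCohort:
    """The imbalanced held-out cohort (558 variants, 187 pathogenic)."""
    return se.gen_labeled_cohort(se.CohortSpec(seed=1).test_set())


@pytest.fixture(scope="session")
def trained_model(default_cohort) -> se.TrainedForest:
    """Forest trained at the default hyperparameters on the default cohort."""
    return se.train(default_cohort.features, default_cohort.labels, seed=1)


@pytest.fixture(scope="session")
def session_rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
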