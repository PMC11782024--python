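import pytest

from avskit import GeneratorConfig, Subtype, generate_cohort


@pytest.fixture(scope="session")
def study_cohort():
    """Synthetic cohort at the study's group sizes (28/15/11), fixed seed."""
    return generate_cohort(GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def large_cohort():
    """A 2000-per-group calibrated cohort for distribution-level checks."""
    return generate_cohort(
        GeneratorConfig(seed=11, group_sizes={s: 2000 for s in Subtype})
    )
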