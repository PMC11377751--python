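import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_family():
    """A 30-member domain family at moderate divergence, with truth."""
    from gmdomains.synthetic import FamilySpec, generate_family
    return generate_family(FamilySpec("famA", domain_length=100, n_members=30,
                                      target_identity=0.5, indel_rate=0.02,
                                      seed=7))


@pytest.fixture(scope="session")
def family_hmm(small_family):
    from gmdomains.hmm import hmm_from_msa
    return hmm_from_msa(small_family.msa, name="famA")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
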