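import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from qascale.synthetic import SynthSpec, default_catalog, generate


@pytest.fixture(scope="session")
def small_corpus():
    """60 synthetic records with the default 10-concept catalog."""
    return generate(SynthSpec(n_records=60, concepts=default_catalog(), seed=11))


@pytest.fixture(scope="session")
def oracle_matrix(small_corpus):
    from qascale.corpus import preextract
    from qascale.qa import run_matrix

    snippets = preextract(small_corpus.records, small_corpus.questions)
    return run_matrix(
        small_corpus.records,
        small_corpus.questions,
        snippets,
        small_corpus.make_backend(),
    )
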