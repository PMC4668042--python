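import pytest
from hypothesis import settings

import lexikit as lk

# keep property tests reproducible run to run
settings.register_profile("repro", deadline=None, derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def demo_lex() -> lk.Lexicon:
    """The built-in demonstration lexicon, fully assembled."""
    return lk.demo_lexicon(seed=42)


@pytest.fixture(scope="session")
def big_lex() -> lk.Lexicon:
    """A 5,000-type synthetic Zipfian lexicon run through the full pipeline.

    Session-scoped because the corpus-relative columns (OLD20 in
    particular) dominate build time.
    """
    lists = lk.generate_synthetic_lexicon(lk.SyntheticSpec(n_types=5000, seed=1))
    lexicon, _report = lk.build_lexicon(lists, seed=1)
    return lexicon
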