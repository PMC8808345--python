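import pytest

from endsner.synthetic import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """200 generated posts with companion lexicons (fixed seed)."""
    return generate_corpus(GeneratorConfig(n_posts=200, seed=11))


@pytest.fixture(scope="session")
def cv_corpus():
    """The 1000-post benchmark corpus: 50 brands, 30 flavors, homograph
    pollution at 0.1, seed 7."""
    return generate_corpus(GeneratorConfig(n_posts=1000, homograph_rate=0.1, seed=7))
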