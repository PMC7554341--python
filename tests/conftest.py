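import pytest

from logimodel import toy_model
from logimodel.fixtures import GeneratorConfig, random_model


@pytest.fixture
def figure3():
    return toy_model("figure3")


@pytest.fixture
def calcium_default():
    return toy_model("calcium_default")


@pytest.fixture
def calcium_corrected():
    return toy_model("calcium_corrected")


def random_models(count, n_range, seed_base=0, n_inputs=2, max_level=1, **kw):
    """Seeded stream of random models with sizes cycling over n_range."""
    sizes = list(n_range)
    for i in range(count):
        n = sizes[i % len(sizes)]
        yield random_model(
            GeneratorConfig(
                n_components=n,
                n_inputs=min(n_inputs, n - 1) if n > 1 else 0,
                max_level=max_level,
                seed=seed_base + i,
                **kw,
            )
        )
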