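import numpy as np
import pytest
from hypothesis import settings

from eoscount.masks import Extent, LabelMaskStack

settings.register_profile("ci", derandomize=True, max_examples=30, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_mask_stack(rng, height, width, p=0.3):
    """Random (possibly overlapping-free) two-class mask stack."""
    labels = rng.choice(3, size=(height, width), p=[1 - p, p / 2, p / 2])
    return LabelMaskStack(
        extent=Extent(height, width),
        masks={"intact": labels == 1, "not_intact": labels == 2},
    )


def random_probability_map(rng, height, width):
    logits = rng.normal(size=(3, height, width))
    e = np.exp(logits - logits.max(axis=0))
    return e / e.sum(axis=0)
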