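import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_set():
    """200 constructively built atom-mapped reactions with known scripts."""
    from enzedit.fixtures import make_reaction_fixtures

    return make_reaction_fixtures(seed=7, n=200)


@pytest.fixture(scope="session")
def putrescine():
    from enzedit.fixtures import make_putrescine_dag

    return make_putrescine_dag()


@pytest.fixture(scope="session")
def tiny_corpus():
    """50 MakeSSREdits examples over the shipped molecule pool."""
    from enzedit.fixtures import base_molecules
    from enzedit.pretrain import build_corpus

    return build_corpus(base_molecules(), "MakeSSREdits", 50, seed=3)


@pytest.fixture(scope="session")
def tiny_checkpoint(tiny_corpus):
    """A desk-scale model trained to memorize the tiny corpus."""
    from enzedit.seq2seq import ModelConfig, TrainConfig, train

    return train(
        ModelConfig.tiny(),
        TrainConfig(peak_lr=3e-3, warmup_steps=20, batch_size=50, seed=0),
        tiny_corpus,
        steps=300,
    )


class ScriptedRng:
    """Deterministic stand-in for a Generator: replays queued draws."""

    def __init__(self, integers=(), randoms=()):
        self._ints = list(integers)
        self._floats = list(randoms)

    def integers(self, low, high=None):
        return self._ints.pop(0)

    def random(self, *a, **k):
        return self._floats.pop(0) if self._floats else 1.0


@pytest.fixture
def scripted_rng():
    return ScriptedRng
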