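import numpy as np
import pytest

from crag.attack import AttackConfig
from crag.fixtures import generate_fixture_smiles
from crag.model import ModelConfig, encode_sequences, greedy_decode
from crag.tokenizer import detokenize
from crag.training import TrainConfig, ae_step, fit

# desk-scale model dimensions used throughout the suite; the architecture is
# identical to the full-size configuration, only widths shrink
TINY_MODEL = dict(d_z=48, d_embed=24, critic_hidden=48, predictor_hidden=48, l_max=40)


@pytest.fixture(scope="session")
def fixture_corpus():
    """200 synthetic valid molecules, <= 9 heavy atoms."""
    return generate_fixture_smiles(200, 42)


@pytest.fixture(scope="session")
def smoke_state(fixture_corpus):
    """A 20-epoch cross-adversarial run on the 200-molecule corpus."""
    cfg = TrainConfig(epochs=20, batch_size=64, eval_samples=200, seed=0,
                      attack=AttackConfig(epsilon=0.1, steps=5))
    return fit(fixture_corpus, cfg, ModelConfig(**TINY_MODEL))


@pytest.fixture(scope="session")
def overfit_state():
    """Autoencoder overfit to perfect greedy reconstruction of 5 molecules."""
    corpus = generate_fixture_smiles(5, 11)
    cfg = TrainConfig(epochs=0, batch_size=5, eval_samples=0, seed=3)
    state = fit(corpus, cfg, ModelConfig(d_z=64, d_embed=32, critic_hidden=32,
                                         predictor_hidden=32, l_max=40))
    targets = [r.canonical for r in state.records]
    for step in range(2000):
        ae_step(state, state.seqs)
        if step % 50 == 49:
            z = encode_sequences(state.seqs, state.model.enc, l_max=40)
            decoded = greedy_decode(z, state.model.dec, l_max=40)
            if [detokenize(s, state.model.vocab) for s in decoded] == targets:
                break
    return state


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
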