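import numpy as np
import pytest

from crag import nn
from crag.model import (
    CragModel,
    ModelConfig,
    critic_bound,
    critic_score,
    decode_backward,
    decode_logits,
    encode,
    encode_backward,
    greedy_decode,
    init_critic,
    init_decoder,
    init_encoder,
    init_predictor,
    pad_batch,
    predictor_forward,
    predictor_loss_grad_z,
    reconstruction_loss,
)
from crag.tokenizer import (
    BOS_ID,
    EOS_ID,
    PAD_ID,
    SPECIALS,
    TokenSequence,
    Vocabulary,
)

VOCAB = Vocabulary(tokens=SPECIALS + ("(", ")", "=", "C", "N", "O"))
CFG = ModelConfig(d_z=8, d_embed=5, critic_hidden=7, predictor_hidden=7, l_max=20)
SEQS = [
    TokenSequence([BOS_ID, 7, 8, 9, EOS_ID, PAD_ID, PAD_ID]),
    TokenSequence([BOS_ID, 9, 9, 7, 4, 8, EOS_ID]),
]


@pytest.fixture
def nets(rng):
    return (
        init_encoder(rng, len(VOCAB), CFG),
        init_decoder(rng, len(VOCAB), CFG),
        init_critic(rng, CFG),
        init_predictor(rng, CFG),
    )


class TestEncoder:
    def test_deterministic_and_shaped(self, nets):
        enc = nets[0]
        ids, mask = pad_batch(SEQS)
        z1, _ = encode(ids, mask, enc, l_max=CFG.l_max)
        z2, _ = encode(ids, mask, enc, l_max=CFG.l_max)
        assert z1.shape == (2, CFG.d_z)
        assert np.array_equal(z1, z2)
        assert np.isfinite(z1).all()

    def test_default_latent_dimension_is_300(self, rng):
        enc = init_encoder(rng, len(VOCAB), ModelConfig())
        ids, mask = pad_batch(SEQS)
        z, _ = encode(ids, mask, enc, l_max=60)
        assert z.shape == (2, 300)

    def test_over_length_errors(self, nets):
        ids, mask = pad_batch(SEQS)
        with pytest.raises(ValueError):
            encode(ids, mask, nets[0], l_max=3)

    def test_zero_recurrent_weights_ignore_tokens(self, nets):
        enc = {k: np.zeros_like(v) for k, v in nets[0].items()}
        enc["b"][:] = 0.3  # bias-driven dynamics only
        ids, mask = pad_batch([SEQS[0], SEQS[0]])
        other = TokenSequence([BOS_ID, 4, 4, 4, EOS_ID, PAD_ID, PAD_ID])
        ids2, _ = pad_batch([other, other])
        z1, _ = encode(ids, mask, enc, l_max=CFG.l_max)
        z2, _ = encode(ids2, mask, enc, l_max=CFG.l_max)
        assert np.allclose(z1, z2)


class TestDecoder:
    def test_one_logit_row_per_position_after_bos(self, nets, rng):
        z = rng.normal(size=(2, CFG.d_z))
        ids, _ = pad_batch(SEQS)
        logits, _ = decode_logits(z, ids, nets[1])
        assert logits.shape == (2, ids.shape[1] - 1, len(VOCAB))
        logits2, _ = decode_logits(z, ids, nets[1])
        assert np.array_equal(logits, logits2)

    def test_teacher_must_start_with_bos(self, nets, rng):
        ids, _ = pad_batch(SEQS)
        bad = ids.copy()
        bad[:, 0] = EOS_ID
        with pytest.raises(ValueError):
            decode_logits(rng.normal(size=(2, CFG.d_z)), bad, nets[1])

    def test_dimension_mismatch_errors(self, nets, rng):
        ids, _ = pad_batch(SEQS)
        with pytest.raises(ValueError):
            decode_logits(rng.normal(size=(2, CFG.d_z + 1)), ids, nets[1])


class TestReconstructionLoss:
    def test_uniform_logits_give_log_vocab(self, rng):
        V = len(VOCAB)
        ids, _ = pad_batch(SEQS)
        logits = np.zeros((2, ids.shape[1] - 1, V))
        loss, _ = reconstruction_loss(logits, ids[:, 1:])
        assert loss == pytest.approx(np.log(V), rel=1e-12)

    def test_confident_correct_logits_drive_loss_to_zero(self):
        ids, _ = pad_batch(SEQS)
        targets = ids[:, 1:]
        logits = np.full((2, targets.shape[1], len(VOCAB)), -1e3)
        for b in range(2):
            for t in range(targets.shape[1]):
                logits[b, t, targets[b, t]] = 1e3
        loss, _ = reconstruction_loss(logits, targets)
        assert loss == pytest.approx(0.0, abs=1e-9)

    def test_matches_bruteforce_per_token_cross_entropy(self, rng):
        ids, _ = pad_batch(SEQS)
        targets = ids[:, 1:]
        logits = rng.normal(size=(2, targets.shape[1], len(VOCAB)))
        loss, _ = reconstruction_loss(logits, targets)
        total, count = 0.0, 0
        for b in range(2):
            for t in range(targets.shape[1]):
                if targets[b, t] == PAD_ID:
                    continue
                row = logits[b, t]
                p = np.exp(row - row.max())
                p /= p.sum()
                total += -np.log(p[targets[b, t]])
                count += 1
        assert loss == pytest.approx(total / count, rel=1e-12)

    def test_all_pad_target_errors(self, rng):
        logits = rng.normal(size=(1, 3, len(VOCAB)))
        with pytest.raises(ValueError):
            reconstruction_loss(logits, np.full((1, 3), PAD_ID))


class TestGreedyDecode:
    def _rigged(self, favored):
        dec = init_decoder(np.random.default_rng(0), len(VOCAB), CFG)
        for k in ("Wx", "Wh", "Wout"):
            dec[k] = np.zeros_like(dec[k])
        dec["b"] = np.zeros_like(dec["b"])
        dec["bout"] = np.zeros_like(dec["bout"])
        dec["bout"][favored] = 10.0
        return dec

    def test_eos_dominant_decoder_emits_bos_eos(self, rng):
        seqs = greedy_decode(rng.normal(size=(3, CFG.d_z)), self._rigged(EOS_ID), l_max=CFG.l_max)
        assert all(s.indices == [BOS_ID, EOS_ID] for s in seqs)

    def test_no_eos_preference_hits_length_cap(self, rng):
        seqs = greedy_decode(rng.normal(size=(2, CFG.d_z)), self._rigged(7), l_max=6)
        assert all(len(s.indices) == 7 for s in seqs)  # BOS + 6 emitted

    def test_never_emits_pad_or_tokens_after_eos(self, rng):
        dec = init_decoder(rng, len(VOCAB), CFG)
        for s in greedy_decode(rng.normal(size=(8, CFG.d_z)), dec, l_max=CFG.l_max):
            assert PAD_ID not in s.indices
            if EOS_ID in s.indices:
                assert s.indices.index(EOS_ID) == len(s.indices) - 1


class TestCritic:
    def test_zero_weights_score_zero(self, rng):
        crit = {k: np.zeros_like(v) for k, v in init_critic(rng, CFG).items()}
        scores, _ = critic_score(rng.normal(size=(4, CFG.d_z)), crit)
        assert np.array_equal(scores, np.zeros(4))

    def test_batch_of_finite_scalars(self, nets, rng):
        scores, _ = critic_score(rng.normal(size=(5, CFG.d_z)), nets[2])
        assert scores.shape == (5,) and np.isfinite(scores).all()

    def test_linear_critic_equals_affine_map(self, rng):
        # identity hidden layer with large positive bias keeps ReLU active,
        # so the critic is an affine map checkable by matrix multiply
        d = CFG.d_z
        w2 = rng.normal(size=(d, 1))
        crit = {"W1": np.eye(d), "b1": np.full(d, 50.0), "W2": w2, "b2": np.array([0.7])}
        z = rng.uniform(-1, 1, size=(6, d))
        scores, _ = critic_score(z, crit)
        expected = (z + 50.0) @ w2[:, 0] + 0.7
        assert np.allclose(scores, expected)

    def test_clipped_critic_is_bounded_on_bounded_latents(self, rng):
        crit = init_critic(rng, CFG)
        c = 0.01
        for k in crit:
            np.clip(crit[k], -c, c, out=crit[k])
        radius = 5.0
        bound = critic_bound(crit, radius)
        z = rng.uniform(-radius, radius, size=(200, CFG.d_z))
        scores, _ = critic_score(z, crit)
        assert np.abs(scores).max() <= bound + 1e-12


class TestPredictor:
    def test_zero_weights_uniform_logits_tie_to_class_zero(self, rng):
        pred = {k: np.zeros_like(v) for k, v in init_predictor(rng, CFG).items()}
        logits, _ = predictor_forward(rng.normal(size=(3, CFG.d_z)), pred)
        assert np.array_equal(logits, np.zeros((3, 2)))
        assert np.argmax(logits, axis=1).tolist() == [0, 0, 0]

    def test_softmax_of_logits_normalizes(self, nets, rng):
        logits, _ = predictor_forward(rng.normal(size=(4, CFG.d_z)), nets[3])
        assert np.allclose(nn.softmax(logits).sum(axis=1), 1.0)

    def test_trains_to_separate_two_points(self, rng):
        pred = init_predictor(rng, CFG)
        opt = nn.Adam(pred, lr=1e-2)
        z = np.vstack([np.full(CFG.d_z, -1.0), np.full(CFG.d_z, 1.0)])
        y = np.array([0, 1])
        for _ in range(200):
            logits, cache = nn.mlp_forward(pred, z)
            _, dlogits = nn.cross_entropy(logits, y)
            grads, _ = nn.mlp_backward(pred, cache, dlogits)
            opt.step(grads)
        logits, _ = predictor_forward(z, pred)
        assert np.argmax(logits, axis=1).tolist() == [0, 1]


class TestGradients:
    """Analytic backward passes vs central finite differences."""

    def test_autoencoder_gradients_match_finite_differences(self, nets, rng):
        enc, dec = nets[0], nets[1]
        ids, mask = pad_batch(SEQS)

        def loss():
            z, _ = encode(ids, mask, enc, l_max=CFG.l_max)
            logits, _ = decode_logits(z, ids, dec)
            return reconstruction_loss(logits, ids[:, 1:])[0]

        z, ec = encode(ids, mask, enc, l_max=CFG.l_max)
        logits, dc = decode_logits(z, ids, dec)
        _, dlogits = reconstruction_loss(logits, ids[:, 1:])
        dec_grads, dz = decode_backward(dec, dc, dlogits)
        enc_grads = encode_backward(enc, ec, dz)

        eps = 1e-6
        for params, grads in ((enc, enc_grads), (dec, dec_grads)):
            for k in params:
                flat = params[k].ravel()
                for idx in rng.choice(flat.size, size=min(6, flat.size), replace=False):
                    orig = flat[idx]
                    flat[idx] = orig + eps
                    lp = loss()
                    flat[idx] = orig - eps
                    lm = loss()
                    flat[idx] = orig
                    assert grads[k].ravel()[idx] == pytest.approx(
                        (lp - lm) / (2 * eps), rel=1e-4, abs=1e-7
                    )

    def test_predictor_latent_gradient_matches_finite_differences(self, nets, rng):
        pred = nets[3]
        z = rng.normal(size=(3, CFG.d_z))
        y = np.array([0, 1, 1])
        _, gz = predictor_loss_grad_z(z, y, pred)
        eps = 1e-6
        for b in range(3):
            for j in rng.choice(CFG.d_z, size=4, replace=False):
                zp = z.copy()
                zp[b, j] += eps
                lp = predictor_loss_grad_z(zp, y, pred)[0]
                zp[b, j] -= 2 * eps
                lm = predictor_loss_grad_z(zp, y, pred)[0]
                assert gz[b, j] == pytest.approx((lp - lm) / (2 * eps), rel=1e-4, abs=1e-8)


class TestCheckpoint:
    def test_roundtrip_preserves_everything(self, tmp_path):
        model = CragModel(VOCAB, CFG, seed=4)
        model.cond_stats = {"TPSA": (0.0, 80.0)}
        path = tmp_path / "model.ckpt"
        model.save(path)
        loaded = CragModel.load(path)
        assert loaded.vocab.tokens == VOCAB.tokens
        assert loaded.cfg == CFG
        assert loaded.cond_stats == {"TPSA": (0.0, 80.0)}
        for name, net in model.networks().items():
            for k in net:
                assert np.array_equal(net[k], loaded.networks()[name][k])

    def test_refuses_vocabulary_mismatch(self, tmp_path):
        model = CragModel(VOCAB, CFG, seed=4)
        path = tmp_path / "model.ckpt"
        model.save(path)
        other = Vocabulary(tokens=SPECIALS + ("C", "N"))
        with pytest.raises(ValueError, match="vocabulary"):
            CragModel.load(path, expect_vocab=other)
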