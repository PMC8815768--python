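"""The four networks: LSTM encoder, LSTM decoder, Wasserstein critic, property
predictor.

The encoder is deterministic: a single LSTM layer reads the embedded token
sequence and its final hidden state is the latent code z (dimension ``d_z``,
default 300). The decoder is a single LSTM layer whose initial hidden state is
z; it is teacher-forced during training and greedy (argmax) at generation
time. The critic and the property predictor are two-layer ReLU perceptrons
with hidden width 200: the critic emits one scalar per latent (its batch means
estimate the Wasserstein distance between real and adversarial latents), the
predictor emits K class logits. An optional Gaussian perturbation on z
(``latent_noise_std``) covers the variational reading of the encoder; it is
off by default.

In conditional mode (``cond_dim > 0``) a property-condition vector is
concatenated to the decoder input at every step and to the predictor input;
the encoder is unchanged.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from . import nn
from .tokenizer import BOS_ID, EOS_ID, PAD_ID, TokenSequence, Vocabulary


@dataclass
class ModelConfig:
    d_z: int = 300
    d_embed: int = 128
    critic_hidden: int = 200
    predictor_hidden: int = 200
    n_classes: int = 2
    l_max: int = 60
    cond_dim: int = 0          # >0 enables conditional decoding/prediction
    latent_noise_std: float = 0.0  # optional Gaussian jitter on z in training
    noise_dim: int = 100       # input dim of the optional prior-noise generator
    use_noise_generator: bool = False


def pad_batch(seqs: Sequence[TokenSequence], length: int | None = None):
    """Stack TokenSequences into (ids, mask) arrays; mask is 1 on non-PAD."""
    if length is None:
        length = max(len(s) for s in seqs)
    ids = np.full((len(seqs), length), PAD_ID, dtype=np.int64)
    for r, s in enumerate(seqs):
        ids[r, : len(s.indices)] = s.indices
    return ids, (ids != PAD_ID).astype(np.float64)


# ------------------------------------------------------------------ encoder
def init_encoder(rng: np.random.Generator, vocab_size: int, cfg: ModelConfig) -> nn.Params:
    p = nn.lstm_init(rng, cfg.d_embed, cfg.d_z)
    p["emb"] = nn.glorot(rng, vocab_size, cfg.d_embed)
    return p


def encode(ids: np.ndarray, mask: np.ndarray, enc: nn.Params, l_max: int = 60):
    """Map token id batch (B, T) to latents (B, d_z); returns (z, cache)."""
    if ids.shape[1] > l_max:
        raise ValueError(f"sequence length {ids.shape[1]} exceeds l_max={l_max}")
    x = nn.embedding_forward(enc["emb"], ids)
    _, h_T, _, lstm_cache = nn.lstm_forward(enc, x, mask)
    return h_T, {"ids": ids, "lstm": lstm_cache}


def encode_backward(enc: nn.Params, cache, dz: np.ndarray) -> nn.Params:
    grads, dx, _, _ = nn.lstm_backward(enc, cache["lstm"], dhs=None, dh_T=dz)
    grads["emb"] = nn.embedding_backward(enc["emb"], cache["ids"], dx)
    return grads


def encode_sequences(seqs: Sequence[TokenSequence], enc: nn.Params, l_max: int = 60) -> np.ndarray:
    ids, mask = pad_batch(seqs)
    z, _ = encode(ids, mask, enc, l_max=l_max)
    return z


# ------------------------------------------------------------------ decoder
def init_decoder(rng: np.random.Generator, vocab_size: int, cfg: ModelConfig) -> nn.Params:
    p = nn.lstm_init(rng, cfg.d_embed + cfg.cond_dim, cfg.d_z)
    p["emb"] = nn.glorot(rng, vocab_size, cfg.d_embed)
    p["Wout"] = nn.glorot(rng, cfg.d_z, vocab_size)
    p["bout"] = np.zeros(vocab_size)
    return p


def _decoder_inputs(dec: nn.Params, ids: np.ndarray, cond: np.ndarray | None):
    x = nn.embedding_forward(dec["emb"], ids)
    if cond is not None:
        tiled = np.repeat(cond[:, None, :], ids.shape[1], axis=1)
        x = np.concatenate([x, tiled], axis=2)
    return x


def decode_logits(z: np.ndarray, teacher_ids: np.ndarray, dec: nn.Params,
                  cond: np.ndarray | None = None):
    """Teacher-forced decoding: logits for positions 1..T-1 of the teacher.

    teacher_ids: (B, T) beginning with BOS; input at step t is teacher token t,
    target is token t+1. Returns (logits (B, T-1, V), cache).
    """
    if np.any(teacher_ids[:, 0] != BOS_ID):
        raise ValueError("teacher sequences must begin with BOS")
    if z.shape[0] != teacher_ids.shape[0] or z.shape[1] != dec["Wh"].shape[0]:
        raise ValueError(
            f"latent batch {z.shape} does not match teacher batch "
            f"{teacher_ids.shape} / decoder hidden {dec['Wh'].shape[0]}"
        )
    inputs = teacher_ids[:, :-1]
    x = _decoder_inputs(dec, inputs, cond)
    mask = np.ones(inputs.shape, dtype=np.float64)  # teacher forcing runs all steps
    hs, _, _, lstm_cache = nn.lstm_forward(dec, x, mask, h0=z)
    logits = hs @ dec["Wout"] + dec["bout"]
    return logits, {"inputs": inputs, "hs": hs, "lstm": lstm_cache, "cond": cond}


def decode_backward(dec: nn.Params, cache, dlogits: np.ndarray):
    """Returns (grads, dz)."""
    hs = cache["hs"]
    grads = {
        "Wout": np.einsum("bth,btv->hv", hs, dlogits),
        "bout": dlogits.sum(axis=(0, 1)),
    }
    dhs = dlogits @ dec["Wout"].T
    lstm_grads, dx, dh0, _ = nn.lstm_backward(dec, cache["lstm"], dhs=dhs)
    grads.update(lstm_grads)
    d_embed = dec["emb"].shape[1]
    grads["emb"] = nn.embedding_backward(dec["emb"], cache["inputs"], dx[:, :, :d_embed])
    return grads, dh0


def reconstruction_loss(logits: np.ndarray, target_ids: np.ndarray):
    """Mean token-level cross-entropy over non-PAD target positions.

    logits: (B, T-1, V) from ``decode_logits``; target_ids: (B, T-1), i.e. the
    teacher shifted left by one. Returns (loss, dlogits).
    """
    B, S, V = logits.shape
    if target_ids.shape != (B, S):
        raise ValueError(f"target shape {target_ids.shape} != logits {(B, S)}")
    weights = (target_ids != PAD_ID).astype(np.float64).ravel()
    if weights.sum() == 0:
        raise ValueError("reconstruction_loss: target is all padding")
    loss, dflat = nn.cross_entropy(logits.reshape(-1, V), target_ids.ravel(), weights)
    return loss, dflat.reshape(B, S, V)


def greedy_decode(z: np.ndarray, dec: nn.Params, l_max: int = 60,
                  cond: np.ndarray | None = None) -> list[TokenSequence]:
    """Autoregressive argmax decoding from latents.

    Each sequence starts at BOS and stops at EOS or after ``l_max`` emitted
    tokens. PAD is never emitted; argmax ties resolve to the lowest token
    index (NumPy convention).
    """
    B = z.shape[0]
    h, c = z.copy(), np.zeros_like(z)
    tok = np.full(B, BOS_ID, dtype=np.int64)
    done = np.zeros(B, dtype=bool)
    out = [[BOS_ID] for _ in range(B)]
    for _ in range(l_max):
        x = _decoder_inputs(dec, tok[:, None], cond)
        mask = np.ones((B, 1))
        hs, h, c, _ = nn.lstm_forward(dec, x, mask, h0=h, c0=c)
        logits = hs[:, 0] @ dec["Wout"] + dec["bout"]
        logits[:, PAD_ID] = -np.inf
        tok = np.argmax(logits, axis=1)
        for b in range(B):
            if not done[b]:
                out[b].append(int(tok[b]))
                if tok[b] == EOS_ID:
                    done[b] = True
        if done.all():
            break
    return [TokenSequence(indices=o) for o in out]


# ------------------------------------------------------- critic & predictor
def init_critic(rng: np.random.Generator, cfg: ModelConfig) -> nn.Params:
    return nn.mlp_init(rng, cfg.d_z, cfg.critic_hidden, 1)


def critic_score(z: np.ndarray, crit: nn.Params):
    """Scalar critic score per latent; returns (scores (B,), cache)."""
    out, cache = nn.mlp_forward(crit, z)
    return out[:, 0], cache


def critic_backward(crit: nn.Params, cache, dscore: np.ndarray):
    return nn.mlp_backward(crit, cache, dscore[:, None])


def critic_bound(crit: nn.Params, z_radius: float) -> float:
    """Upper bound on |score| over the ball ||z||_inf <= z_radius.

    |hidden_j| <= z_radius * ||W1[:, j]||_1 + |b1_j| (ReLU only shrinks), so
    |out| <= sum_j |W2_j| * bound_j + |b2|. Used to check that weight clipping
    keeps the critic bounded on bounded latent sets.
    """
    hidden = z_radius * np.abs(crit["W1"]).sum(axis=0) + np.abs(crit["b1"])
    return float(np.abs(crit["W2"][:, 0]) @ hidden + abs(float(crit["b2"][0])))


def init_predictor(rng: np.random.Generator, cfg: ModelConfig) -> nn.Params:
    return nn.mlp_init(rng, cfg.d_z + cfg.cond_dim, cfg.predictor_hidden, cfg.n_classes)


def predictor_forward(z: np.ndarray, pred: nn.Params, cond: np.ndarray | None = None):
    """Class logits per latent; returns (logits (B, K), cache)."""
    x = z if cond is None else np.concatenate([z, cond], axis=1)
    return nn.mlp_forward(pred, x)


def predictor_loss_grad_z(z: np.ndarray, y: np.ndarray, pred: nn.Params,
                          cond: np.ndarray | None = None):
    """Cross-entropy L(omega, z, y) and its gradient w.r.t. z (params fixed).

    The gradient the PGD block ascends: per-sample, so the loss is summed, not
    averaged (each sample's gradient is independent of batch size).
    """
    logits, cache = predictor_forward(z, pred, cond)
    n = z.shape[0]
    loss, dlogits = nn.cross_entropy(logits, y)
    dlogits *= n  # per-sample gradients
    _, dx = nn.mlp_backward(pred, cache, dlogits)
    return loss * n, dx[:, : z.shape[1]]


def init_noise_generator(rng: np.random.Generator, cfg: ModelConfig) -> nn.Params:
    """Optional ARAE-style prior generator: noise -> latent, 2x200 MLP."""
    return nn.mlp_init(rng, cfg.noise_dim, 200, cfg.d_z)


# --------------------------------------------------------------- checkpoints
class CragModel:
    """Bundle of vocabulary, configuration and all parameter sets."""

    def __init__(self, vocab: Vocabulary, cfg: ModelConfig, seed: int = 0):
        self.vocab = vocab
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.enc = init_encoder(rng, len(vocab), cfg)
        self.dec = init_decoder(rng, len(vocab), cfg)
        self.critic = init_critic(rng, cfg)
        self.pred = init_predictor(rng, cfg)
        self.gen = init_noise_generator(rng, cfg) if cfg.use_noise_generator else None
        # per-property (min, max) over the training corpus, conditional mode
        self.cond_stats: dict[str, tuple[float, float]] = {}

    @property
    def conditional(self) -> bool:
        return self.cfg.cond_dim > 0

    def networks(self) -> dict[str, nn.Params]:
        nets = {"enc": self.enc, "dec": self.dec, "critic": self.critic, "pred": self.pred}
        if self.gen is not None:
            nets["gen"] = self.gen
        return nets

    def scale_condition(self, values: np.ndarray, names: Sequence[str]) -> np.ndarray:
        """Min-max scale raw property values using the stored training ranges."""
        out = np.empty_like(values, dtype=np.float64)
        for j, name in enumerate(names):
            lo, hi = self.cond_stats[name]
            span = hi - lo if hi > lo else 1.0
            out[..., j] = (values[..., j] - lo) / span
        return out

    def save(self, path) -> None:
        manifest = {
            "config": asdict(self.cfg),
            "vocab_tokens": list(self.vocab.tokens),
            "vocab_hash": self.vocab.content_hash(),
            "cond_stats": {k: list(v) for k, v in self.cond_stats.items()},
            "arrays": [],
        }
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
            for net_name, net in self.networks().items():
                for k, arr in net.items():
                    name = f"{net_name}.{k}"
                    manifest["arrays"].append(name)
                    buf = io.BytesIO()
                    np.save(buf, arr)
                    zf.writestr(name + ".npy", buf.getvalue())
            zf.writestr("manifest.json", json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, path, expect_vocab: Vocabulary | None = None) -> "CragModel":
        with zipfile.ZipFile(path) as zf:
            manifest = json.loads(zf.read("manifest.json"))
            vocab = Vocabulary(tokens=tuple(manifest["vocab_tokens"]))
            if vocab.content_hash() != manifest["vocab_hash"]:
                raise ValueError("checkpoint corrupt: vocabulary hash mismatch")
            if expect_vocab is not None and expect_vocab.tokens != vocab.tokens:
                raise ValueError(
                    "checkpoint vocabulary does not match the requested vocabulary"
                )
            cfg = ModelConfig(**manifest["config"])
            model = cls(vocab, cfg, seed=0)
            model.cond_stats = {k: tuple(v) for k, v in manifest["cond_stats"].items()}
            for name in manifest["arrays"]:
                net_name, k = name.split(".", 1)
                arr = np.load(io.BytesIO(zf.read(name + ".npy")))
                model.networks()[net_name][k] = arr
        return model
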