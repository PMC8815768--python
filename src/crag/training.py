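"""Cross-adversarial training loop.

Each batch runs five phases in a fixed order:

1. autoencoder step — minimize token cross-entropy reconstruction loss
   (encoder + decoder, Adam, lr 1e-3);
2. predictor step — cross-entropy on binarized property labels, latents
   treated as constants (no encoder gradient);
3. PGD block — perturb the batch latents into labeled adversarial samples;
4. critic step(s) — ascend the Wasserstein estimate E[f(z)] - E[f(z_hat)]
   (Adam, lr 2e-6), then clip every critic weight into [-c, c];
5. encoder/generator step — descend the same estimate through the encoder
   (Adam, lr 1e-5), critic frozen.

The adversarial latents produced by PGD stand in for the classic prior-noise
generator as the critic's fake distribution; an optional ARAE-style noise
generator can be enabled for comparison. Everything is seeded NumPy, so a run
is bit-reproducible for a fixed seed, config and corpus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import metrics as metrics_mod
from . import nn
from .attack import AttackConfig, adversarial_latents
from .chem import MoleculeRecord, binarize_property, canonicalize, compute_property
from .model import (
    CragModel,
    ModelConfig,
    decode_backward,
    decode_logits,
    encode,
    encode_backward,
    pad_batch,
    predictor_forward,
    reconstruction_loss,
)
from .tokenizer import TokenSequence, build_vocabulary, tokenize

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Optimization constants; the three adversarial rates follow the
    autoencoder/generator/discriminator settings 1e-3 / 1e-5 / 2e-6."""

    lr_ae: float = 1e-3
    lr_gen: float = 1e-5
    lr_critic: float = 2e-6
    lr_pred: float = 1e-3
    batch_size: int = 64
    epochs: int = 10
    clip_c: float = 0.01       # critic weight-clip bound
    n_critic: int = 1          # critic steps per generator step
    seed: int = 0
    eval_samples: int = 500    # molecules generated per epoch for metrics
    attack: AttackConfig = field(default_factory=AttackConfig)
    property_name: str = "logP"
    threshold: float | str = "median"
    predictor_pretrain_epochs: int = 0  # >0 trains the predictor before the loop

    def __post_init__(self):
        if min(self.lr_ae, self.lr_gen, self.lr_critic, self.lr_pred) < 0:
            raise ValueError("learning rates must be >= 0")
        if self.n_critic < 1:
            raise ValueError("n_critic must be >= 1")


LOSS_KEYS = ("L_rec", "L_pred", "L_cri", "L_gen")


@dataclass
class TrainState:
    """Everything ``fit`` accumulates: parameters, optimizers, histories."""

    model: CragModel
    cfg: TrainConfig
    records: list[MoleculeRecord]
    seqs: list[TokenSequence]
    labels: np.ndarray
    cond: np.ndarray | None
    train_canonical: set[str]
    rng: np.random.Generator
    optim: dict[str, nn.Adam]
    epoch: int = 0
    history: dict[str, list[float]] = field(
        default_factory=lambda: {k: [] for k in LOSS_KEYS}
    )
    metrics_history: list[metrics_mod.MetricsReport] = field(default_factory=list)


def _check_finite(loss: float, phase: str) -> float:
    if not np.isfinite(loss):
        raise RuntimeError(f"non-finite loss {loss!r} in {phase}; training aborted")
    return float(loss)


# ------------------------------------------------------------------- phases
def ae_step(state: TrainState, seqs: Sequence[TokenSequence],
            cond: np.ndarray | None = None) -> float:
    """One reconstruction update of encoder + decoder; returns L_rec."""
    m = state.model
    ids, mask = pad_batch(seqs)
    z, enc_cache = encode(ids, mask, m.enc, l_max=m.cfg.l_max)
    if m.cfg.latent_noise_std > 0:
        z = z + state.rng.normal(0.0, m.cfg.latent_noise_std, size=z.shape)
    logits, dec_cache = decode_logits(z, ids, m.dec, cond)
    loss, dlogits = reconstruction_loss(logits, ids[:, 1:])
    _check_finite(loss, "ae_step")
    dec_grads, dz = decode_backward(m.dec, dec_cache, dlogits)
    enc_grads = encode_backward(m.enc, enc_cache, dz)
    state.optim["enc_ae"].step(enc_grads)
    state.optim["dec_ae"].step(dec_grads)
    return loss


def predictor_step(state: TrainState, latents: np.ndarray, labels: np.ndarray,
                   cond: np.ndarray | None = None) -> float:
    """One cross-entropy update of the property predictor only.

    ``latents`` are constants here: no gradient reaches the encoder.
    """
    m = state.model
    labels = np.asarray(labels, dtype=np.int64)
    if labels.min() < 0 or labels.max() >= m.cfg.n_classes:
        raise ValueError(f"labels out of range [0, {m.cfg.n_classes})")
    logits, cache = predictor_forward(latents, m.pred, cond)
    loss, dlogits = nn.cross_entropy(logits, labels)
    _check_finite(loss, "predictor_step")
    grads, _ = nn.mlp_backward(m.pred, cache, dlogits)
    state.optim["pred"].step(grads)
    return loss


def critic_step(state: TrainState, z_real: np.ndarray, z_adv: np.ndarray) -> float:
    """One ascent step on E[f(z)] - E[f(z_hat)], then weight clipping.

    Returns the Wasserstein estimate before the update. Clipping every
    critic parameter into [-c, c] enforces the Lipschitz surrogate.
    """
    m = state.model
    out_r, cache_r = nn.mlp_forward(m.critic, z_real)
    out_f, cache_f = nn.mlp_forward(m.critic, z_adv)
    w_est = float(out_r.mean() - out_f.mean())
    _check_finite(w_est, "critic_step")
    # ascend: gradient of -(E[f(z)] - E[f(z_hat)])
    gr, _ = nn.mlp_backward(m.critic, cache_r, np.full_like(out_r, -1.0 / len(out_r)))
    gf, _ = nn.mlp_backward(m.critic, cache_f, np.full_like(out_f, 1.0 / len(out_f)))
    state.optim["critic"].step({k: gr[k] + gf[k] for k in gr})
    c = state.cfg.clip_c
    for k in m.critic:
        np.clip(m.critic[k], -c, c, out=m.critic[k])
    return w_est


def encoder_adv_step(state: TrainState, seqs: Sequence[TokenSequence],
                     z_adv: np.ndarray, noise: np.ndarray | None = None) -> float:
    """One descent step of the encoder (critic frozen) on the critic's
    distance estimate; updates the optional noise generator too.

    The adversarial samples are fixed inputs, so the encoder gradient comes
    from the E[f(z)] term alone. Returns L_gen = E[f(z)] - E[f(z_hat)].
    """
    m = state.model
    ids, mask = pad_batch(seqs)
    z, enc_cache = encode(ids, mask, m.enc, l_max=m.cfg.l_max)
    out_r, cache_r = nn.mlp_forward(m.critic, z)
    out_f, _ = nn.mlp_forward(m.critic, z_adv)
    l_gen = float(out_r.mean() - out_f.mean())
    _check_finite(l_gen, "encoder_adv_step")
    _, dz = nn.mlp_backward(m.critic, cache_r, np.full_like(out_r, 1.0 / len(out_r)))
    enc_grads = encode_backward(m.enc, enc_cache, dz)
    state.optim["enc_adv"].step(enc_grads)
    if m.gen is not None and noise is not None:
        z_gen, cache_g = nn.mlp_forward(m.gen, noise)
        out_g, cache_c = nn.mlp_forward(m.critic, z_gen)
        _, dz_gen = nn.mlp_backward(
            m.critic, cache_c, np.full_like(out_g, -1.0 / len(out_g))
        )
        gen_grads, _ = nn.mlp_backward(m.gen, cache_g, dz_gen)
        state.optim["gen"].step(gen_grads)
    return l_gen


# ---------------------------------------------------------------------- fit
def _prepare_corpus(corpus: Sequence[str], cfg: TrainConfig, model_cfg: ModelConfig):
    records: list[MoleculeRecord] = []
    skipped = 0
    for s in corpus:
        r = canonicalize(s)
        if r.is_valid:
            records.append(r)
        else:
            skipped += 1
    if skipped:
        logger.warning("skipped %d invalid corpus line(s)", skipped)
    if not records:
        raise ValueError("corpus contains no valid SMILES")
    vocab = build_vocabulary(r.canonical for r in records)
    seqs, kept = [], []
    for r in records:
        try:
            seqs.append(tokenize(r.canonical, vocab, l_max=model_cfg.l_max))
            kept.append(r)
        except ValueError:
            skipped += 1
            logger.warning("skipped over-length molecule %s", r.canonical)
    return kept, seqs, vocab


def fit(
    corpus: Sequence[str],
    cfg: TrainConfig | None = None,
    model_cfg: ModelConfig | None = None,
    epoch_callback=None,
) -> TrainState:
    """Train the full model on a SMILES corpus.

    Per epoch: shuffle, then for each batch run
    ae_step -> predictor_step -> PGD -> critic_step x n_critic ->
    encoder_adv_step; at epoch end generate ``eval_samples`` molecules and log
    a MetricsReport. ``epoch_callback(state)`` runs after every epoch (used by
    the CLI for CSV logs and checkpoints).
    """
    cfg = cfg or TrainConfig()
    model_cfg = model_cfg or ModelConfig()
    records, seqs, vocab = _prepare_corpus(corpus, cfg, model_cfg)

    values = [compute_property(r, cfg.property_name) for r in records]
    labels = np.array(binarize_property(values, cfg.threshold), dtype=np.int64)

    model = CragModel(vocab, model_cfg, seed=cfg.seed)
    cond = None
    if model.conditional:
        raw = np.array(
            [[compute_property(r, p) for p in metrics_mod.CONDITION_PROPERTIES]
             for r in records]
        )
        model.cond_stats = {
            p: (float(raw[:, j].min()), float(raw[:, j].max()))
            for j, p in enumerate(metrics_mod.CONDITION_PROPERTIES)
        }
        cond = model.scale_condition(raw, metrics_mod.CONDITION_PROPERTIES)

    rng = np.random.default_rng(cfg.seed)
    optim = {
        "enc_ae": nn.Adam(model.enc, cfg.lr_ae),
        "dec_ae": nn.Adam(model.dec, cfg.lr_ae),
        "pred": nn.Adam(model.pred, cfg.lr_pred),
        "critic": nn.Adam(model.critic, cfg.lr_critic),
        "enc_adv": nn.Adam(model.enc, cfg.lr_gen),
    }
    if model.gen is not None:
        optim["gen"] = nn.Adam(model.gen, cfg.lr_gen)

    state = TrainState(
        model=model, cfg=cfg, records=records, seqs=seqs, labels=labels,
        cond=cond, train_canonical={r.canonical for r in records},
        rng=rng, optim=optim,
    )

    n = len(seqs)
    if cfg.predictor_pretrain_epochs:
        for _ in range(cfg.predictor_pretrain_epochs):
            order = rng.permutation(n)
            for lo in range(0, n, cfg.batch_size):
                idx = order[lo: lo + cfg.batch_size]
                ids, mask = pad_batch([seqs[i] for i in idx])
                z, _ = encode(ids, mask, model.enc, l_max=model_cfg.l_max)
                cb = None if cond is None else cond[idx]
                predictor_step(state, z, labels[idx], cb)

    for epoch in range(cfg.epochs):
        sums = {k: 0.0 for k in LOSS_KEYS}
        n_batches = 0
        order = rng.permutation(n)
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo: lo + cfg.batch_size]
            batch = [seqs[i] for i in idx]
            cb = None if cond is None else cond[idx]
            yb = labels[idx]

            sums["L_rec"] += ae_step(state, batch, cb)
            ids, mask = pad_batch(batch)
            z, _ = encode(ids, mask, model.enc, l_max=model_cfg.l_max)
            sums["L_pred"] += predictor_step(state, z, yb, cb)
            z_adv = adversarial_latents(z, yb, model.pred, cfg.attack, cb)
            l_cri = 0.0
            for _ in range(cfg.n_critic):
                l_cri = critic_step(state, z, z_adv)
            sums["L_cri"] += l_cri
            noise = (rng.standard_normal((len(batch), model_cfg.noise_dim))
                     if model.gen is not None else None)
            sums["L_gen"] += encoder_adv_step(state, batch, z_adv, noise)
            n_batches += 1

        for k in LOSS_KEYS:
            state.history[k].append(sums[k] / n_batches)
        state.epoch = epoch + 1

        if cfg.eval_samples > 0:
            eval_seed = int(rng.integers(0, 2**31 - 1))
            gen_cond = None
            if model.conditional:
                gen_cond = cond[int(rng.integers(0, n))]
            generated = metrics_mod.generate(
                model, records, cfg.attack, cfg.eval_samples, eval_seed,
                cond=gen_cond,
            )
            state.metrics_history.append(
                metrics_mod.evaluate(generated, state.train_canonical)
            )
        if epoch_callback is not None:
            epoch_callback(state)
    return state


def scaled_config(cfg: TrainConfig, **overrides) -> TrainConfig:
    """Convenience for desk-scale experiments: replace selected fields."""
    return replace(cfg, **overrides)
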