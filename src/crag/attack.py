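"""Projected gradient descent on latent vectors.

Starting from a latent code z with class label y, PGD repeatedly takes a
signed-gradient ascent step on the property predictor's cross-entropy loss
and projects back onto the l-infinity ball of radius epsilon around the
original z:

    z_{k+1} = Proj_{||.-z||_inf <= eps} ( z_k + alpha * sign(grad_z L(omega, z_k, y)) )

The perturbed latent z_hat, relabeled by the predictor, is the model's
"fake"/adversarial sample. The predictor's parameters are never updated
inside the attack. A single step (K=1) is the FGSM special case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .model import predictor_forward, predictor_loss_grad_z


@dataclass
class AttackConfig:
    """PGD ball and step schedule.

    epsilon: l-inf ball radius in latent units; alpha: per-iteration step
    size; steps: iteration count K; random_start: begin from a uniform random
    point inside the ball instead of z itself. The default schedule
    alpha = 2.5 * epsilon / steps lets the iterate reach the ball boundary.
    """

    epsilon: float = 0.1
    alpha: float | None = None
    steps: int = 5
    random_start: bool = False

    def __post_init__(self):
        if self.alpha is None:
            self.alpha = 2.5 * self.epsilon / max(self.steps, 1)
        if self.epsilon < 0 or self.alpha < 0 or self.steps < 0:
            raise ValueError("epsilon, alpha and steps must be non-negative")


@dataclass
class PerturbedLatent:
    """An adversarial latent z_hat with its predictor labels."""

    z_adv: np.ndarray
    label_adv: int
    origin_label: int
    linf_distance: float
    gradient_vanished: bool = False  # every PGD step saw an all-zero gradient


def attack_batch(
    zs: np.ndarray,
    ys: np.ndarray,
    pred: nn.Params,
    cfg: AttackConfig,
    cond: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> list[PerturbedLatent]:
    """PGD on a batch of latents; semantically identical to a per-item loop.

    Per-sample gradients of the summed cross-entropy are independent across
    the batch, so batching changes nothing but speed.
    """
    zs = np.atleast_2d(np.asarray(zs, dtype=np.float64))
    ys = np.asarray(ys, dtype=np.int64).reshape(-1)
    if zs.shape[0] != ys.shape[0]:
        raise ValueError(f"{zs.shape[0]} latents but {ys.shape[0]} labels")
    if zs.shape[0] == 0:
        return []

    z0 = zs.copy()
    z = z0.copy()
    if cfg.random_start:
        if rng is None:
            rng = np.random.default_rng(0)
        z = z0 + rng.uniform(-cfg.epsilon, cfg.epsilon, size=z0.shape)
    vanished = np.ones(z0.shape[0], dtype=bool)
    for _ in range(cfg.steps):
        _, grad = predictor_loss_grad_z(z, ys, pred, cond)
        step = np.sign(grad)
        vanished &= ~np.any(step != 0, axis=1)
        z = z + cfg.alpha * step
        z = np.clip(z, z0 - cfg.epsilon, z0 + cfg.epsilon)
    if cfg.steps == 0:
        vanished[:] = False

    logits, _ = predictor_forward(z, pred, cond)
    labels_adv = np.argmax(logits, axis=1)
    dists = np.abs(z - z0).max(axis=1) if z0.shape[1] else np.zeros(z0.shape[0])
    return [
        PerturbedLatent(
            z_adv=z[b],
            label_adv=int(labels_adv[b]),
            origin_label=int(ys[b]),
            linf_distance=float(dists[b]),
            gradient_vanished=bool(vanished[b]),
        )
        for b in range(z0.shape[0])
    ]


def pgd_attack(
    z: np.ndarray,
    y: int,
    pred: nn.Params,
    cfg: AttackConfig,
    cond: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> PerturbedLatent:
    """Attack a single latent vector. See ``attack_batch``."""
    cond2 = None if cond is None else np.atleast_2d(cond)
    return attack_batch(z[None, :], np.array([y]), pred, cfg, cond2, rng)[0]


def adversarial_latents(zs, ys, pred, cfg, cond=None, rng=None) -> np.ndarray:
    """Convenience: stacked z_adv array from ``attack_batch``."""
    out = attack_batch(zs, ys, pred, cfg, cond, rng)
    if not out:
        return np.empty((0, np.atleast_2d(zs).shape[1]))
    return np.stack([p.z_adv for p in out])
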