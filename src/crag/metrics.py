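"""Molecule generation and the four generation-quality metrics.

Validity is the fraction of generated strings RDKit can parse; uniqueness the
fraction of valid molecules that are distinct as canonical SMILES; novelty the
fraction of unique molecules absent from the training set; Novel/Sample the
product of the three — identically the fraction of generated samples that are
valid, unique and novel. Any ratio with a zero denominator is 0 by convention,
which keeps the product identity exact in rational arithmetic.

Also here: conditional generation under a fixed (logP, SAS, TPSA) target, and
latent-space property optimization — ridge regression of QED on latent codes
gives a direction along which a seed molecule is pushed and re-decoded.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Iterable, Sequence

import numpy as np

from .attack import AttackConfig, adversarial_latents
from .chem import MoleculeRecord, canonicalize, compute_property
from .model import CragModel, encode_sequences, greedy_decode, predictor_forward
from .tokenizer import detokenize, tokenize

CONDITION_PROPERTIES = ("logP", "SAS", "TPSA")


@dataclass(frozen=True)
class MetricsReport:
    """Counts and ratios for one generated batch."""

    n_generated: int
    n_valid: int
    n_unique: int
    n_novel: int

    @property
    def validity(self) -> float:
        return self.n_valid / self.n_generated if self.n_generated else 0.0

    @property
    def uniqueness(self) -> float:
        return self.n_unique / self.n_valid if self.n_valid else 0.0

    @property
    def novelty(self) -> float:
        return self.n_novel / self.n_unique if self.n_unique else 0.0

    @property
    def novel_per_sample(self) -> float:
        return self.n_novel / self.n_generated if self.n_generated else 0.0

    def as_dict(self) -> dict[str, float]:
        return {
            "n_generated": self.n_generated,
            "n_valid": self.n_valid,
            "n_unique": self.n_unique,
            "n_novel": self.n_novel,
            "validity": self.validity,
            "uniqueness": self.uniqueness,
            "novelty": self.novelty,
            "novel_per_sample": self.novel_per_sample,
        }


def evaluate(generated: Sequence[str], training_set: Iterable[str]) -> MetricsReport:
    """Score a generated SMILES list against a pre-canonicalized training set."""
    if len(generated) == 0:
        raise ValueError("evaluate requires a non-empty generated list")
    train = set(training_set)
    canon = [r.canonical for r in map(canonicalize, generated) if r.is_valid]
    unique = set(canon)
    novel = unique - train
    return MetricsReport(
        n_generated=len(generated),
        n_valid=len(canon),
        n_unique=len(unique),
        n_novel=len(novel),
    )


def novel_per_sample(validity: float, uniqueness: float, novelty: float,
                     ndigits: int = 3) -> float:
    """Novel/Sample from the three ratios, rounded half-up to ``ndigits``.

    Matches how benchmark tables report the combined metric from the three
    already-rounded columns.
    """
    product = Decimal(str(validity)) * Decimal(str(uniqueness)) * Decimal(str(novelty))
    q = Decimal(1).scaleb(-ndigits)
    return float(product.quantize(q, rounding=ROUND_HALF_UP))


# ----------------------------------------------------------------- generation
def generate(
    model: CragModel,
    seeds: Sequence[MoleculeRecord],
    cfg: AttackConfig,
    n: int,
    seed: int,
    cond: np.ndarray | None = None,
) -> list[str]:
    """Generate ``n`` raw SMILES by PGD-perturbing encoded seed molecules.

    Seed molecules are drawn uniformly with the run's RNG, encoded, perturbed
    by PGD against the property predictor (the adversarial label is the
    predictor's own at z, so the attack pushes each code across the nearest
    decision region) and greedy-decoded. With epsilon=0 or steps=0 this
    reduces to reconstructing the seeds. Validity is NOT filtered here.
    """
    if n == 0:
        return []
    if not seeds:
        raise ValueError("generate requires at least one seed molecule")
    rng = np.random.default_rng(seed)
    out: list[str] = []
    batch = 256
    while len(out) < n:
        b = min(batch, n - len(out))
        picks = rng.integers(0, len(seeds), size=b)
        seqs = [
            tokenize(seeds[i].canonical, model.vocab, l_max=model.cfg.l_max)
            for i in picks
        ]
        z = encode_sequences(seqs, model.enc, l_max=model.cfg.l_max)
        if model.conditional and cond is None:
            raise ValueError("conditional model requires a condition vector")
        cond_b = None
        if cond is not None:
            cond_b = np.repeat(np.atleast_2d(cond), b, axis=0)
        logits, _ = predictor_forward(z, model.pred, cond_b)
        y = np.argmax(logits, axis=1)
        z_adv = adversarial_latents(z, y, model.pred, cfg, cond_b, rng) if cfg.steps else z
        decoded = greedy_decode(z_adv, model.dec, l_max=model.cfg.l_max, cond=cond_b)
        out.extend(detokenize(s, model.vocab) for s in decoded)
    return out[:n]


@dataclass(frozen=True)
class Condition:
    """Fixed generation target for the three controlled properties."""

    logP: float
    SAS: float
    TPSA: float

    def __post_init__(self):
        if not 1.0 <= self.SAS <= 10.0:
            raise ValueError("SAS target must lie in [1, 10]")

    def as_array(self) -> np.ndarray:
        return np.array([self.logP, self.SAS, self.TPSA], dtype=np.float64)


def conditional_generate(
    model: CragModel,
    condition: Condition,
    seeds: Sequence[MoleculeRecord],
    cfg: AttackConfig,
    n: int,
    seed: int,
) -> list[str]:
    """Generate under a fixed (logP, SAS, TPSA) condition.

    The raw condition is min-max scaled with the training-corpus ranges stored
    in the checkpoint, then fed to the decoder at every step.
    """
    if not model.conditional or not model.cond_stats:
        raise ValueError("model was not trained in conditional mode")
    scaled = model.scale_condition(condition.as_array(), CONDITION_PROPERTIES)
    return generate(model, seeds, cfg, n, seed, cond=scaled)


# ------------------------------------------------- latent property optimization
def fit_latent_direction(
    latents: np.ndarray,
    scores: Sequence[float],
    ridge: float = 1e-6,
) -> np.ndarray:
    """Unit-norm linear-regression direction of a property score on z.

    Solves the (ridge-regularized, centered) least-squares problem
    min_w ||(Z - mean) w - (s - mean)||^2 + ridge ||w||^2 and returns
    w / ||w||. Constant scores give the zero vector (with a warning);
    ridge=0 on a rank-deficient design raises.
    """
    Z = np.asarray(latents, dtype=np.float64)
    s = np.asarray(scores, dtype=np.float64)
    if Z.ndim != 2 or Z.shape[0] != s.shape[0]:
        raise ValueError("latents must be (n, d_z) with one score per row")
    Zc = Z - Z.mean(axis=0)
    sc = s - s.mean()
    A = Zc.T @ Zc + ridge * np.eye(Z.shape[1])
    if ridge == 0:
        # exact least squares: refuse silently-underdetermined problems
        if np.linalg.matrix_rank(Zc) < Z.shape[1]:
            raise np.linalg.LinAlgError(
                "design matrix is rank-deficient; enable ridge regularization"
            )
    w = np.linalg.solve(A, Zc.T @ sc)
    norm = np.linalg.norm(w)
    if norm < 1e-12:
        import warnings

        warnings.warn("scores carry no linear signal; returning the zero vector",
                      stacklevel=2)
        return np.zeros(Z.shape[1])
    return w / norm


def optimize_molecule(
    model: CragModel,
    start: MoleculeRecord,
    direction: np.ndarray,
    step_size: float,
    n_steps: int,
    score_fn: Callable[[MoleculeRecord, np.ndarray], float | None] | None = None,
) -> list[tuple[MoleculeRecord, float | None]]:
    """Walk the latent space along ``direction`` and re-decode at each step.

    The trajectory z_k = encode(start) + k * step_size * direction for
    k = 0..n_steps is greedy-decoded; each step yields (record, score) where
    the score defaults to QED and is None for invalid decodes. All steps are
    returned in order (duplicates included).
    """
    if not start.is_valid:
        raise ValueError("starting molecule must be valid")
    if score_fn is None:
        def score_fn(record, _z):
            return compute_property(record, "QED") if record.is_valid else None

    seq = tokenize(start.canonical, model.vocab, l_max=model.cfg.l_max)
    z0 = encode_sequences([seq], model.enc, l_max=model.cfg.l_max)[0]
    direction = np.asarray(direction, dtype=np.float64)
    trajectory: list[tuple[MoleculeRecord, float | None]] = []
    for k in range(n_steps + 1):
        z = z0 + k * step_size * direction
        decoded = greedy_decode(z[None, :], model.dec, l_max=model.cfg.l_max)[0]
        record = canonicalize(detokenize(decoded, model.vocab))
        trajectory.append((record, score_fn(record, z)))
    return trajectory
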