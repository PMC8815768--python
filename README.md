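# crag

Cross-adversarial molecular generation over SMILES strings.

`crag` is a research implementation of an adversarially regularized SMILES
autoencoder in which the usual prior-noise generator of the ARAE family is
replaced by a **projected gradient descent (PGD) block**: adversarial latent
samples, labeled by a property predictor, play the role of the "fake"
distribution that a Wasserstein critic compares against the encoder's real
latent codes. It is aimed at people experimenting with latent-variable
molecular generators — the whole stack runs on CPU with NumPy and RDKit, and a
synthetic-corpus module makes every stage testable without downloading any
dataset.

## The model

A single-layer LSTM encoder $p_\theta(z\mid x)$ maps a tokenized SMILES string
$x$ to a latent code $z \in \mathbb{R}^{300}$ (the final hidden state); a
single-layer LSTM decoder $q_\phi(x\mid z)$ maps $z$ back to a token sequence,
with $\tilde{x} = \operatorname{argmax} q_\phi(x \mid z)$ at generation time.
A two-layer perceptron $f_\omega$ predicts a binarized molecular property
(median-split logP by default) from $z$. PGD perturbs each code within an
$\ell_\infty$ ball:

$$\hat{z} \leftarrow \Pi_{\|\hat z - z\|_\infty \le \epsilon}
  \bigl(\hat{z} + \alpha\,\mathrm{sgn}\,\nabla_z L(\omega, \hat z, y)\bigr),$$

where $L$ is the predictor's cross-entropy loss. Training alternates three
objectives per batch:

1. $\min_{\theta,\phi} L_{rec}$ — token cross-entropy reconstruction;
2. $\max_{\omega} \mathbb{E}[f_\omega(z)] - \mathbb{E}[f_\omega(\hat z)]$ —
   the critic's Wasserstein estimate, with weight clipping to $[-c, c]$;
3. $\min_{\theta} \mathbb{E}[f_\omega(z)] - \mathbb{E}[f_\omega(\hat z)]$ —
   the encoder descends the same estimate with the critic frozen.

Generated batches are scored with the four standard metrics — validity
(parseable fraction), uniqueness (distinct canonical SMILES among valid),
novelty (unique molecules absent from the training set) and **Novel/Sample**,
the product of the three, identically the fraction of samples that are valid,
unique and novel. Conditional generation concatenates a min–max-scaled
(logP, SAS, TPSA) target to every decoder input; property-targeted
optimization walks a latent code along the unit direction recovered by ridge
regression of QED on $z$.

All networks and gradients are implemented in NumPy (hand-written backprop,
verified against finite differences in the test suite); chemistry goes through
RDKit.

## Worked example

```python
from crag import (AttackConfig, ModelConfig, TrainConfig, evaluate, fit,
                  generate, generate_fixture_smiles)

corpus = generate_fixture_smiles(200, seed=42)   # small valid molecules, <= 9 heavy atoms
state = fit(
    corpus,
    TrainConfig(epochs=20, batch_size=64, eval_samples=200, seed=0),
    ModelConfig(d_z=48, d_embed=24, critic_hidden=48, predictor_hidden=48, l_max=40),
)
print(f"L_rec epoch 1 -> 20: {state.history['L_rec'][0]:.3f} -> {state.history['L_rec'][-1]:.3f}")

samples = generate(state.model, state.records, AttackConfig(epsilon=0.3, steps=5),
                   n=200, seed=1)
report = evaluate(samples, state.train_canonical)
print(f"validity={report.validity:.3f} uniqueness={report.uniqueness:.3f} "
      f"novelty={report.novelty:.3f} novel_per_sample={report.novel_per_sample:.3f}")
```

prints

```
L_rec epoch 1 -> 20: 2.483 -> 1.614
validity=1.000 uniqueness=0.005 novelty=1.000 novel_per_sample=0.005
```

The reconstruction loss falls as the autoencoder learns, and every generated
string is a parseable molecule not in the training corpus — but at this desk
scale (200 molecules, 20 epochs, 48-dim latent) the decoder has collapsed onto
a single output, so uniqueness is near zero. That trade-off between the four
metrics is exactly what Novel/Sample summarizes: high validity means little
when it is bought with repetition. Full-scale corpora and training budgets are
needed for competitive absolute numbers.

There is also a CLI:

```bash
crag fixtures --n 500 --seed 1 --out train.smi
crag train --data train.smi --out runs/demo        # per-epoch CSV + checkpoints
crag sample --ckpt runs/demo/final.ckpt --data train.smi --n 100 --out gen.smi
crag evaluate --generated gen.smi --train train.smi
crag optimize --ckpt runs/demo/final.ckpt --data train.smi --smiles "CCO" --steps 10
```

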