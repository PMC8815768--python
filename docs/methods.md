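# Methods

## Model

The generator is an adversarially regularized autoencoder over SMILES token
sequences in which the adversarial ("fake") latent distribution is produced by
a projected-gradient-descent attack on a property predictor rather than by a
prior-noise generator.

**Encoder.** Token embeddings (dimension 128 by default) feed a single LSTM
layer with hidden size `d_z` (default 300); the hidden state at each
sequence's last real token is the latent code z. The encoder is
deterministic. An optional Gaussian perturbation on z during training
(`latent_noise_std`, default 0) covers a variational reading of the
architecture; it also turns out to be the practical way to make conditional
decoding load-bearing (below).

**Decoder.** A single LSTM layer whose initial hidden state is z (initial
cell state zero), with its own embedding table and an output projection to
the vocabulary. Training is teacher-forced; generation is greedy argmax with
ties broken toward the lowest token index, stopping at EOS or at `l_max`
(default 60 tokens). The PAD logit is masked at decode time so padding can
never be emitted mid-sequence.

**Critic and predictor.** Both are two-layer ReLU perceptrons with hidden
width 200. The critic maps z to one scalar; the difference of its batch means
on real versus adversarial codes estimates the Wasserstein distance. The
predictor emits K class logits (K = 2 by default) for a binarized molecular
property — median-split logP unless configured otherwise; the median split is
used because the predictor loss is cross-entropy, which needs discrete
labels. The critic and the predictor are deliberately two distinct networks
even though they play symmetric roles in different parts of the objective.

**Reconstruction loss** is mean token-level cross-entropy over non-PAD
positions. Sequences are discrete, so a squared distance between token
sequences would be ill-defined; cross-entropy is the loss actually minimized.

## PGD block

For each latent z with label y, K iterations (default 5) of
`z <- clip(z + alpha * sign(grad_z L(omega, z, y)), z0 - eps, z0 + eps)`,
with L the predictor cross-entropy. The perturbation set is the l-infinity
ball: the sign step is the canonical l-inf PGD update. Defaults: eps = 0.1
latent units, alpha = 2.5*eps/K so the ball boundary is reachable,
random_start off (the attack grows from the real sample). No box clipping is
applied to latents — unlike images, latent space has no data range. A
gradient that is exactly zero at every iteration returns z unchanged with a
`gradient_vanished` flag rather than an error. The perturbed code is
relabeled by the predictor; K = 1 recovers the FGSM special case.

## Training loop

Per batch, in fixed order: (1) autoencoder reconstruction step; (2) predictor
step on the batch latents, which are treated as constants so no gradient
reaches the encoder; (3) PGD generation of adversarial latents; (4) n_critic
critic ascent steps (default 1) on E[f(z)] - E[f(z_hat)], each followed by
clipping every critic weight into [-c, c] (default c = 0.01) as the Lipschitz
surrogate; (5) one encoder descent step on the same estimate with the critic
frozen — the adversarial samples are fixed inputs there, so the encoder
gradient flows through the E[f(z)] term. All parts use Adam, with learning
rates 1e-3 (autoencoder), 1e-5 (encoder-adversarial/generator) and 2e-6
(critic). The predictor rate is not separately specified anywhere
authoritative; it uses the autoencoder rate 1e-3. Batch size defaults to 64.

The adversarial latents replace the classic prior-noise generator as the
critic's fake distribution. An optional ARAE-style noise generator (2x200
MLP, noise dim 100) can be enabled for comparison; when on, it is trained to
raise the critic's score of its samples with the generator learning rate.
Whether the predictor should be pre-trained before the adversarial phases is
ambiguous; both orders are supported (`predictor_pretrain_epochs`), default
joint per-batch training.

At each epoch's end the model generates `eval_samples` molecules (default
500; the headline experiments use 10,000, scaled down here) from PGD-perturbed
encodings of randomly drawn training molecules and logs a metrics report, so
a run traces the per-epoch validity/uniqueness/novelty/Novel-per-Sample
curves. Everything is seeded NumPy running single-threaded, so a run is
bit-reproducible given seed, config and corpus.

## Data handling

Corpora are canonicalized before training; unparseable lines are skipped with
a logged count rather than failing, and over-length molecules likewise. The
vocabulary is built from the canonical forms: specials (PAD, BOS, EOS, UNK) at
fixed indices 0-3, corpus tokens after them in sorted order, making the build
deterministic and order-insensitive. Tokenization is character-level with a
fixed longest-match table (two-letter elements, whole bracket atoms, %nn ring
closures) — the standard reversible scheme for recurrent SMILES models.

Uniqueness and novelty compare canonical SMILES, not raw strings ("OCC" and
"CCO" are one molecule). Novelty is counted against the full training corpus.
Ratios with zero denominators are 0; reported combined metrics round half-up
to 3 decimals.

## Synthetic corpus

`generate_fixture_smiles` emulates small-organic datasets of up to 9 heavy
atoms over {C, N, O, F}: random valence-respecting trees, optional 3-6
membered ring closures (p = 0.35) and carbonyl decorations (p = 0.3), built
as molecular graphs and sanitized by RDKit, so every emitted string is valid
by construction. What it does **not** emulate: aromatic systems, charged or
bracket atoms, stereochemistry, and the property diversity of drug-like
libraries. Passing tests on this corpus therefore demonstrates the mechanics
(reconstruction, adversarial shaping, metric accounting) at small scale, not
chemical coverage; absolute metric values from fixture-scale runs say nothing
about full-scale benchmark performance, and generation at this scale visibly
collapses in uniqueness.

## Conditional mode

With `cond_dim = 3`, a (logP, SAS, TPSA) vector — min-max scaled per property
over the training corpus, ranges stored in the checkpoint — is concatenated
to the decoder input at every step and to the predictor input (concatenation
conditioning, in the conditional-ARAE style; an architectural choice, not an
established fact of the original design). Because a noiseless autoencoder
makes the condition redundant given z, conditional training is run with
substantial latent noise (the two-scaffold test uses std 1.0) so the decoder
must actually consult the condition; the test demonstrates that conditioning
on each mode of a bimodal-TPSA corpus shifts the mean TPSA of generated
molecules accordingly.

## Latent property optimization

`fit_latent_direction` ridge-regresses (default ridge 1e-6) a property score,
typically QED, on latent codes after centering, returning the unit-norm
weight vector; constant scores return a flagged zero vector, and exact least
squares (ridge 0) refuses rank-deficient designs. `optimize_molecule` decodes
the trajectory z_k = z_0 + k * step_size * direction, recording each decoded
molecule and its score (None for invalid decodes), duplicates included — step
size and stopping are caller-chosen, with no claimed canonical defaults.

## Numerical notes

All networks and backward passes are hand-written NumPy, validated against
central finite differences to ~1e-9 relative error in the suite. LSTM forget
gates start with bias 1; weights are Glorot-uniform. Adam with lr = 0 is an
exact no-op (weight clipping still applies in the critic step, by design).
One closed-form caveat: for an exactly linear predictor the one-step PGD
margin drop equals alpha * ||w||_1, but if logits carry a huge constant
offset, softmax saturation (p -> 1 rounding to 1.0 in float64) destroys the
cancellation this identity relies on; the linear-oracle tests therefore
construct predictors whose logits are exactly z @ W2.

## Scale choices

The test suite and the acceptance script run the study miniaturized: 200
fixture molecules, 20 epochs, latent width 48, 200 generated molecules per
evaluation, chosen so the full suite completes in well under a minute on one
CPU while still exhibiting the qualitative behaviors (loss trends, clipping,
perfect small-corpus reconstruction, metric accounting). The default
`ModelConfig`/`TrainConfig` keep the full-scale constants (d_z 300, hidden
200, the three learning rates, batch 64).
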