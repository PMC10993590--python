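# Methods

## Pipeline overview

`xairob` studies how stable per-token attributions are when a SMILES
transformer is shown different strings of the same molecule. The pipeline
is: clean and canonicalize molecules → tokenize → (optionally pre-train a
representation) → transfer-learn a binary toxicity head on a frozen
encoder → attribute test molecules with eight XAI methods under
test-time augmentation (TTA) → align attributions to canonical atom order
→ report robustness distances, entropy and structural-alert importance,
always alongside a randomly initialised control model.

## Data model and cleaning

A molecule's identity is its canonical SMILES. Cleaning removes
stereochemistry annotations, keeps the largest fragment by heavy-atom
count (ties broken by lexicographic order of the fragments' canonical
SMILES, so the choice is deterministic), re-sanitizes, and collapses
duplicates to the first occurrence. Duplicates with conflicting labels
are dropped entirely rather than resolved by majority — with label noise
present, any resolution rule would manufacture a label; dropping is
conservative and logged. All structure handling is RDKit.

Scaffold splits group molecules by Bemis–Murcko scaffold and assign whole
groups largest-first to train, then validation, then test (80/10/10), so
test molecules are structurally out-of-domain.

## Tokenization

Character-level tokenization with three exceptions that keep one token
per heavy atom: `Cl` and `Br` are single tokens, and any bracket atom
(`[nH]`, `[N+]`, …) is a single token. This bijection between atom tokens
and heavy atoms is what makes atom-level alignment exact. The vocabulary
is a fixed 68-code table: 4 specials (BOS, EOS, PAD, MASK), 36
single/double-character SMILES symbols, and 28 curated bracket-atom
tokens covering the charged/protonated states that survive cleaning. A
character outside the table is a hard error, not an `<unk>`: silently
remapping tokens would corrupt both model inputs and atom alignment.
Sequences are `BOS + tokens + EOS`, padded to a fixed length; the maximum
SMILES length is 175 tokens (177 with specials).

Masking corruption (for masked pre-training regimens) selects each
non-special position independently with probability 0.15; a selected
position becomes MASK with probability 0.80, a uniformly random
non-special token with 0.10, or stays unchanged with 0.10. The plan
(ground truth) is returned alongside the corrupted sequence.

## Models

The encoder is a standard pre-LN-free transformer: token embedding scaled
by √E plus sinusoidal positions, then L layers of multi-head softmax
attention (with PAD keys masked) and a ReLU feed-forward block, each with
residual connection and layer normalisation. Per layer the forward pass
stores the head-wise attention matrices α (row-stochastic by
construction) and the attention-block output h after the W^O projection —
the two intermediates the gradient-based attribution methods need.

Defaults are standard for character-level SMILES transformers — embedding
512, vocabulary 68, max length 175, Xavier initialisation, AdamW (weight
decay 0.01), dropout 0.1 pre-training / 0.3 transfer, learning rates
1e-4 / 5e-5, batch 128 — with depth L=3 and heads h=8 chosen to keep the
default encoder under a 16.5 M parameter budget. Demo and test configurations use much smaller widths
(E=16–64, L=1–2); all dimensions are overridable.

Two pre-training architectures share the encoder: encoder-only (a
per-position MLP emits the output string, BERT-style) and encoder-decoder
(a causal transformer decoder with cross attention, greedy-decoded for
sequence accuracy). Pre-training is auto-translation to canonical SMILES
from canonical (C2C), randomized (R2C) or enumerated (E2C = up to ten
randomized + the canonical) inputs, with an `M` prefix adding input
masking. Early stopping monitors validation cross-entropy with patience 5
and restores the best state.

Transfer learning freezes the encoder and trains a head — masked max-pool
+ two-layer MLP, or a TextCNN (kernels 3/4/5, 100 filters each, one
highway unit) — on binary labels. Because the encoder is frozen, its
outputs are cached once and the head is trained on the cached features;
this is mathematically identical to backpropagating through frozen
weights and much cheaper. Frozenness is verified by SHA-256 digest of the
encoder weights before and after, not assumed. At desk scale the head is
trained with lr 1e-3: the default transfer rate (5e-5) suits fine-tuning
over thousands of molecules and is far too slow for a few-hundred-sample
head-only fit. The "randomized" control model is the
same architecture, Xavier-initialised and never trained.

## Attribution methods

All eight methods emit one value per full-string token position
(BOS/EOS/PAD included). Scores with an extra axis are averaged down:
an (S, E) score over the embedding axis; an (S, S) attention-shaped score
over the **query** axis, so φⱼ is the mean attention (or
attention-gradient) token j *receives*. The alternative — averaging each
query's row — is degenerate for attention itself: rows of a softmax
matrix sum to one, so every row mean is the constant 1/S and all
attention-map explanations of all inputs would be identical. The received
convention is used uniformly for all square scores so the family stays
comparable.

- **Attention Maps** — last-layer attention, head-averaged.
- **Rollout** — per-layer head-averaged attention combined with the
  residual path as ½(α + I), row-renormalised, multiplied through the
  layers. A `literal` switch multiplies the raw attention matrices
  instead (under which a one-layer rollout coincides with Attention
  Maps); the default follows the standard rollout construction because
  multiplying by the identity alone is a no-op that ignores the residual
  stream.
- **Grads** — gradient of the class logit w.r.t. last-layer attention,
  head-averaged.
- **AttGrads** — Σₗ (head-averaged ∇α) ⊙ (head-averaged α).
- **CAT** — Σₗ ∇h ⊙ h, embedding-averaged.
- **AttCAT** — CAT with each token's term scaled by the mean attention it
  receives.
- **Integrated Gradients** — path integral of ∇f on the straight line in
  embedding space from an all-PAD baseline to the input, holding the
  attention PAD mask fixed at the input's (the function being integrated
  must not change along the path). PAD is the baseline because it is the
  only semantically empty token; the baseline is configurable.
- **SHAP** — Shapley values of the game whose players are the non-special
  tokens; "absent" replaces a token by PAD and the payoff is the class
  logit. Exact mode enumerates all 2ⁿ coalitions (n ≤ 12); sampled mode
  averages marginal contributions over seeded random permutations.
  Coalition evaluations are batched through the forward pass.

Gradients of the class logit with respect to α and h are read directly
off the autodiff tape after one backward pass — exact to machine
precision, as the finite-difference tests verify. By default the
*predicted* class is attributed; a fixed class index can be forced.

### Integrated-gradients quadrature

The path derivative of a ReLU/max-pool network is piecewise smooth with
jump discontinuities wherever an activation pattern or pooling argmax
switches, and a plain midpoint rule can leave a completeness gap of
several percent at 256 steps. The integrator therefore uses a per-cell
control variate: the exact mass of each cell, f(b) − f(a) from two cheap
forward evaluations at its boundaries, is distributed over the per-dimension
midpoint-gradient direction. Cells where the midpoint direction disagrees
with the exact mass by more than a factor 5 (an activation switch inside
the cell) are subdivided once into 8 sub-cells instead of rescaled. As
steps → ∞ this converges to the same limit as the plain Riemann sum,
while the completeness axiom Σφ = f(x) − f(x̄) holds to well under 1% of
|f(x) − f(x̄)| at the default 64 steps. The realised gap is always
reported on the attribution.

## Normalisation, alignment and metrics

Attributions are normalised by the absolute sum over the full token
string: φ̂ᵢ = φᵢ / Σₖ|φₖ| (signs preserved). An all-zero vector — possible
for the gradient family on a constant-output control — passes through
with a flag and is excluded pairwise from distance statistics.

Alignment extracts the atom-token entries of φ̂ and places entry *a* at
the atom's canonical rank, computed with RDKit's canonical atom ranking
(ties broken), which assigns each atom of a molecular graph the same rank
regardless of which SMILES string produced it. Aligned vectors of
different strings of one molecule are therefore comparable entry by
entry; a tokenizer/parser disagreement on atom count raises rather than
misaligns.

- **Cosine distance** 1 − u·v/(‖u‖₂‖v‖₂) on the aligned *signed* values;
  range [0, 2]. The robustness score of an augmentation set is the mean
  of the off-diagonal pairwise matrix — the diagonal is structurally zero
  and would only dilute the mean (switchable).
- **Entropy** is Shannon entropy in bits of the |values| renormalised to
  sum 1 (signed values carry no probability interpretation), with
  0·log 0 := 0; bounded by log₂(heavy-atom count).
- **Relative importance** of a component (full string / SMILES tokens /
  atom tokens / alert atoms) is by default Σ|φ̂ᵢ| over the component's
  positions, so fractions lie in [0, 1] and disjoint components add to 1;
  a `signed` switch sums φ̂ᵢ instead for the literal signed reading.
- **TTA averaging** is the arithmetic mean of aligned vectors; the
  in-between-model and in-between-method comparisons can use canonical
  vectors or TTA-averaged vectors.

## Statistics

Mann–Whitney U (two-sided, tie-corrected) uses the exact null
distribution when both groups have ≤ 8 observations and no ties, and the
normal approximation otherwise; the test suite validates it against
exhaustive permutation enumeration for all group sizes ≤ 6. Test-time
bootstrapping resamples (score, label) pairs with replacement to full
test length, 1000 times by default; resamples containing a single class
are redrawn (keeping the replicate count fixed) and counted.
Classification metrics (AUROC, accuracy, F1, MCC, precision, recall) are
scikit-learn's. The carbon-dependence diagnostic buckets per-molecule
robustness scores by heavy-carbon count and reports per-bucket
median/IQR and a Spearman rank correlation (0 for constant scores,
flagged undefined for a single bucket).

## Synthetic data

The generator assembles SMILES from a fragment grammar — alkyl chains,
ethers, amines, benzene/pyridine/thiophene/cyclohexane/THF rings, halogen
and carboxyl terminals — validated by RDKit and deduplicated, up to 60
tokens. With a planted alert (default: the nitro group `[N+](=O)[O-]`,
the classic mutagenicity toxicophore), about half the molecules carry the
alert and labels are `contains(alert) XOR Bernoulli(ε)` with ε = 0.1 by
default, emulating assay noise on an otherwise separable task. Everything
is seeded.

What the generator does *not* emulate: realistic chemical space coverage,
stereochemistry, charged states beyond the alert, tautomers, or label
structure more subtle than one toxicophore. Green tests on this corpus
show the machinery is correct and that the qualitative phenomena
(trained vs randomized overlap, TTA-averaging effects) are measurable at
desk scale — not that any particular attribution method is adequate on
real mutagenicity data.

## Problem sizes

The shipped study uses 500 synthetic molecules, an L=2 / E=64 encoder,
all eight methods on 50 scaffold-split test molecules with 3 augmentations
each, plus a randomized control — sizes chosen so a complete run finishes
in minutes on one CPU core while every statistic remains well-populated.
The test suite uses smaller models (E=16–48, L=1–2) and corpora (6–200
molecules) per check.

## Known limitations

- Cosine distances use signed normalised values; an absolute-value
  variant would rank some pairs differently.
- The in-between-method distance averaged over TTA is a *reported*
  comparison: with few augmentations and tiny models the averaging
  benefit seen at full scale need not reproduce.
- Exact SHAP is capped at 12 tokens (4096 coalitions); longer inputs use
  permutation sampling with a reported efficiency gap.
- Pre-training at realistic corpus scale (millions of molecules) is out
  of scope; the pre-training code is exercised at memorization scale.
- Only frozen-encoder transfer is implemented; unfreezing would require
  full-encoder optimisation that desk-scale budgets don't justify.
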