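# Methods

`latentmol` implements an inverse-QSAR workflow: molecules are mapped to
a continuous, decodable descriptor space by a sequence-to-sequence
translator; property models and desirability scoring define a fitness
surface over that space; and a particle swarm searches it for improved,
decodable molecules under similarity and substructure constraints.
This note records the models, assumptions, numerical choices and
limitations.

## 1. The reversible SMILES translator

**Model.** A recurrent encoder–decoder over character-level SMILES
tokens.  The tokenizer is character-level with the standard exceptions:
two-letter organic-subset atoms (`Cl`, `Br`), whole bracket-atom groups
(`[nH]`, `[O-]`) and two-digit ring closures (`%12`) are single tokens;
pure per-character splitting would make `Cl` ambiguous with `C`+`l`.
The encoder is three stacked GRU layers followed by a fully connected
bottleneck of 512 units with tanh activation, so every latent component
lies in [−1, 1] by construction — an architecture-level contract, not a
training outcome.  The decoder is three stacked GRU layers; the latent
vector initializes each decoder layer's hidden state through a learned
tanh-activated linear map and is also concatenated to the token
embedding at every decoding step, so the decoder can consult the
molecule representation at any position.  A final linear layer over the
top GRU's states produces token logits.

**Training objective.**  Pairs are (enumerated SMILES rendering →
canonical SMILES): the encoder reads an arbitrary rendering of a
molecule, and the decoder is teacher-forced on the canonical form under
per-token cross-entropy.  Translating between renderings, rather than
copying, forces molecule-level features into the bottleneck.  Ten
renderings per molecule are generated by random atom-renumbering of the
canonical writer, deduplicated, with a 10× attempt budget.

**Regularization and optimization.**  Input embeddings receive dropout
0.15 and additive zero-mean Gaussian noise (sd 0.05) during training
only.  Optimization is Adam (lr 1e-3 in the full profile; the
desk-scale profile uses 2e-3) with a 1/(1+0.01·epoch) decay, global
gradient-norm clipping at 5, and decoupled weight decay (0.01 in the
desk profile) on weight matrices.  Batches of 64 are length-sorted to
reduce padding, with batch order shuffled per epoch.  Training splits
the corpus 9:1 *by molecule* — every rendering of a molecule lands in
one split — and stops when held-out teacher-forced character accuracy
has not improved by 0.1 percentage points for 8 consecutive epochs
(desk profile: patience equal to the epoch budget is also used when a
full trace is wanted); the best-scoring weights are restored.

**Implementation.**  The network, backpropagation-through-time, Adam
and beam search are implemented directly in NumPy (float32, batched
matrix products; `src/latentmol/_nn.py`).  The backward pass is checked
against finite differences in development.  All stochastic behaviour —
initialization, dropout, noise, splitting, enumeration, batching —
derives from explicit seeds, so training runs are bit-reproducible.

**Profiles.**  The conformant full profile uses decoder GRUs of
1024/512/256 units (encoder mirrored in reverse) and 128-d embeddings.
The desk-scale profile — used by the test suite and the acceptance
script — keeps the 512-d tanh bottleneck but uses 96-unit GRUs and
64-d embeddings so that training on the synthetic corpus takes minutes
on one CPU.  `TranslatorConfig.full_profile` flags the distinction.

**Decoding.**  Beam search over cumulative log-probability with stable
tie-breaking by (score, then token index); width 1 is exactly greedy
argmax decoding, and a batched greedy decoder evaluates whole swarms in
one pass.  Arbitrary latent points may decode to syntactically invalid
strings; these are returned flagged, never raised.  The maximum decode
length is twice the longest training sequence, capped by config.

**Character accuracy.**  The headline translation metric is
teacher-forced character accuracy: the fraction of positions where the
argmax prediction matches the ground-truth character, computed over all
non-padding target positions (micro average), with the ground-truth
prefix supplied at every step.  The free-running analog is the
round-trip rate: the fraction of molecules whose top decode of their
own encoding canonicalizes back to the input.  Teacher-forced accuracy
is the headline number; the round-trip rate is the stricter,
error-compounding measure.

## 2. Synthetic corpus and planted labels

No external data is used anywhere.  The fixture generator assembles
molecules from a small, valence-clean fragment grammar: carbon chains
of 1–7 atoms with an optional single methyl branch, terminal groups
from {none, O, N, F, Cl}, and an optional terminal phenyl ring.  The
grammar spans roughly a few hundred distinct molecules, so a
200-molecule corpus covers the family densely and every held-out
molecule has close homologs in training.  (Grammars with freer
heteroatom placement were tried and generalize measurably worse: atoms
whose canonical ordering depends on subtle invariants make the
rendering→canonical mapping harder to induce from 180 examples.)  This is a
deliberate design point: the corpus exists to let a desk-scale
translator learn the rendering→canonical mapping *systematically* (the
full-scale analog relies on millions of molecules instead).  It is
**not** chemically representative — no stereochemistry, charges,
fused rings, or drug-like scaffolds — so translation metrics on it
bound nothing about real chemical space; they demonstrate the pipeline
mechanics only.

Planted property labels are structure-derived quantities — heteroatom
fraction, scaled heavy-atom count, ring presence — plus Gaussian noise
(default sd 0.05), giving the property-model harness a recoverable
ground truth that exercises the true encode→features→model pipeline.

## 3. Property models

SlogP (Crippen atomic contributions), QED and the fragment-contribution
synthetic-accessibility score are computed directly from structure via
RDKit.  Trainable endpoints are gradient-boosted tree ensembles
(XGBoost) over the 512-d latent features.  Defaults: 800 trees of depth
2, learning rate 0.1, early stopping on a 10% validation carve-out.
Shallow trees are a deliberate choice: with a few hundred training rows
and 512 correlated features, depth-2 boosting recovers additive signal
well (planted-signal CV R² ≈ 0.86) where depth-6 trees overfit
(CV R² ≈ 0.54); every value is exposed in `GBTConfig`.  The evaluation
protocol is a 75/25 train/test split (random by default, or a MaxMin
maximum-diversity sweep on Tanimoto distance via
`diverse_split`) with 5-fold cross-validation on the training portion;
metrics are RMSE/MAE/R² for regression and accuracy/sensitivity/AUC for
classification, reported as mean ± sd over folds plus the held-out
value.  Nine customary ADMET endpoint definitions (logD7.4, logS,
Caco-2, MDCK, PPB, AMES, hERG, hepatotoxicity, LD50 — the last treated
as a classification endpoint) ship with editable default ranges; no
trained weights are distributed.  An optional augmentation re-encodes
enumerated renderings of each training molecule, copying labels
(off by default).

## 4. Desirability scoring

Each objective rescales a raw value into S ∈ [0, 1]: exactly 1 inside
the closed optimal range, 0 at or beyond the recommended range, and a
linear interpolation on the shoulders — the simplest monotone choice,
isolated in one function (`desirability`) so it can be swapped.
One-sided objectives carry infinite bounds on the unbounded side.  The
final score is F = Σ SᵢWᵢ / Σ Wᵢ, invariant under uniform weight
rescaling.  The similarity constraint (Tanimoto on 2048-bit radius-2
Morgan fingerprints, the ECFP4-equivalent) scores 1 at or above the
threshold and ramps linearly to 0 below it — a soft score by default so
it composes with the weighted mean; strict mode turns it into a hard
filter.  The substructure constraint is binary SMARTS matching and is
hard by default: a molecule missing the motif scores F = 0 regardless
of its other properties.  Invalid molecules score F = 0.

## 5. Particle swarm optimization

Standard velocity/position updates: inertia plus cognitive attraction
to the particle's historical best plus social attraction to the swarm's
historical best, with r1, r2 drawn per particle per step from
Uniform(0,1).  Defaults: inertia 0.9 decayed linearly to 0.4 (flag to
hold constant), c1 = c2 = 2.0, swarm 100, velocities capped at 1.0 per
component, positions clipped to [−1, 1] after each move (the decoder
was only ever trained on tanh-range vectors).  Personal and global
bests replace only on strictly greater scores, so equal scores keep the
earlier best and the swarm-best trajectory is non-decreasing by
construction.  The swarm is initialized at the encoder output: one
particle exactly at the seed encoding, the rest with isotropic Gaussian
jitter (sd 0.1 by default), velocities zero.

**Evaluation.**  Each position is decoded (batched greedy by default;
beam search optional), the top valid candidate canonicalized, and the
molecule scored; positions with no valid decode score 0.  Property
models that consume latent features are fed the *re-encoded decoded
molecule*, not the raw particle position, so every reported score
belongs to a realizable structure.  Scores are cached per canonical
SMILES.  Each iteration's newly decoded valid molecules are ranked by F
and the top-k kept; restarts run independent swarms from child seeds of
the master seed, and results merge by canonical SMILES keeping each
molecule's best report.  Ranking of the final table is F descending,
then similarity to seed, then lexicographic SMILES.  A raw-position
hook (`run_pso` with any vectorized objective) supports analytic
surfaces for testing.

**High-dimensional behaviour.**  On the separable surface
f(z) = 1 − mean|z|, the swarm converges essentially to the optimum
within 50 iterations at low dimension (d ≈ 8) but not at d = 512: the
update rule learns only from whole-vector rank comparisons
(best-replacement, no recombination), whose information rate limits
relative progress to roughly ln(swarm size)/d per iteration — about
0.9%/iteration at d = 512, an empirical plateau of F ≈ 0.7 from a 0.5
start regardless of constants (verified over a broad scan of inertia
schedules, c1/c2, velocity caps and swarm sizes, with both scalar and
per-component uniform draws; scalar draws, the documented choice, were
slightly better).  In the intended use this is not the operative
regime: swarms start at an encoded seed molecule and exploit local
structure of the decode-and-score surface rather than solving a global
512-d problem.

## 6. Problem sizes used by the test suite and acceptance script

Desk-scale throughout, chosen so the full pipeline runs in minutes on
one CPU: 200-molecule corpus × 10 renderings, 9:1 split; property
recovery at n = 500 with noise sd 0.1; optimization demonstrations with
swarms of 10–30, 4–15 iterations, 2–3 restarts.  The full profile
(1024/512/256 decoder, swarm 100 × 50 iterations × 100 restarts)
is the configured default for real use.

## 7. Known limitations

- The synthetic grammar's narrowness means translation metrics say
  nothing about drug-like chemical space; a real deployment needs a
  large real corpus and the full profile.
- Teacher-forced accuracy at corpus size 200 saturates below the
  full-scale figure (0.96–0.99 held-out on the fixture family across
  training seeds): with 180 training molecules the model partially
  memorizes rather than fully inducing the canonicalization rule.
  Round-trip rates, which compound per-token errors, run lower still
  (0.75–0.85 held-out).  Both rise with corpus size, not with model
  capacity — 128-unit and 96-d-embedding variants score the same.
- Stereochemistry is passed through tokenization but the enumeration
  and grammar make no stereo-diversity claims.
- PSO constants are standard but untuned per task; the high-dimensional
  information bound above applies to any purely rank-based swarm.
- Property endpoint ranges ship as editable defaults, not assertions;
  no trained ADMET weights are included.
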