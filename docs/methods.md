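# Methods

## Data model

A molecule is parsed from SMILES with RDKit (default sanitization and
aromaticity perception; kekulized input is re-aromatized, stereochemistry
is assigned before featurization). Graphs contain heavy atoms only —
hydrogens stay implicit, which is consistent with the degree feature
counting *heavy* neighbours. Every bond yields two opposed directed
edges; four index lists (edge source/target, per-node incoming edges, the
reverse-edge involution, per-node neighbours) fully describe the graph and
are what the encoder consumes. The per-node edge list stores *incoming*
edges because the final aggregation sums messages arriving at each node.

Feature layout (all one-hot / binary):

- atom: atomic number 1–118 (118), heavy-neighbour count 0–5 (6, counts
  above 5 clamp to the last bucket with a warning), formal charge −2…+2
  (5, clamped into range with a warning), chirality R/S/unspecified/
  unrecognized (4, from CIP codes where assignable), hybridization
  sp…sp³d² (5; anything else leaves the block all-zero), aromatic flag
  (1) — 139 total;
- bond: order single/double/triple/aromatic (4), in-ring (1), stereo
  none/any/Z/E/cis/trans (6) — 11 total.

Dataset cleaning collapses duplicate *structures* (canonical-SMILES
identity, not string identity, since one structure has many SMILES),
keeping the per-property maximum of the observed values and OR-ing the
observation masks; unparseable rows are logged and dropped. Cleaning is
idempotent and keeps first-occurrence order.

## Encoder

The directed-edge message passing recursion and the node aggregation are
exactly the three equations in the README. Updates are synchronous
(Jacobi-style): every depth-d message is computed from depth-(d−1)
messages, which satisfies the rule that a node forwards to y only what it
received from its other neighbours. The neighbour sum for edge x→y is
computed as (all messages into x) − (message y→x), via a scatter-add over
the edge index lists. No bias terms are used: the recursion is a pure
composition of matrix products and the activation. The default
activation is ReLU; Tanh, ELU, LeakyReLU, SELU and a fixed-slope (0.25)
variant of PReLU are selectable so the whole activation axis of the
hyperparameter grid is exercisable. (A learned PReLU slope is not
supported — the NumPy layer keeps activations stateless; the fixed slope
is this package's own simplification.)

Message dropout (inverted scaling) is applied to messages after each
activation during training only; placement inside the recursion is this
package's choice since only the rate appears in the standard grid.

Weights use uniform(−1/√fan_in, +1/√fan_in) initialization. Each
parameter draws from its own named, seed-keyed stream, so changing one
layer's width (e.g. widening the head from one to two outputs) never
shifts another parameter's draws — this is what makes a two-target model
with one target fully masked reproduce the single-target run bit-for-bit
at the start of training, a property the tests assert.

Everything runs in float32 by default; float64 is available and is used
for the oracle and gradient-check tests (the explicit-loop reference
implementation agrees with the vectorized encoder to ≤1e−10, and
hand-written gradients match central finite differences to ~1e−7 with
smooth activations).

## Attention readout

`W_att = softmax(G Gᵀ)` is deliberately **unscaled** — no 1/√H factor and
no learned query/key/value projections; the readout attends G to itself
directly. Pooling is the arithmetic mean (not sum) of G + E_G over atoms.
In batches the attention matrix is block-diagonal by construction: each
molecule's block is computed from its own scope, so atoms never attend
across molecules (tested).

The atom *weight score* aggregates W_att by **column mean** (attention
received) by default; whether rows or columns should be aggregated is
genuinely ambiguous, so a `score='row'` switch exists and rendered outputs
record the convention in their legend/sidecar. Coefficients are the
scores minus their mean, hence always sum to zero.

## Training

- Loss: MSE on z-score-normalized targets over *observed* entries only
  (masked multi-target loss); metrics (MAE, MSE, RMSE, R², Pearson) are
  always computed on the original scale. R² is taken against the mean of
  the true values; zero-variance inputs make Pearson undefined and are
  reported as NaN with a warning.
- Normalization: per-property mean/std from the training partition's
  observed values (std 0 falls back to 1).
- Optimizer: Adam (β 0.9/0.999, ε 1e−8), batch size 50, 30 epochs by
  default.
- Schedule: linear warm-up over 2 epochs from 1e−4 to the peak rate, then
  exponential decay to the final rate at the last step. The defaults peak
  at 3e−3 and end at 1e−3: the package targets desk-scale experiments of
  a few hundred optimizer steps, and a lower/faster-decaying schedule
  measurably underfits at that scale (held-out R² ~0.72 vs ~0.93 on the
  standard synthetic recovery task). All five numbers are configurable.
- Model selection: the checkpoint with the best validation RMSE is
  retained, matching the criterion used for the grid search.
- Determinism: NumPy-only computation plus named seed streams make runs
  exactly reproducible; two runs with one seed agree to the last bit.

## Evaluation protocol

Stratified k-fold cross-validation for a continuous target: records are
binned into 10 quantile bins (of the mean observed target, so partially
labelled multi-target tables stratify too), each bin is shuffled and
split into k chunks, and fold f tests on chunk f, validates on chunk f+1
and trains on the rest — 80/10/10 for k=10, every record tested exactly
once, bin remainders rotated across folds to keep sizes balanced.
Repeats re-split with their own seeds. Train/test structure leakage is
impossible by construction after cleaning (one record per canonical
structure) and is still checked explicitly.

The grid space is the standard lattice: activation × depth 2–6 × hidden
32–512 (step 32) × dropout 0–0.4 (step 0.05) × head layers 1–3. Search
draws uniformly without replacement up to the budget (exhaustive
enumeration is available); trials are ranked by validation RMSE.

The classical baseline is a 500-tree random forest on 1024-bit hashed
circular-substructure fingerprints (radius 2, the conventional
ECFP4-equivalent; only the length is standard, the radius is this
package's choice), trained on train+validation and scored on test with
the same metrics.

## Synthetic fixtures

The generator assembles molecules from a fragment grammar — an optional
heteroatom/halide prefix, an alkyl chain of 1–6 carbons with an optional
methyl branch and 0–3 continuation carbons, an optional ring (benzene,
pyridine, cyclohexane, furan, thiophene) on either side, and a terminal
group (hydroxyl, amine, halides, carbonyls, nitrile, ethers) — all
concatenations are valid SMILES, molecules stay under ~25 heavy atoms,
and duplicates are allowed so the cleaning stage is exercised. 600 draws
yield ~560 unique structures.

Properties: `atom_count_linear` (default; y = Σ c_e·n_e + ε with
coefficients C 0.5, O 0.8, N −0.4, F −0.6, Cl 0.9, S 0.2 and
ε ~ N(0, 0.1²) by default), `heavy_atom_count`, and `ring_fraction`
(used as the second, partially missing property of the two-target
dataset). Structure and noise come from independently seeded streams.

What this does and does not show: the linear-composition property is
exactly recoverable (a linear regression on element counts reaches
R² ≈ 0.997 under the default noise, bounding what any model can do), so
passing the recovery experiment demonstrates that the pipeline learns
composition from raw graphs end to end — it says nothing about
real-world lipophilicity/solubility accuracy, which depends on
experimental data the package reads from the same CSV schema but does
not ship. Property ranges, scaffold diversity and label noise of real
assay data are not emulated.

## Numerical and degenerate cases

- Softmax rows are max-shifted before exponentiation.
- A single-atom molecule has no edges: its hidden vector comes from the
  self-feature path alone, attention is the 1×1 identity and the latent
  is twice the atom vector.
- Empty neighbour sums leave messages at their initial value, so
  messages out of degree-1 atoms are constant in depth (exact, tested).
- An all-masked batch contributes zero loss and zero gradients.
- RMSE² = MSE and MAE ≤ RMSE hold as identities on every report.

## Known limitations

- No learned attention projections or multi-head attention (by design).
- No uncertainty estimation, classification heads or ensembling.
- PReLU's slope is fixed, not learned.
- CPU-only NumPy: fine for thousands of molecules, not for millions.
- Checkpoints are NumPy archives, not portable to other frameworks.
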