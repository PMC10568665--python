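# Methods

## Problem and model

`molcarc` classifies small molecules as carcinogens (label 1) or
non-carcinogens (label 0). A molecule enters the model through two parallel
representations:

1. **Fingerprints.** One of twelve registered families: three hashed-path
   families of 1024 bits (plain, extended with ring/charge atom annotation,
   and graph-style ignoring bond orders; all enumerate simple atom–bond
   paths of up to seven bonds and hash the canonical path string to a bit
   position with a fixed-salt CRC32), keyed substructure families (MACCS
   166, PubChem-length 881, Klekota-Roth-length 4860, substructure/FP4-length
   307, E-state 79, plus count variants), and a 780-long 2D atom-pair family
   (12 element types × 78 unordered pairs × topological distances 1–10).
2. **Molecular graph.** Heavy atoms as nodes with 74-d canonical features
   (element, degree, implicit valence, formal charge, radicals,
   hybridization, aromaticity, hydrogen count), bonds as bidirected edges
   with 12-d features. Bond features are computed and exposed but the
   encoder consumes node features only.

Fingerprints are filtered on training data only: columns with population
variance `D(X) = E(X²) − E²(X) < 0.05` are dropped, then a greedy
left-to-right pass drops any column whose |Pearson correlation| with an
already-kept earlier column exceeds 0.7. The surviving vector is
concatenated with a 50-d graph embedding from a two-layer, four-head graph
attention network (per node `z_i = W h_i`,
`e_ij = LeakyReLU(aᵀ[z_i‖z_j])` with slope 0.2, `α_ij = softmax_{j∈N(i)} e_ij`,
`h'_i = σ(Σ_j α_ij z_j)`; heads concatenated with ELU at layer 1, averaged
with identity at layer 2; elementwise max over a molecule's nodes as
readout). Self-loops are added transiently so isolated atoms receive a
message.

The fused vector passes through two fully connected blocks
(Linear → BatchNorm → ReLU → Dropout, 128 units), is reshaped row-major into
16 input capsules of dimension 8 and squashed with
`squash(s) = (1 − e^{−‖s‖}) s/‖s‖`. A capsule layer computes votes
`û[i,j] = u_iᵀ W[i,j]` and routes them in a single non-iterative pass: per
output capsule j the vote-similarity matrix `A_j = U_j U_jᵀ / D` (D = 128)
is row-summed and softmax-normalised **across output capsules** to give
coupling coefficients C; the output pre-activation is the `(C + B)`-weighted
vote sum with a learnable log-prior matrix B initialised at zero, squashed
into two output capsules of dimension 2. Capsule 0 is the carcinogen class;
its length is the ranking score, the larger length the predicted label, and
a tie resolves to non-carcinogen.

Training minimises the margin loss
`L_k = T_k max(0, 0.9 − ‖v_k‖)² + 0.5 (1 − T_k) max(0, ‖v_k‖ − 0.1)²`,
batch-averaged, with Adam (learning rate 1e-3, L2 weight decay 1e-3,
batch size 256, 100 epochs by default, dropout 0.2). The whole network,
graph encoder included, is trained end-to-end under the single margin loss.

Variants: `full` (both branches, self-attention routing), `NA` (both
branches, classic 3-iteration dynamic routing), `OF` (fingerprints only),
`OG` (graph only).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| variance threshold | 0.05 | minimum column variance kept (binary column ⇒ minority frequency ≳ 5%) |
| correlation threshold | 0.7 | maximum \|ρ\| to an already-kept column |
| GAT hidden width / heads | 50 / 4 | embedding capacity per head |
| feat/attn dropout | 0.2 / 0.2 | graph-encoder regularisation (training mode only) |
| capsules in/out | 16×8 → 2×2 | reshape of the 128-d FC output; two class capsules |
| attention stabiliser D | 128 | divisor of the vote-similarity matrix; a √D option exists because the self-attention literature scales by √d |
| m⁺ / m⁻ / λ | 0.9 / 0.1 / 0.5 | margin-loss targets and absent-class down-weight |
| batch / lr / weight decay / epochs | 256 / 1e-3 / 1e-3 / 100 | optimiser settings |

## Numerical and design choices

* **NumPy + in-package autodiff.** The network runs on a minimal
  reverse-mode tensor autodiff engine (`molcarc.autodiff`) with segment
  reductions for batched graphs. Gradients are verified against finite
  differences (tolerance 1e-4) and all neural operations against explicit
  scalar-loop references (1e-6) in the test suite.
* **Correlation filter uses |ρ|** so a complement bit is as redundant as a
  copy; the greedy order is original column order, earlier column kept —
  a deterministic convention. Variance is the population variance (ddof 0).
* **Selection is refit inside every CV training fold** by default to avoid
  leakage into validation folds; a fit-once global mode exists.
* **Squash at zero** maps the zero vector to itself (the continuous limit);
  a 1e-12 floor inside the norm keeps the gradient finite.
* **Count-valued fingerprint columns** are z-scored with training-fold
  statistics before entering the network; binary columns pass through.
* **Routing combination is additive** (`C + B` weighting of votes); the
  dynamic-routing ablation path updates agreement logits without gradient
  flow through the logit accumulation, as in the classic formulation.
* **Eq-level interpretation choices** (softmax of coupling over the
  output-capsule axis; division by D rather than √D; concat-then-average
  head combination; ELU/identity layer activations) are documented in the
  module docstrings as the implemented reading, with flags where an
  alternative is standard practice.
* **Ties in the max-pool readout** route the gradient to the first maximal
  node per feature; BatchNorm batches need ≥ 2 rows (singleton tail batches
  are skipped during training).
* Keyed families whose published key-definition files are not bundled
  (Klekota-Roth-, PubChem- and FP4-length sets) use deterministic synthetic
  key sets of the exact published lengths built from a curated
  functional-group list plus an element-chain SMARTS grammar
  (`molcarc.keysets`); position semantics (match indicator / count per key)
  and all length contracts are preserved, only key identity differs. MACCS
  and E-state use RDKit's real key definitions.

## Synthetic data

The generator (`molcarc.synthetic`) assembles molecules from small organic
scaffolds with neutral decorations and attaches four classic toxicophores
(nitro, nitrosamine, aromatic amine, epoxide) independently with
probability 0.35. The alert-presence pattern is drawn *first* and assembly
retries (for validity or uniqueness) never change it, so presence is exactly
Bernoulli per alert. Labels follow a logistic model on presence; the base
log-odds is calibrated by bisection so the expected carcinogen fraction is
726/1564 ≈ 0.464, emulating a near-balanced curated training set.
`bayes_auc` Monte-Carlo-estimates the AUC of the true log-odds scorer — the
ceiling any classifier can reach on that spec.

The default per-alert log-odds of 3.0 gives a moderately strong, realistic
signal; the learning benchmark used in tests and in `scripts/acceptance.py`
raises it to 6.0, where the generative ceiling is ≈ 0.97, so that learning
failures are attributable to the model rather than to label noise. Scaffolds
stay ≤ 30 heavy atoms, keeping path enumeration and graphs small.

What passing tests show: the pipeline can recover a planted
substructure→label signal from both representations, the fusion does not
underperform its branches, and a label-permuted control stays at chance.
What they do not show: performance on real rodent-bioassay chemistry, whose
diversity, assay noise and alert spectrum the generator does not attempt to
match.

## Problem sizes

The test suite trains on 800 molecules (200 held out) for 30 epochs per
variant, and checks the CV protocol at n = 1564 with single-epoch fits.
`scripts/acceptance.py` uses 1000 training + 100 external molecules, 30
epochs, fivefold CV — sizes chosen so a complete run stays desk-scale on one
CPU while keeping every class of the pipeline's behaviour measurable.

## Known limitations

* Hashed-path and synthetic keyed fingerprints are not bit-compatible with
  PaDEL's; only family semantics and lengths match.
* The dynamic-routing ablation is a test-time reference path, not tuned.
* No hyperparameter search is performed; defaults follow the published
  optimum values table.
* SDF reading is minimal (requires a `label` property); no 3-D conformers
  or stereochemistry-aware geometry.
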