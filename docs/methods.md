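# Methods

## Signal model

Two residues are conventionally in contact when their Cβ atoms lie within
8 Å.  On a predicted contact map, backbone hydrogen bonding between two β
strands produces a contiguous run of contacts: residue *a+m* of one strand
pairs with *b+m* (parallel, a diagonal line at constant offset) or with
*b+k−1−m* (antiparallel, an anti-diagonal line).  The package estimates,
for every residue pair with sequence separation ≥ 3, the probability that
the pair is such a bridge-partner pair.  Separation 3 is the tightest
possible cross-strand contact (a minimal β hairpin); closer pairs are
excluded everywhere — from the feature mask, the loss, and the output,
whose near-diagonal band is identically zero.

## Ridge features

Ridge detection follows the γ-normalized scale-space scheme: the map is
smoothed by a separable Gaussian of variance *t* (kernel truncated at
4√t, reflective boundary), the Hessian is taken by finite differences
(central second differences in the interior, the shifted stencil at
borders — exact on quadratics and free of fabricated edge curvature; the
mixed term uses nested first differences), and a pixel's bright-ridge
strength at scale *t* is

&nbsp;&nbsp;&nbsp;&nbsp;S(t) = t^γ · max(0, −λ₁),

where λ₁ ≤ λ₂ are the Hessian eigenvalues.  Only bright crests count
(contacts are high values); valleys score zero.  The height channel is
max over scales, and the orientation θ ∈ [0, π) of the λ₁ eigenvector
(the across-ridge direction) is taken at the winning scale.

Defaults: scales t ∈ {1, 2, 4} pixel², γ = 3/4.  β-strand ridges are one
to two pixels wide, so small scales suffice; γ = 3/4 is the standard
ridge-normalization exponent that makes strengths comparable across
scales.  Orientation is encoded as (cos 2θ, sin 2θ) — doubling the angle
identifies θ with θ+π, removing the wrap-around discontinuity — and both
direction channels are weighted by the height normalized to the map
maximum, so flat regions carry no spurious direction.  Ridge features are
computed from each of the two input maps independently (6 ridge channels
total): the two upstream predictors have different error modes and
neither is privileged.

Useful exact properties (all tested): heights are invariant to adding a
constant to the map, scale linearly with the map, and transpose with it
(with θ ↦ π/2 − θ).

## Feature tensor

56 channels of shape L×L:

| group | channels | range |
|---|---|---|
| contact maps | 2 | [0, 1] |
| ridge height (per map) | 2 | [0, 1] (normalized to map max) |
| ridge direction (per map) | 4 | [−1, 1] |
| ss3 (helix/strand/coil) row+col | 6 | [0, 1] |
| one-hot residue identity row+col | 40 | {0, 1} |
| ln(1+N)/10, L/500 planes | 2 | O(1) |

Per-residue features enter twice — broadcast along rows (value of residue
*i* at every (i, ·)) and along columns — so cell (i, j) sees both
residues' profiles.  The coupling-score map (unbounded above) is divided
by its per-protein maximum when that maximum exceeds 1, then both map
channels are clipped to [0, 1]; probability-style maps pass through.  The
0D scalars are log-compressed / rescaled to keep the constant planes
order one.  Non-canonical residue letters one-hot to all-zero rows:
prediction must not crash on them even though such proteins are typically
excluded from training sets.  Feature-removal experiments are supported
by assembling with a subset of the channel groups.

## Network

Input 56 → C channels by 1×1 convolution; then B residual blocks

&nbsp;&nbsp;&nbsp;&nbsp;y = x + Conv₃ₓ₃(LReLU(IN(Conv₃ₓ₃(LReLU(NORM1(x))))))

with NORM1 = (RN(x) + CN(x))/2 (or IN when row/column normalization is
disabled); then 1×1 convolution to one channel, logistic squashing,
symmetrization (P+Pᵀ)/2 and masking.  The reference configuration is
B = 15, C = 45 with RN/CN on; desk-scale experiments use B = 4, C = 16.

RN standardizes each row of each channel to zero mean and unit standard
deviation over the masked-in entries of that row (ε = 10⁻⁵ in the
denominator; rows with fewer than two valid entries pass through), CN
does the same per column, IN per whole channel; each carries a learnable
per-channel gain and bias initialized to (1, 0).  Averaging RN and CN in
the first repeat treats rows and columns symmetrically while preserving
the channel count; a channel-split alternative would halve the width each
operation sees.  Masked-out positions are shifted and scaled by their
slice's statistics but never contribute to them.  Leaky-ReLU slope is
0.01.

Everything — convolutions as im2col matrix products, the masked
normalization statistics, and their exact gradients — is implemented
directly in NumPy with float32 parameters and verified against central
finite differences.  Pure NumPy makes runs bit-reproducible for a given
seed with no kernel nondeterminism to request or suppress.

## Training

Masked binary cross-entropy over pairs with |i−j| ≥ 3, optimized by Adam
(default learning rate 10⁻⁴ for the reference configuration; the
desk-scale experiments use 10⁻³, appropriate to the much smaller model
and dataset).  Proteins are split into k folds (default 5, minimum 2) by
a seeded permutation; each fold's model trains on the remaining folds one
protein at a time (maps vary in size, so no padding is needed in
training; `pad_batch` exists for batched inference).  After each epoch
the fold's validation proteins are pooled and scanned for the F1-optimal
cutoff; early stopping keeps the parameters with the best pooled
validation F1, with a configurable patience.  Folds whose training or
validation part contains no positive pair are skipped with a warning.
The deployed predictor is the arithmetic mean of the fold models, and the
operating cutoff is selected on the pooled out-of-fold predictions —
ensembling the folds needs no extra training protocol, and cutoff
selection on out-of-fold data avoids optimism.  Class reweighting
(`positive_weight`) is available but defaults to 1; the class imbalance
is handled by the cutoff instead.  One master seed drives fold splitting,
weight initialization and batch order, and is echoed in the checkpoint
manifest.

## Evaluation

Residue-level precision, recall, F1 over unordered valid pairs, with the
0/0 → 0 convention (an empty prediction scores zero, not undefined).
Pooled (micro-averaged) counts are the headline aggregate, matching the
convention of β–β pairing benchmarks; per-protein rows and the fraction
of proteins one prediction set strictly beats another on are also
reported.  PR curves place one point per distinct score, and AUPRC uses
step integration Σ(Rₖ−Rₖ₋₁)Pₖ, which never interpolates optimistically.
Cutoff selection scans all distinct pooled scores and returns the
midpoint of the optimal open interval (ties toward the higher cutoff).

## Synthetic benchmark

The generator plants a strand topology (strand lengths 3–10, ≥ 2 loop
residues between strands, pairings forming a chain so each strand has at
most two partners, register offsets keeping ≥ 3 aligned residues), derives
the exact bridge-partner labels from the pairing geometry, and corrupts
the ideal map — ones at label pairs and on the sequence-neighbor band
|i−j| ≤ 2 — with four noise processes: random deletion of true pairs
(miss rate), Gaussian blur, uniform(0.3, 1) false positives at a given
density, and clipping to [0, 1].  Two independent corruption draws per
protein emulate the two upstream predictors; real predictors have
correlated errors, so this is the simplest model that makes the two-map
input non-redundant rather than a faithful error model.
Secondary-structure profiles put (0.05, 0.9, 0.05) on strand residues and
(0.1, 0.05, 0.85) elsewhere, flip the assignment with the configured
error rate, and jitter rows with a Dirichlet of concentration 50; homolog
counts are log-uniform in [10, 10⁴].

Default regime: L ∈ [50, 120], 2–6 strands, false-positive density 0.01,
miss rate 0.1, blur σ 0.5, secondary-structure error 0.1.  In the
noiseless limit the simulation is exactly invertible — thresholding the
map at 0.5 off the neighbor band recovers the labels with F1 = 1 — which
anchors the generator's correctness.

**What passing does and does not show.**  The synthetic task shares the
real task's geometry (diagonal/anti-diagonal ridges, band, class
imbalance, two noisy views) but not its hardness: real coupling matrices
have structured, correlated noise, strand signals of varying intensity,
and secondary-structure errors that cluster at strand ends.  Held-out
synthetic F1 ≈ 0.96 therefore demonstrates that the pipeline — features,
network, gradients, cutoff selection — learns and generalizes the planted
geometry, not that it would reach any particular accuracy on real
proteins, which requires the real upstream predictors and benchmark sets.
The desk-scale experiments (150 training proteins, 4 blocks, 16 channels,
2 folds, 6 epochs) were sized so a full train/evaluate cycle over three
seeds runs in minutes on one CPU; the relative comparisons (trained model
vs. raw-map threshold, row/column normalization on vs. off) are the
meaningful outputs at this scale.

## Constraints

Predicted β pairs at or above the cutoff, ranked by probability and
truncated to the top L, get Cβ distance bounds 3.5–6 Å; the set is then
enriched with the highest-valued non-redundant pairs of a general contact
map at 3.5–10 Å until min(L, available) constraints, written as 1-based
"i j dmin dmax confidence" lines.  When β pairs alone exceed L they are
truncated before enrichment.  General pairs are ranked by raw map value —
only the ordering matters for the fill — and the confidence column
carries the source score clipped to [0, 1].

## Numerical and design notes

- Input contact matrices are symmetrized as (M+Mᵀ)/2 on read; upstream
  maps are symmetric by construction, so the averaging is defensive.
- Internal indices are 0-based everywhere; RR and DSSP formats convert at
  the I/O boundary.  DSSP parsing uses the classic fixed columns
  (structure letter at 16, BP1/BP2 at 25:33) because the table is
  column-aligned and token splitting breaks on crowded fields.
- The homolog count N is accepted as a given scalar; whether it is a raw
  or effective (weighted) MSA depth is up to the caller's upstream
  pipeline.
- Cutoff-selection returns the exact boundary score when adjacent
  distinct scores are one float apart (the open interval is empty).
- The flip-equivariance of the forward map under residue-order reversal
  holds exactly only for centro-symmetric 3×3 kernels (a 180° rotation
  commutes with correlation only then); the property test constructs such
  kernels.  Generic trained kernels are not constrained this way.
- Known limitations: no β-bulge irregularities, multi-chain sheets or
  barrel-closure constraints in the simulator; no strand-level scoring
  (residue-level pairing is the target); folding itself (constraint
  consumption, model building, TM-score selection) is out of scope.
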