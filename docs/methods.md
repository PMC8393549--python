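# Methods

This note records the scientific conventions, numerical choices and
deliberate simplifications behind `segweight`, in the order the
pipeline uses them.

## Losses

All objectives operate on flattened fields `g, p ∈ R^{N×C}` — `g`
one-hot ground truth, `p` a per-voxel probability simplex produced by a
channelwise softmax — with the background included as class 0 and
weighted like any other class.

* **Cross-entropy** `L_CE = -(1/N) Σ_c Σ_i w_ic g_ic log p_ic`, where
  `w` is 1 (none), a per-class constant (inverse/median), or a per-voxel
  field (focal/dtm/dpt).  Probabilities are clipped to
  `[1e-7, 1 - 1e-7]` before the logarithm; the clip has zero derivative
  outside the interval.
* **Dice** is the all-classes-pooled ratio as a single fraction, not a
  mean of per-class Dice scores.  Inverse/median/focal weights multiply
  both numerator and denominator (generalised-Dice form); dtm/dpt
  weights multiply only the false-positive `Σ W (1-g) p` and
  false-negative `Σ W g (1-p)` denominator terms, with the overlap
  numerator unweighted.
* **Smoothing.** A constant `ε = 1e-7` is added to *both* numerator and
  denominator of every Dice ratio.  Denominator-only smoothing would
  make the focal-weighted Dice evaluate to 1 at a perfect one-hot
  prediction (its weighted numerator and denominator both vanish there,
  since `(1-p)^γ = 0` on every correct voxel); symmetric smoothing keeps
  all twelve objectives ≤ 1e-6 at `p = g` while leaving the unit-weight
  reduction to the base losses exact.
* **Parameter defaults.** Inverse power `α = 1` (CE) / `2` (Dice, the
  generalized Dice choice); focusing parameter `γ = 2` (CE) / `1`
  (Dice).  The original focal loss's additional class-balancing factor
  is deliberately not implemented.
* **Class frequencies** for inverse/median weights are accumulated over
  the *full training subset*, never per batch: per-batch counts would be
  undefined for batches missing a class, and the weight is meant to
  describe the dataset's imbalance.  Absent classes get an
  epsilon-guarded count with a logged warning.
* **Focal weights are detached**: `(1-p)^γ` is recomputed every forward
  pass but treated as a constant modulation in the gradient.  The
  gradient check therefore compares the analytic gradient with finite
  differences of the loss evaluated at a frozen weight field — that is
  the objective actually optimised per step.  Differentiating through
  the weight is a defensible alternative reading; the detached form is
  the common one for a "weighting" and is what the trainer uses.

Gradients are taken with respect to logits, chaining through the
softmax, and are verified against central differences (step 1e-4) for
every registry entry.

## Distance maps

The boundary `∂G` of a mask is the set of foreground voxels with at
least one background *face* neighbour (4-connectivity in 2D,
6-connectivity in 3D); voxels outside the lattice are not background, so
a mask filling the lattice has no boundary.  The DTM is the Euclidean
distance to `∂G` (zero on the boundary, positive inside *and* outside),
computed with an exact Euclidean distance transform of the boundary
complement.

The DPT is a bounded inversion of the DTM.  A literal reciprocal
`1/DTM` is singular on the boundary, so the package uses the
max-normalised form `DPT = (max DTM - DTM) / max DTM ∈ [0, 1]`: 1 on
the boundary, 0 at the farthest voxel, strictly reversing the DTM
ordering, and keeping the weight `1 + DPT` bounded in `[1, 2]` (stable
gradients).  If every voxel is boundary, DPT is 1 everywhere.

Loss-side weight maps are computed per 2D training slice in voxel units
(the network is 2D and the weights are dimensionless modulations);
metric-side distances use physical spacing.  Classes that are absent
from a slice (or cover it entirely) get all-ones weight maps so that
training loops never fail on the routine empty-class slice; the
standalone `compute_dtm`/`compute_dpt` operations raise on such
degenerate masks instead.  Weight maps derive from ground truth only,
are cached before training, and carry no gradient.

## Metrics

Surfaces are voxel sets under the same boundary convention, so surface
cardinalities are voxel counts, not mesh areas.  Directed distances are
read off an exact Euclidean distance transform of the opposite surface,
with anisotropic spacing passed through; DSC is count-based and
spacing-free.

* **Surface DSC**: fraction of the pooled surfaces within tolerance τ of
  the other surface; τ defaults to 1 mm.
* **ASD** is the symmetric form
  `(Σ_{x∈∂G} D(x,∂P) + Σ_{y∈∂P} D(y,∂G)) / (|∂G| + |∂P|)`.
* **95HD** is the 95th percentile of the *pooled* two-direction distance
  sample, with linear interpolation between order statistics; it never
  exceeds the exact Hausdorff distance.  (Taking the max of
  per-direction percentiles is a defensible alternative; pooling is
  pinned here for reproducibility.)
* **Empty structures**: DSC is 1 if both masks are empty and 0 if
  exactly one is; all surface metrics are `nan` (flagged missing)
  whenever either surface is empty.  Per-case evaluation reports one
  record per foreground class, background excluded.

## Ranking

For each (metric, class) cell, all loss pairs are compared by a
two-sided Wilcoxon signed-rank test on the paired per-case differences.
Zeros are dropped before ranking (Wilcoxon's original treatment); the
exact null distribution is used for n ≤ 25 without tied magnitudes,
otherwise the normal approximation with continuity correction.  "Worse"
is decided by the orientation-adjusted median difference (higher-better
for DSC/SDSC, lower-better for ASD/95HD), falling back to the mean
difference on a zero median, with no winner if both vanish.  The
significance score counts competitors beaten at p < 0.05 with no
multiplicity adjustment (deliberately, matching the exploratory framing
of such comparisons); the rank score is its mean over metrics and
classes, and the aggregate over several datasets is the mean over all
(dataset, metric, class) cells, so datasets with more classes weigh
proportionally more.

Missing metric values (collapsed predictions) are handled by pairwise
deletion; comparisons with fewer than 6 complete pairs are treated as
missing and can never increase a score.

## Synthetic phantoms

The generator emulates the *structure* of a multi-sequence brain-MR
segmentation study — one large rippled object (cerebrum-like), a medium
and a small blob below it (cerebellum/brainstem-like), thin random tubes
with varying location and shape (vessel-like), a bright rim around the
blob union in the MRC-like channel (cerebrospinal-fluid contrast) and
tube-only brightness in the MRA-like channel — at controlled voxel
ratios: presets at 9:1, 86:1, 352:1, 749:1 background:foreground and
3/4/5-class mixtures (677:72:1, 668:72:9:1, 666:72:9:2:1).  Class voxel
budgets are realised almost exactly by thresholding each class's smooth
shape field at the matching quantile on still-unassigned voxels,
smallest classes first.  Intensities are per-class means plus additive
Gaussian noise (σ = 0.1 on an intensity scale of ~0.15–0.95), then each
channel is normalised to zero mean and unit variance.

The default lattice is 96×96×24 at unit spacing — a desk-scale stand-in
for 512×512×(144–190) volumes at 0.47×0.47×1.0 mm; the full-scale
geometry works but is not the default.  The phantoms deliberately lack
anatomy, partial-volume effects, bias fields, scanner noise structure
and inter-rater label noise, so a passing benchmark shows that the
*pipeline and the relative behaviour of the losses under imbalance* are
sound, not that any absolute accuracy transfers to clinical MR data.

## Network and training protocol

The segmentation model is a 2D U-Net — symmetric encoder-decoder with
skip connections, two (3×3 conv → batch norm → ReLU) blocks per level,
2×2 max pooling, nearest-neighbour upsampling, 1×1 convolution head —
implemented directly in NumPy with hand-derived backpropagation (itself
verified by finite differences), which keeps the whole stack
dependency-light and bit-reproducible on CPU.  The desk-scale default is
base width 8 and depth 2; width/depth are configurable where a
study-scale variant is wanted.

Training is slice-wise over all axial slices, *including* slices without
foreground — discarding them would silently reduce the imbalance the
package exists to study.  The optimiser is Adam with β₁ = 0.9,
β₂ = 0.999, ε = 1e-7 and batch size 5; the study-scale protocol sweeps
learning rates {1e-3, 1e-4, 1e-5} with checkpoints at {10, 20, 30}
epochs, and `TrainConfig.desk_scale()` shrinks this to {1e-3, 1e-4} ×
{3, 6} for CPU experiments.  Model selection takes the checkpoint with
the highest mean foreground DSC on the validation cases — the selection
criterion had to be pinned to something, and mean foreground DSC is the
natural choice for imbalance studies — with ties broken to the lowest
learning rate, then the fewest epochs.  Prediction is per-slice argmax
restacked to a 3D label volume.  No data augmentation is implemented.

## Verification battery and problem sizes

The test suite and `scripts/acceptance.py` verify each stage against
independent oracles: exhaustive min-over-boundary distance computations
(50 random 32×32 masks), brute-force pairwise surface distances (20
random volumes up to 16³ at 0.47×0.47×1.0 mm spacing), full enumeration
of signed-rank null distributions (n ≤ 12), and closed-form loss values.
The directional training benchmark uses the vessels preset at 48×48×12,
10/2/5 train/val/test cases, the desk-scale grid, and 5 seeded
replicates — sized so a full run stays in the minutes range on one CPU —
and checks two qualitative effects of frequency weighting at extreme
imbalance: inverse-weighted Dice raises the minority-class test DSC over
unweighted Dice, and inverse-weighted CE increases false-positive
(over-extracted) voxels relative to unweighted CE.  The 12-loss smoke
benchmark (3-class preset, 48×48×12, one learning rate, 2 epochs) checks
completeness of the metric table and rank report, not accuracy.

## Known limitations

* The phantoms are geometric, not anatomical; absolute metric values on
  them say nothing about clinical MR performance.
* The NumPy network is CPU-bound and desk-scale; the harness is built
  for studying losses, not for production training.
* The DPT normalisation, boundary connectivity, 2D-per-slice distance
  maps, pooled-percentile 95HD, detached focal weights and the
  validation-selection criterion are pinned conventions among several
  defensible readings; each is stated above and implemented exactly
  once.
* Epoch-dependent scheduling of distance-map weights, compound losses,
  signed/geodesic distance transforms and 3D or patch-based networks are
  out of scope.
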