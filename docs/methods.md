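# Methods

`s3seg` implements a two-stage approach to segmenting tumors in
co-registered multi-sequence brain-image slices when expert masks are
scarce: a graph-regularized semi-supervised support vector machine (S3VM)
propagates patch labels from a small labeled subset to the rest of the
training data, and a small convolutional patch classifier trained on the
completed labels produces pixel-level segmentations by sliding window.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic benchmark does and does not demonstrate.

## The semi-supervised SVM

Given features `x_i ∈ R^d` with labels `y_i ∈ {+1, −1}` on a subset and
unknown elsewhere, the joint objective couples four blocks of variables —
hyperplane `(w, b)`, row-stochastic similarity matrix `s`, spectral
embedding `F` with `FᵀF = I`, and the unlabeled labels `y_u`:

```
min  ½ wᵀw + λ1 Σ_i u_ii max(0, 1 − y_i (wᵀx_i + b))
     + λ2 (Xw)ᵀ L_s (Xw) + λ3 ‖s‖² + λ4 tr(Fᵀ L_s F)
```

where `L_s` is the Laplacian of the symmetrized similarity
`(s + sᵀ)/2` and `u_ii` down-weights the hinge loss of unlabeled samples.
The margin term is implemented as a standard hinge (positive part): a raw
linear margin term would be unbounded below and non-convex in intent, so
the soft-margin reading is the only coherent one.

Each block subproblem is solved exactly, which makes the alternating
scheme a true block-coordinate descent:

- **Embedding.** `F` minimizes `tr(Fᵀ L F)` under orthonormality; the
  columns are the eigenvectors of the `c_embed` smallest Laplacian
  eigenvalues (dense symmetric eigensolver). Signs are fixed so the first
  nonvanishing component of each column is positive, making the result
  deterministic.
- **Similarity.** Each row decouples into
  `min Σ_j e_ij s_ij + 2 λ3 s_ij²` over the probability simplex, with
  `e_ij = λ2 (wᵀx_i − wᵀx_j)² + λ4 ‖f_i − f_j‖²`. Completing the square
  reduces this to the Euclidean projection of `−e_i/(4λ3)` onto the
  simplex, computed by the standard sort-and-threshold rule. The diagonal
  is excluded: a sample is not its own neighbor.
- **Hyperplane.** The `(w, b)` subproblem is
  `½ wᵀ(I + 2λ2 XᵀLX) w + λ1 Σ u_ii · hinge_i`. Substituting
  `v = A^{1/2} w` with `A = I + 2λ2 XᵀLX` (symmetric positive definite
  because `L` is PSD) turns it into an ordinary weighted soft-margin
  linear SVM in the transformed features `X A^{−1/2}`, which we solve with
  a deterministic SMO solver at tight tolerance and map back. Solving the
  subproblem exactly (rather than by a few first-order steps) is what
  guarantees the monotone objective trace; a keep-best guard additionally
  rejects any update that fails to improve the objective by solver
  round-off.
- **Relabeling.** For fixed `(w, b)` the hinge is minimized over
  `y_i ∈ {±1}` by `y_i = sign(wᵀx_i + b)`; zero decision values map
  to +1.

**Initialization.** The similarity matrix starts from each row's own `k`
nearest neighbors with squared Euclidean distances `d_ij`:
`s_ij = (d_{i,k+1} − d_ij) / (k d_{i,k+1} − Σ_{j≤k} d_ij)`, which makes
every row a probability vector by construction, and the shared
regularizer is `λ3 = λ4 = mean_i (k/2 · d_{i,k+1} − ½ Σ_{j≤k} d_ij)`,
then frozen. If all `k+1` nearest distances of a row coincide the closed
form is 0/0; the row gets uniform mass `1/k` and a warning. Unlabeled
labels are warm-started from an SVM fit on the labeled samples alone.
Iteration stops when the relative objective change over a full cycle
falls below `tol` (default 1e−6) or after `max_iter` cycles (default 30).

Defaults: `λ1 = 1`, `λ2 = 0.1`, `k = 10`, `c_embed = 2` (binary task),
`γ_unlabeled = 0.1`. The affinity-graph utility (mutual k-NN with RBF
weights, `σ` defaulting to the median pairwise distance) follows the
convention that an edge requires reciprocity; the similarity
initialization deliberately does not, since its closed form is row-wise.

## The patch classifier

The network is an AlexNet-style classifier adapted to small patches:
repeated convolution → ReLU → overlapping max pooling (window 3, stride
2 — the window must exceed the stride) with local response normalization
(LRN) placed **after** the first and second pooling stages, then three
fully connected layers with dropout (keep probability 0.5) on the first
two and a softmax head. Putting pooling before the divisive
normalization, rather than the classical order, is the architectural
variation this package carries; the emitted layer sequence is
introspectable and tested. LRN constants default to
`(k, α, β, m) = (2, 0.78, 1e−4, 7)`; `α` and `β` look transposed relative
to the classical values, so both are config-overridable.

Two presets exist. `tiny` (2 conv layers with 8/16 maps, patch 16, FC
64/32/2, "same" padding) is the desk-scale workhorse used throughout the
tests. `paper` mirrors the classical 5-conv/3-FC shape at patch 64 with
"valid" padding; conv kernel sizes (7, 5, 3, 3, 3) were chosen so all
five stages fit a 64-pixel patch, since no canonical setting exists at
this input size.

Everything is plain numpy with analytic gradients: im2col convolutions,
argmax-routed pooling backward (first occurrence wins ties), an exact
LRN backward, and dropout masks drawn from a dedicated seeded generator.
Gradients were verified against central finite differences to ~1e−9
relative error. Determinism is exact for fixed seed and platform.

## Loss, companding, schedule

Pixel losses operate on softmax probabilities `p_ik`:

- plain cross-entropy `−Σ_k q_ik log p_ik` with the log clamped at 1e−12;
- hard-example mining ("ohem"): mean of `−log p_{i,y_i}` over pixels whose
  true-class probability is below the threshold `η` (default 0.7);
- weighting ("weighted"): `w_ik = 1/ln(c + p_ik)` with `c = 1.10`, applied
  to the one-hot cross-entropy sum;
- the default "combined" mode applies the weighting over the hard
  selection, normalized by the selection count. The selection and the
  weights are treated as constants when differentiating, which is the
  usual convention for loss re-weighting schemes. An empty selection
  contributes zero loss and logs a warning.

Inputs are μ-law companded before entering the network:
`f(x) = sign(x) ln(1 + μ|x|)/ln(1 + μ)` with `μ = 255`, after per-channel
min-max scaling into `[−0.999, 0.999]` (the companding domain is open, so
a margin is required; the scaling statistics are frozen on the training
set and reused at inference). Companding followed by uniform 8-bit
quantization of `[−1, 1]` yields exactly 256 levels on a dense grid.

Training is plain minibatch SGD — no momentum or adaptive variants — with
the polynomial decay `lr(e) = init_lr (1 − e/max_epoch)^power`,
`power = 0.9`. The schedule's classical initial rate 5e−4 remains the
`LrSchedule` default; the phantom pipeline uses `init_lr = 0.02` when
masks are fully supervised and `0.005` in its default configuration,
because plain SGD under the count-normalized hard-example loss takes very
large steps whenever a minibatch contains only one or two hard (tumor)
pixels, and larger rates made training oscillate between recalling and
forgetting the minority class. Each epoch reshuffles with a seeded
generator; runs are bit-reproducible from the seed.

## Segmentation and evaluation

A trained classifier labels an image by sliding a window with a given
stride (default 4); each pixel's class probability is the mean over all
windows covering it, with reflect padding on the bottom/right edges just
large enough that the anchor grid reaches the image border. The label is
the per-pixel argmax, ties to the lower class index. With stride equal to
the patch size this reduces exactly to tiling the per-patch outputs.

Overlap metrics for binary masks `T` (expert) and `P` (prediction):
Jaccard `|T∧P|/|T∨P|`, Dice `2|T∧P|/(|T|+|P|)`, positive predictive value
`|T∧P|/|P|`, sensitivity `|T∧P|/|T|`, reported per image with the raw
counts and macro-averaged across a dataset. Conventions for empty
denominators (not fixed by the definitions): both masks empty scores 1
everywhere — a perfect all-background prediction should not be punished —
and exactly one empty mask scores 0 on the affected ratios; both cases
are logged. RMSE and MAE are provided for regression-style readouts such
as predicted tumor-area fractions.

## Synthetic data

`generate_clusters` draws two isotropic unit-variance Gaussians at
`±(separation/2)·e₁` with a stratified, seeded reveal of a fraction of
labels (at least one per class). `generate_phantom` emulates a
co-registered 4-channel (T1/T2/T1c/FLAIR-like) slice: an elliptical brain
covering roughly 70% of the frame on a dark background; one or more
mildly elliptical tumor blobs with radius 14–20% of the frame placed
fully inside the brain by bounded rejection sampling — the lower bound is
chosen so that even the smallest blob covers a clear majority of some
16-pixel patch, keeping the ground truth representable by the pipeline's
patch-level labeling; per-channel tumor
contrast with sequence-like signs (hypointense on the T1-like channel,
hyperintense on T2/FLAIR-like, strongest on the contrast-enhanced
channel); a multiplicative bias field — the exponential of a random
quadratic polynomial, normalized to mean 1 — emulating scanner intensity
inhomogeneity; and additive Gaussian noise (σ = 0.05 by default). The
ground-truth mask is exact, and every sample is bit-reproducible from its
seed. The 7:3 train/test split is stratified per class with
largest-remainder rounding (ties to the training side), so 20 items split
14/6 and 40 split 28/12.

What the phantoms do *not* model: anatomy beyond a single brain
compartment, partial-volume boundaries, registration error, or realistic
MR physics. Passing the phantom benchmark therefore demonstrates that the
pipeline's machinery — label propagation, training, windowed inference,
metrics — is correct and end-to-end effective on mask-correlated
multi-channel structure, not that the defaults transfer to clinical data.

## The end-to-end pipeline

Stage 1 featurizes training patches (per channel: mean, standard
deviation, and an 8-bin histogram of companded intensities; 40 features
for 4 channels), assigns each patch the majority label of its mask pixels
(ties to tumor), reveals labels only for a configurable fraction of
images (default 50%), fits the S3VM, and pseudo-labels the rest. Pseudo-
labels whose decision-value magnitude falls below 0.1× the median over
unlabeled patches are dropped as uncertain. If every image is labeled the
stage is a pass-through; if the revealed patches are single-class the
SVM has nothing to separate and training falls back to the revealed
patches alone (both cases logged). Stage 2 trains the `tiny` network for
120 epochs at batch size 16 on the completed labels. Stage 3 segments the
held-out 30% and reports overlap metrics. Every run writes its resolved
configuration, a seed registry, and a JSON report, sufficient to
reproduce the run bit-for-bit.

Problem sizes were chosen for desk-scale reproducibility: 40 phantoms of
64×64 pixels give 1372 training patches (49 per image at stride 8), which
the default benchmark completes in about a minute on one CPU core.

## Known limitations

- Patch-majority labels cannot represent tumors much smaller than half a
  patch, which bounds the boundary resolution of the whole pipeline; the
  phantom generator's minimum blob radius respects this, but on real data
  small lesions below that scale would be invisible to the labeling.
- The S3VM is linear and binary; no kernelization or multi-class scheme.
- The alternating optimizer guarantees a non-increasing objective, not a
  global optimum; results depend on the warm start.
- Dropout uses the classical inference-time scaling by the keep
  probability rather than inverted dropout.
- The μ-law/8-bit pathway is exposed and tested but the network consumes
  companded floats directly; quantized inference is not implemented.
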