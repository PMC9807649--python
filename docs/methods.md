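# Methods

## The model

One patient's OCT acquisition is an ordered sequence of B-scans; the
hidden state of scan *t* is its cystic status (state 1 = cystic, state 2 =
non-cystic) and the observation is a length-K feature vector extracted
from the scan.  The chain is ergodic (no structural zeros: a cystic scan
can follow a non-cystic one and vice versa).  The model's central
assumption is first-order persistence: given the status of scan *t−1*,
the status of scan *t* is independent of earlier scans.  Anatomically
this encodes that a cyst spanning several adjacent tissue slices appears
in several consecutive B-scans.

### Supervised estimation

No Baum–Welch iteration is used; labels are available for every training
scan, so λ = (A, B, π) is estimated by counting and averaging,
per patient first:

* πᵢ is the one-hot indicator of the first scan's label;
* Aᵢ rows are empirical transition frequencies between consecutive
  labels (row j: counts of j→1 and j→2 divided by all transitions out of
  j);
* row j of Bᵢ is the element-wise sum of |oₜ| over scans labelled j,
  normalised to sum to one.  Absolute values come first because feature
  components (e.g. deep-embedding activations) may be negative while
  probabilities cannot be.

The final parameters are the plain means over the N training patients.
The mean of row-stochastic matrices is row-stochastic, so the averaged
model always validates.

**Degenerate patients.**  A patient who never visits one state (e.g. no
cystic scan) contributes no information about that state's transition or
emission row; the 0/0 ratio is resolved to a uniform row and the patient
is flagged (`PatientEstimate.fallback_A/B`).  The
`exclude_fallback_rows` option instead drops flagged rows from the
averages.  Both conventions are deterministic; the default (include,
uniform) weights every patient equally, matching the plain-average
estimator.

**Small-sample bias.**  Averaging per-patient frequency ratios is not
the pooled maximum-likelihood estimator.  For strongly persistent chains
and short sequences the per-patient ratios out of the rarely-visited
state are estimated from very few transitions, and their mean is biased;
we measure an asymptotic (N→∞) max-entry bias of ≈ 0.056 at
a₁₁ = a₂₂ = 0.9, T = 31, dropping to ≈ 0.02 at T = 61 and to well under
0.01 for moderately mixing chains (a = 0.7) at T = 31.  The
parameter-recovery studies in the test suite and acceptance script
therefore use the moderately persistent regime, where the estimator's
consistency is informative; the bias in the strong-persistence regime is
an intrinsic property of the per-patient averaging rule, not of this
implementation.

### Emission reduction

The Viterbi recursion needs a scalar bⱼ(o) for a whole observation
vector.  Three reductions are provided:

* **dot** (default): ⟨Bⱼ, |o|/Σ|o|⟩, the expected emission probability
  under the observation's own normalised weight profile.  Bounded in
  (0, 1], smoothing-free, and symmetric with how B is estimated.  Its
  drawback is dynamic range: scores for both states sit near 1/K, so
  per-scan log-likelihood ratios are O(10⁻²) and, under strong
  persistence, transitions dominate decoding.
* **multinomial**: Σₖ |oₖ| log Bⱼₖ, the log-likelihood of |o| read as
  multinomial counts.  Information-consistent weighting (a scan with
  more mass is more informative), used wherever decoding quality
  matters.  Zero entries of B are ε-smoothed (ε = 10⁻³⁰⁰) before the
  logarithm.
* **emission_mass** (multinomial option): each |o| is rescaled to a
  fixed total mass.  Raw detector-aggregate features have masses in the
  thousands, which makes unscaled multinomial scores absurdly confident;
  fixing the mass (the phantom study uses 30) bounds per-scan evidence
  at a few times the transition log-odds.
* **calibrate_emissions** (multinomial option, estimated by `fit()`):
  per-state constants subtracted from the log emission scores so that
  the class-conditional log-likelihood ratio is centred on the training
  scans.  Needed because the cystic emission profile is typically a
  mixture (cyst structure *plus* the background anatomy every scan
  shares), so the sharper non-cystic row can outscore it on every scan
  by a constant; the ranking of scans is unaffected but hard Viterbi
  decisions inherit the offset.  This is the balanced scaled-likelihood
  device familiar from hybrid HMM decoders.  Default off.

### Decoding and posteriors

Viterbi runs in the log domain with −∞ for zero probabilities.  All
argmax ties break toward state 1 (lowest index), making decoding
deterministic even in the fully degenerate equal-δ case.  If the final δ
column is entirely −∞ a `DecodingError` is raised rather than returning
an arbitrary path.  The per-scan cystic posterior comes from scaled
forward–backward recursions under the same emission reduction and is the
continuous score used for ROC curves; how a published ROC for a
Viterbi-decoded model was computed is generally ambiguous, so the
smoothing posterior is this package's explicit choice.

## Feature extraction

* **Gradient field**: standard Sobel kernels, applied by
  cross-correlation; a unit horizontal ramp gives a = 8 exactly.  The
  G_y variant with +2 in the bottom row that sometimes appears in print
  is a typographical error — it is not a derivative operator (nonzero
  response on constant images) — so the standard kernel is used.
  θ = arctan(b/a) ∈ (−π/2, π/2], with θ = ±π/2 when a = 0, b ≠ 0 and 0
  when both vanish; radians by default, degrees by option.
* **HOG**: d×d cells (default 8), 9 unsigned bins over [0°, 180°),
  magnitude-weighted nearest-bin histograms, overlapping 2×2-cell blocks
  with L2 normalisation, concatenated row-major.  Gradients for HOG are
  computed on an edge-replicated frame so an (8m)×(8n) image tiles into
  exactly m×n cells.
* **Harris / Min-Eigen**: structure tensor smoothed by an explicit 5×5
  Gaussian window with σ = 5/3; Harris response det − k·tr² with
  k = 0.04 and detection threshold 0.01 (the classical parameter pair —
  both exposed); Min-Eigen uses the smaller eigenvalue as the response.
  Keypoints are strict 3×3 local maxima; plateau ties go to the
  lexicographically smallest (row, col).
* **FAST**: radius-3 Bresenham circle of 16 pixels enumerated clockwise
  from the top; corner iff ≥ N contiguous circle pixels are all brighter
  than center+t or all darker than center−t.  N defaults to 12 (the
  classical segment-test default; 9-of-16 selectable).  Every passing
  pixel is reported (per-pixel decision, no suppression) with the summed
  threshold excess as score.
* **Determinant of Hessian**: SURF-style box-filter approximations of
  the Gaussian second derivatives (base scale 1.2 ↔ 9×9 filter),
  response Dxx·Dyy − (w·Dxy)² with w = 0.9, the standard box-filter
  correction.
* **Keypoint aggregation**: detector output varies in length, so
  keypoints are pooled on a grid of cells — per cell, count and summed
  response — giving K = 2·rows·cols for any image content.
* **Deep embeddings** are behind a plug-in contract (`DeepEmbedding`):
  the image is colorized through a monotone warm–cold lookup table
  (red non-decreasing, blue non-increasing in intensity) and
  area-average downsampled to 227×227×3, then handed to the registered
  embedding function.  Pretrained weights are deliberately outside the
  package; tests use stub embeddings.

KAZE- and BRISK-style detectors are supported only through the same
plug-in interface, not reimplemented.

## Feature ranking

Features are ranked by held-out accuracy of a per-scan classifier:
a linear-margin SVM (prediction by the sign of wᵀx + b) or a
k-nearest-neighbour vote (k = 5, Euclidean).  The split is always by
patient (default 80/20, seeded) — consecutive scans of one eye are
heavily correlated and scan-level splits would leak.  Batch fitting is
used; for a linear margin the converged decision function does not
depend on whether samples were presented incrementally.  Ties in
accuracy break alphabetically.

## Metrics

Cystic is the positive class everywhere.  Accuracy, sensitivity and
specificity are exact ratios of integer confusion counts; zero
denominators yield NaN plus an explanatory flag rather than a silent 0.
ROC curves sweep the unique score thresholds; the trapezoidal AUC then
equals the pairwise rank statistic with ties counted ½.  DeLong's paired
test uses placement values (structural components) and a two-sided
normal p-value; when the variance of the AUC difference is zero the test
degenerates to z = 0, p = 1.  The implementation reproduces an
independent reference implementation to 8 decimals on a frozen case, and
agrees with a score-swap permutation reference up to the normal
approximation expected at small n.

## Synthetic data

Two generators define the study conditions:

* **Phantoms**: bright horizontal bands (the layered retina) on a dark
  background, dark elliptical cysts confined to band regions,
  multiplicative speckle image·(1 + σ·N(0,1)) clipped to [0, 1].
  Default frame 496×512 (height×width), matching SD-OCT geometry; the
  smaller studies use 96×128.  What is *not* modelled: real layer
  curvature and texture, vendor noise physics, shadowing, motion
  artefacts.  Tests passing on phantoms therefore demonstrate algorithmic
  correctness and the persistence mechanism, not clinical performance.
* **Sequences**: hidden states from a known chain (π, A); observation
  vectors multinomial with a fixed count mass from the active state's
  emission profile, so the "normalise summed |o|" training rule is a
  consistent estimator of the true B and parameter recovery is testable.
  An optional sign-flip fraction exercises the absolute-value step.

Study sizes were chosen so each experiment runs in seconds on one CPU:
recovery cohorts of 200 patients × 31 scans (5 replicates — the initial
distribution is a 200-draw binomial mean with SE 0.035, so replication
is needed before comparing to a 0.05 band), persistence studies of 60+20
patients over 50 seeded replicates, phantom cohorts of 24+8 patients ×
10 scans.

## Known limitations

* The per-patient averaging estimator is biased for strongly persistent
  chains at clinical sequence lengths (see above); pooled counting would
  remove this but is a different estimator.
* The generative emission model scores profile shape only; a
  discriminative per-scan classifier with access to feature magnitudes
  can outperform it when per-scan evidence is strong.  The sequence
  model's advantage appears exactly where the paper-level mechanism
  predicts: weak per-scan evidence plus strong persistence.
* Hard Viterbi decisions require the calibration described above
  whenever the two emission profiles overlap strongly; posterior-based
  ranking does not.
* The equal-δ tie case is resolved deterministically toward the cystic
  state; any fixed convention is defensible, but decoded paths in
  exactly-tied cases are convention-dependent.
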