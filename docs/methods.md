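# Methods

This note documents the models, conventions and numerical choices behind
`icamam`, in the spirit of a model-documentation page: what is computed,
under which assumptions, and where the genuinely open design decisions were
made.

## Synthetic multi-site data

The generator emulates the *statistical structure* of a multi-clinic
film-screening archive, not radiographic realism.

**Backgrounds.** Normal tissue is modeled as Gaussian white noise smoothed
by a Gaussian kernel of sigma `texture_scale` (default 6 px) and scaled
analytically to standard deviation `texture_sd` (default 0.18 OD) around a
per-site mean optical density (1.45–1.60 OD). A 2-D Gaussian kernel has sum
of squares `1/(4πσ²)`, so the amplitude gain `texture_sd·2σ√π` gives the
target variance without empirical renormalization — keeping the field's
mean exactly unbiased and its standard error analytic (used by the tests).

**Masses.** A mass is a star-convex region `r ≤ r(θ)` with the angular
radius profile normalized so `max r(θ) = diameter/2`:

* *round* — constant radius; *oval* — ellipse with axis ratio 0.6 and
  random orientation; *lobulated* — sinusoidal lobes (3–5, amplitude 0.25);
  *irregular* — random smooth perturbation over harmonics 2–6.
* The OD elevation peaks at `contrast` and falls off by margin class:
  *circumscribed* — plateau with a sharp edge inside the mask;
  *ill-defined* — linear ramp reaching 1.5× the radius;
  *spiculated* — sharp core plus 6–12 narrow radial intensity spikes
  reaching 1.9× the radius (the spikes are intensity-only; the mask stays
  star-convex so boundary tracing is well-posed).

Normalizing the radius profile to the nominal diameter keeps the ROI side
distribution of masses aligned with the normal-patch side distribution
(both span the configured diameter range, default 24–56 px), so patch
*size* itself carries no class signal — at `effect = 0` the two classes are
statistically identical and downstream AUC is at chance (verified:
mean AUC 0.503 over 12 independent runs, spread equal to the sampling SE).

**Separability.** The single `effect` knob scales every mass contrast.
Malignant masses draw contrast from `effect·U(0.50, 0.90)` OD and skew
toward irregular/spiculated morphology; benign masses draw from
`effect·U(0.30, 0.60)` and skew toward round/oval circumscribed. Benign
lesions are thus systematically subtler — which is what makes the
benign-free site's training deficit matter downstream.

**Scanners.** Each site has a calibration curve mapping gray level to OD
(`od = a + b·g` linear, `od = a + b·log10 g` logarithmic, `b < 0` as for
film digitizers: brighter pixel, lower density). `digitize` applies the
inverse curve, adds Gaussian gray-level noise, clips to `[0, max_gray]` and
rounds; the logarithmic site quantizes coarsely at high OD, adding a
site-specific distortion. Gray 0 is clamped to 1 under the log response
before taking the log.

**Default roster.** Four sites at ~1/8 the scale of a large public archive,
~630 prototypes total: two mid-size sites, one large balanced site, and a
`dba`-like site (logarithmic response) holding the majority of normal
tissue, few malignant and *zero* benign cases. This roster is the study
condition for every end-to-end test; it is deliberately not a tuning knob.

What the generator does **not** model: breast anatomy, pectoral muscle,
labels/markers, microcalcifications, annotation-style differences between
radiologists. Passing tests therefore demonstrate that the *pipeline and
protocol* behave as documented under controlled domain shift, not that the
classifiers would reach any particular accuracy on clinical data.

## ROI conventions

* Coordinates are 0-based `(row, col)`, row increasing downward; boxes are
  half-open `[r0, r0+side)`.
* Freeman directions 0–7 are E, SE, S, SW, W, NW, N, NE — clockwise on
  screen. The encoder (Moore-neighbor tracing with Jacob's stopping
  criterion, starting at the topmost-leftmost pixel) and decoder share this
  table, so encode∘decode is exact by construction and tested on generated
  masses.
* The centered square has `side = max(bbox height, bbox width)` and origin
  `floor(center − (side−1)/2)` per axis (ties toward smaller indices); it
  is DISCARDed iff it leaves the image. An independent brute-force scan of
  all legal placements backs this in the tests.
* Patches are converted to OD **before** bilinear resizing. Resizing uses
  a corner-aligned sampling grid and is exact on constant and affine
  intensity surfaces (tested to 1e-9).

## ICA basis

Centering subtracts training column means; test patches are centered with
the *training* mean. PCA uses the economy SVD of the centered data
(sample covariance with N−1 denominator), keeps the top `q` eigenvectors
(descending eigenvalues, sign fixed by making each eigenvector's
largest-magnitude entry positive), and whitens by `1/√λ`. Whitening is on
by default because FastICA's fixed point assumes unit-variance input.

FastICA is the symmetric (parallel) fixed-point iteration with
`g = tanh` (log-cosh contrast, slope 1): `w ← E[z·g(wᵀz)] − E[g′(wᵀz)]·w`
for all rows followed by symmetric decorrelation `(WWᵀ)^(−1/2)W`;
convergence when `max_i |1 − |⟨w_i*, w_i⟩|| < 1e-4`, at most 400
iterations. Symmetric rather than deflationary orthogonalization keeps the
result order-independent, matching ICA's inherent component-order
indeterminacy. Non-convergence (e.g. on Gaussian data, where ICA is
unidentifiable) warns and returns the current estimate with a flag.

The stored basis keeps `W_T = K_PCAᵀ·W` with features `s = (x − mean)·W_T`.
One subtlety: with that formula the coefficient vector is `Wᵀz` in the
whitened space, so the fitted basis stores the *transpose* of the FastICA
unmixing matrix — making the extracted coefficients coincide with the ICA
sources. Since `W` is orthogonal this changes nothing about reconstruction
(which equals the rank-q PCA reconstruction either way, a tested identity)
but makes the per-component ordering meaningful.

Component order and sign are arbitrary in ICA; for reproducibility the
basis orders components by descending |excess kurtosis| of their training
coefficients and flips signs so each coefficient skewness is positive.

## Classifiers

**MLP + Rprop.** Architecture `q → H → 1` with logistic activations and
targets mass = 1, normal = 0, so the intermediate decision threshold is
0.5. Training is batch Rprop with weight backtracking on the sum-of-squares
error: per-weight steps grow by 1.2 on gradient-sign agreement (cap 50),
shrink by 0.5 on disagreement (floor 1e-6) with the previous step reverted
and the stored gradient zeroed. These are the classical Rprop constants.
Early stopping keeps the weights with the best validation success rate
(earliest epoch wins ties; patience 50 epochs, cap 1000). Model selection
sweeps `H ∈ {50, …, 650}` with four random restarts; ties prefer the
smaller `H`, then the earlier restart.

**RBF SVM.** `gamma = 2^a`, `C = 2^b` over `a ∈ [−5, 20]`,
`b ∈ [−5, 10]` in steps of 0.5 — the grid values are base-2 *exponents*,
since the kernel requires `γ > 0`. The quadratic program is delegated to a
standard solver (scikit-learn's SVC); the model is stored as its kernel
expansion (support vectors, `αᵢyᵢ`, bias) and every prediction is computed
from those stored fields, a contract tested against the trainer's own
decision function to 1e-8. No class weighting and no feature
standardization beyond the ICA projection are applied; imbalance effects
are deliberately surfaced by the evaluation module rather than corrected.

## Evaluation protocol

* `success_rate` = percentage correct at the intermediate threshold
  (score strictly greater than threshold ⇒ mass; a score exactly at the
  threshold is called normal).
* ROC curves sweep all distinct score thresholds; AUC is the trapezoidal
  integral and equals the Mann–Whitney statistic with ties counted 1/2
  (tested against an O(n²) pairwise oracle).
* `kfold_cv` stratifies by class × site, relaxing to class-only (then to
  unstratified) with a warning when strata are smaller than k.
* `optimize_extractor` runs the (size, q) grid under k-fold CV, refitting
  the ICA basis on each fold's training portion; ties prefer smaller q,
  then smaller size.
* **Site mode**: the learning set is *all* prototypes of one site, the test
  set is the complement; **overall mode**: a stratified random split,
  default 90/10. The learning set is split 80/20 into train/validation.
  The ICA basis and classifier never see test prototypes.
* Relative variation is `100·(overall_test − site_test)/overall_test`,
  rounded half-up (the `decimal` module; numpy's round-half-even would
  disagree on exact halves) to one decimal by default, two on request.

## Problem sizes and grids used in tests

The test suite and the acceptance script run the full pipeline at the
default roster scale (~630 prototypes, 32 px working size for the
robustness sweeps, 64 px for the headline pipeline AUC) with decimated
hyperparameter grids (`log2 γ ∈ {−9, −7, …, −1}`, `log2 C ∈ {−1, 1, 3, 5}`;
MLP `H ∈ {50}`–`{50, 100}` with 2 restarts, ≤ 200 epochs). These sizes are
the package's chosen desk-scale study conditions; the full grids remain the
defaults of the library functions.

## Known limitations

* The synthetic domain shift is driven by class imbalance, calibration and
  noise differences; real archives add annotation-style and population
  shifts the generator does not represent.
* FastICA on natural-patch data frequently stops at `max_iter` rather than
  the tolerance; the returned rotation is still orthogonal and the
  convergence flag/warning reports it.
* MLP determinism holds for a fixed seed on a fixed platform; across BLAS
  implementations bit-identity is not guaranteed.
* `LearningSplit.random` stratifies on class (and optionally site) only;
  pathology proportions within the mass class are left to chance.
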