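# Methods

This note records the models the package implements, the numerical and
design choices made where the method description left the design open,
what the synthetic generator does and does not emulate, and the known
limitations.

## Diverse-density dictionary learning

A class's dictionary atom is the maximizer of the diverse density

DD(t) = ∏ᵢ Pr(x=t|Bᵢ⁺) · ∏ᵢ Pr(x=t|Bᵢ⁻),

with noisy-OR positive-bag probabilities, product-form negative-bag
probabilities, and the Gaussian instance kernel exp(−‖b − t‖²) on the
plain (unweighted) Euclidean distance.  Implementation choices:

- **Log-domain arithmetic.**  DD is a product of potentially hundreds
  of factors and underflows linearly; all evaluation sums per-bag log
  factors.  An exact zero factor (a negative bag containing *t*) is
  represented by a −inf sentinel, never by a denormal.  Linear and log
  values agree to 1e-10 relative whenever DD > 1e-300 (tested).
- **Candidate-set maximization** is the default: DD is evaluated at
  every instance of every positive bag and the argmax returned, with
  ties broken by first occurrence.  This is deterministic and cheap
  (the candidate set is the training set).
- **Optional quasi-Newton refinement** (`refine=True`) runs L-BFGS-B
  from the best candidate with an analytic gradient, since the true
  argmax lives in the continuous spectral space.  Positive-bag
  gradients use leave-one-out products of (1 − pⱼ) so the pⱼ → 1 limit
  stays finite.  Near-saturated bags leave the objective O(1e-4) flat,
  so the stopping tolerances are far tighter than scipy's defaults
  (ftol 1e-15, gtol 1e-12).  On synthetic clouds (20 bags of 5
  instances at σ = 0.1 per dimension in 10-D) refinement moves the
  recovered concept from ~0.15 to ~0.04–0.06 of the true center, and
  the refined point scores a strictly higher DD than the true center —
  the residual displacement is finite-sample estimator error, not an
  optimization defect.
- **Kernel scale.**  The exp(−d²) kernel resolves structure at squared
  distances of order 1 — it has a fixed bandwidth.  DD therefore runs
  on **raw reflectance by default**.  Pre-normalizing spectra to unit
  L2 before DD (available as `normalize=True`) collapses all pairwise
  squared distances of realistically correlated covers to ~0.03, two
  orders of magnitude under the bandwidth; the DD landscape then goes
  flat and atom selection becomes noise-driven (we measured occasional
  selection of contaminated instances and 10–25 point accuracy
  collapses).  The flag is kept because heavily scaled products
  (e.g. reflectance × 10⁴ integers) sit in the opposite regime, where
  every kernel value underflows and only the log-domain positive terms
  rank candidates.
- **Bag construction.**  Training pixels become singleton bags by
  default (`bag_size=1`): with no documented grouping protocol this is
  the least-assumption choice, and the negative-bag product is
  partition-invariant anyway.  Note that for positive bags the
  noisy-OR is degenerate at size 1 (bag probability = instance
  probability), so the "a bag is satisfied by any one good instance"
  robustness only operates at `bag_size ≥ 2`.  We measured size-2 bags
  on the benchmark and kept size 1: with very few positive bags the
  negative-repulsion term dominates the refined optimum and costs
  about a point of accuracy at the smallest training size.
- One atom per class; atoms are L2-normalized (the pursuit's energy
  identity requires unit atoms) and ordered by class code.

## Constrained matching pursuit

Greedy pursuit with three constraints reflecting linear-mixing physics:
selected atoms must correlate positively with the residual,
coefficients are non-negative by construction, and the finalized
coefficient vector lies on the probability simplex.

- **Selection** maximizes the signed inner product restricted to
  strictly positive values; anti-correlated atoms are never selected.
  Inner products at or below 1e-12 count as numerical zero — after an
  atom is subtracted its residual correlation is ±1e-17 in floats, and
  without the floor the pursuit chases roundoff-sign reselections.
- **Stopping**: residual norm ≤ ξ (default 1e-3 on unit-norm pixels),
  accumulated raw coefficient mass ≥ 1, no positively correlated atom,
  or the iteration cap (default 4× the atom count).  The residual test
  runs first; when a pixel equals an atom exactly both conditions
  coincide.
- **Sum-to-one** is enforced by rescaling the accumulated non-negative
  coefficients after termination.  Rescaling preserves the coefficient
  ranking, which is all the downstream threshold decision consumes.
  Re-selection of an atom accumulates onto its coefficient, preserving
  the expansion identity.
- The raw expansion trace is retained on every code; the energy
  identity ‖x‖² = Σc²ₘ + ‖R^M x‖² holds to 1e-10 on arbitrary random
  problems (tested on 1000 draws).

## Decision rule

A pixel is assigned by coefficient when its largest finalized
coefficient strictly exceeds the threshold (default 0.5; on the simplex
at most one coefficient can exceed 0.5, so the rule is unambiguous).
Otherwise the per-class squared reconstruction residual
r_k = ‖x − D_k α_k‖² decides, using the pursuit's stored coefficients
restricted to class k (a per-class least-squares refit is available as
`refit=True`; with one atom per class the argmin is unchanged).
Ties — including the all-zero code, for which every r_k equals ‖x‖² —
go to the lowest class code and are flagged as degenerate.  The
threshold is applied per atom; `per_class_sums=True` switches to
per-class coefficient sums for multi-atom dictionaries.
Zero-vector pixels cannot be normalized and receive a configurable
fill code (default 0, the unlabeled code), logged.

## Synthetic scenes

The generator produces desk-scale scenes in which every downstream
quantity has a known answer.

- **Endmembers** are sums of Gaussian bumps on the band grid,
  peak-normalized to 1.  The default family is a continuum shared by
  all classes plus one moderate class-specific feature, giving pairwise
  spectral cosines of ~0.977–0.986 — deliberately in the range of real
  same-biome ground covers, where small-sample classification is
  actually hard.  Classes closer than cosine 0.999 are rejected as
  indistinct.  Presets: 65 bands / 7 classes (push-broom VNIR style,
  40×42 px) and 166 bands / 6 classes (AVIRIS style, 30×36 px).
- **Layout** is one rectangular patch (vertical strip) per class; every
  pixel is labeled.
- **Brightness variability**: each pixel's composition is scaled by a
  lognormal factor with mean 1 and coefficient of variation 0.10
  (default).  This models illumination/geometry variability — the
  dominant within-class variance of real scenes and the reason
  angle-based classifiers outperform Euclidean nearest-mean there.
  With `brightness_cv=0` classes are spherical Gaussian clusters and a
  nearest-mean classifier is near-optimal by construction.
- **Mixed pixels**: a `mix_fraction` subset of pixels is drawn as
  convex combinations of the pixel's class endmember and one adjacent
  class's endmember, with 2-component flat-Dirichlet weights sorted so
  the labeled class keeps the larger abundance — ground truth remains
  the majority cover, so mixtures near weight 0.5 are genuinely
  ambiguous and bound the attainable accuracy.  Abundances are recorded
  and always sum to 1 within 1e-12.
- **Noise** is i.i.d. zero-mean Gaussian with σ² = mean(signal²) /
  10^(SNR/10), calibrated on the brightness-scaled signal; the
  empirical SNR of a rendered scene is within ±1 dB of the request
  (tested at 10⁴ pixels).
- **Training sampling**: total count = round(ratio × bands), split as
  evenly as possible with the remainder on the lowest class codes,
  drawn without replacement; exact per-class designs (e.g. 4/class on
  65 bands, 14/class on 166) are available as an override.  The
  `contaminate` step replaces a fraction of each class's training
  spectra with spectra drawn from the other classes, emulating
  mislabeled/impure training pixels.
- Everything is a pure function of (spec, seed).

**What passing tests do not show.**  The generator has no
radiative-transfer realism, no spatially correlated noise or textures,
no band-dependent noise, no spectral libraries, and its within-class
variability is purely multiplicative.  Results transfer to real scenes
only to the extent that those scenes are dominated by the modeled
effects (correlated endmembers, amplitude variability, two-member
mixing, label noise in training).

## Benchmark configuration

The pinned small-sample benchmark (used by the test suite and
`scripts/acceptance.py`) is the 65-band / 7-class preset at 40×42
pixels (240 labeled pixels per class — small enough that the full sweep
runs in seconds on one core), SNR 20 dB, 10% mixed pixels, 25%
contaminated training bags, training ratios {0.5, 1.0, 1.5} × bands,
3 repeated training draws per ratio.  On it the sparse classifier's
mean overall accuracy stays within about half a point across ratios
while the PCA minimum-distance baseline loses roughly 9 points between
ratio 1.5 and ratio 0.5 — the same qualitative ordering the method is
designed to produce.  Per-run metrics are written as
sorted-key JSON so identical configurations are byte-identical.

## Baselines

`PCA_MinD` fits PCA on the pooled training spectra, keeps the smallest
number of components reaching 99% explained variance (default,
configurable), and assigns pixels to the nearest class mean in the
projected space — distances in raw principal components, not whitened.
The SVM comparator is scikit-learn's RBF SVC behind a thin adapter; its
hyperparameters are exposed, not tuned, and it takes no part in
correctness guarantees.

## ENVI I/O

A deliberately small dialect: data types 1 (uint8), 2 (int16),
4 (float32), 12 (uint16); BSQ/BIL/BIP interleaves; byte-order honored;
unknown header keys ignored with a logged warning.  In memory every
cube is (rows, cols, bands) with 0-based coordinates regardless of
file interleave.  Integer payloads round-trip bit-exactly; float
payloads are stored as float32.  Label maps: code 0 is reserved for
unlabeled/background and classifiers never emit it (except as the
explicit zero-pixel fill code); storage as whitespace-delimited integer
grids or 1-band ENVI classification rasters.  No georeferencing,
projections, atmospheric correction, or bad-band masking.

## Known limitations

- The DD kernel has no per-dimension scaling, so results depend on the
  data's physical scale (see "Kernel scale" above); the normalize flag
  is the only provided control.
- One atom per class (the default) limits each class to a single
  spectral mode; `atoms_per_class=k` learns k atoms by repeated
  maximization with previously chosen candidates excluded, but the
  benchmark and defaults use one.
- Mean ± std columns from repeated runs use 3 repeats by default; the
  repeat count is configurable and the std is the sample standard
  deviation (ddof = 1).
- The pursuit is plain matching pursuit, not orthogonal MP or an
  L1 solver, by design.
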