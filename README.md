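# ddsr — diverse-density sparse classification for hyperspectral images

`ddsr` classifies hyperspectral image pixels when labeled training data
is scarce — the small-sample-size regime where the number of training
pixels is comparable to (or below) the number of spectral bands and
conventional supervised classifiers degrade (the Hughes phenomenon).
It is aimed at remote-sensing practitioners working with airborne
VNIR/SWIR cubes (tens to hundreds of bands, a handful of ground-cover
classes) and at anyone who wants a small, fully testable reference
implementation of multiple-instance dictionary learning plus
constrained sparse coding.

## The method

**1. Dictionary learning by diverse density (DD).**  Training pixels
for a target cover form *positive bags*; pixels of all other covers
form *negative bags*.  The diverse density of a candidate spectrum *t*
is

```
DD(t) = ∏ᵢ Pr(x = t | Bᵢ⁺) · ∏ᵢ Pr(x = t | Bᵢ⁻)
Pr(x = t | Bᵢ⁺) = 1 − ∏ⱼ (1 − Pr(x = t | Bᵢⱼ⁺))        (noisy-OR)
Pr(x = t | Bᵢ⁻) = ∏ⱼ (1 − Pr(x = t | Bᵢⱼ⁻))
Pr(x = t | Bᵢⱼ)  = exp(−‖Bᵢⱼ − t‖²)
```

DD is large where *t* is close to every positive bag and far from all
negative instances, so its maximizer is a noise- and
contamination-robust representative of the class: a bag containing a
few mislabeled pixels is still satisfied by its good ones.  The
maximizer (evaluated over all positive-bag instances, optionally
polished by a quasi-Newton ascent) is L2-normalized and becomes the
class's dictionary atom.

**2. Constrained matching pursuit.**  Each unit-normalized pixel *x*
is greedily decomposed over the dictionary *D*: at every step the atom
with the largest **positive** inner product with the residual is
selected (negative correlations have no physical meaning for mixed
pixels) and its projection subtracted, `R^{m+1}x = R^m x − ⟨R^m x, d⟩ d`,
until the residual norm falls below the relaxation factor ξ, the
accumulated coefficient mass reaches 1, or no positively correlated
atom remains.  The raw expansion obeys the energy identity
`‖x‖² = Σ|⟨R^m x, d_m⟩|² + ‖R^M x‖²`; the final coefficients are
rescaled onto the probability simplex (non-negative, summing to 1).

**3. Decision rule.**  If the largest coefficient exceeds 0.5 the
pixel takes that atom's class directly; otherwise the class minimizing
the per-class reconstruction residual `r_k(x) = ‖x − D_k α_k‖²` wins.

The package also ships a synthetic scene simulator with known ground
truth (endmembers, abundances, calibrated SNR, mixed pixels,
contaminated training bags), a PCA minimum-distance baseline
(`PCA_MinD`), an SVM adapter, ENVI-format I/O, and accuracy metrics
(overall/per-class accuracy, Cohen's kappa).

## Worked example

Simulate a 65-band, 7-class scene at SNR 20 dB with 10% mixed pixels,
learn a dictionary from training pixels amounting to half the band
count (32 pixels, 4–5 per class), classify, and score:

```
$ ddsr simulate --spec scene.cfg --out scene
scene written: scene/scene.hdr (40x42x65, 7 classes, SNR 20 dB)

$ ddsr learn --cube scene/scene.hdr --truth scene/truth.txt --ratio 0.5 --seed 7 --out dict.txt
dictionary with 7 atoms written to dict.txt

$ ddsr classify --cube scene/scene.hdr --dict dict.txt --out map
classification map written to map.txt

$ ddsr evaluate --truth scene/truth.txt --pred map.txt --out metrics.json
OA 98.81%  kappa 0.986  (1680 pixels)
```

where `scene.cfg` contains

```
rows = 40
cols = 42
bands = 65
n_classes = 7
snr_db = 20
mix_fraction = 0.1
seed = 7
```

`OA` is the percentage of labeled pixels classified correctly; `kappa`
is the chance-corrected agreement.  With only 32 training pixels for a
65-band cube the sparse classifier stays near 99% on this scene, while
the PCA minimum-distance baseline drops into the low 80s (run
`ddsr sweep --config <cfg>` for the side-by-side table).

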