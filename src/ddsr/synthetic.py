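"""Synthetic hyperspectral scenes with known ground truth.

Scenes are built from smooth per-class endmember spectra (sums of
Gaussian bumps on the band grid, peak-normalized to 1), laid out as one
rectangular patch per class, with additive Gaussian noise calibrated to
a target SNR in dB and an optional fraction of two-class linearly mixed
pixels.  Every output is a pure function of (spec, seed), so each
downstream stage — dictionary learning, sparse coding, decision rule,
metrics — has a desk-scale oracle with recorded abundances.

Presets mirror the two airborne-campaign configurations used throughout
the package's benchmarks: a 65-band / 7-class scene (push-broom imager
style) and a 166-band / 6-class scene (AVIRIS style).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .io_hsi import HsiCube, LabelMap

#: (center_band, width_bands, amplitude) triples per class
BumpSpec = tuple[tuple[float, float, float], ...]


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.

    snr_db is mean signal power over mean noise power in dB;
    mix_fraction is the share of labeled pixels drawn as two-class
    convex mixtures.  endmember_spec gives per-class Gaussian bump
    triples (center_band, width_bands, amplitude); when None a default
    family of overlapping smooth spectra is generated.
    """

    rows: int = 40
    cols: int = 42
    bands: int = 65
    n_classes: int = 7
    snr_db: float = 20.0
    mix_fraction: float = 0.0
    brightness_cv: float = 0.10
    seed: int = 0
    endmember_spec: tuple[BumpSpec, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.bands < 2:
            raise ValueError("need at least 2 bands")
        if not (0 <= self.mix_fraction < 1):
            raise ValueError("mix_fraction must be in [0, 1)")
        if self.brightness_cv < 0:
            raise ValueError("brightness_cv must be >= 0")
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")
        if self.endmember_spec is not None and len(self.endmember_spec) != self.n_classes:
            raise ValueError("endmember_spec needs one bump list per class")


def phi_like_spec(**overrides) -> SceneSpec:
    """65-band, 7-class scene in the style of a push-broom VNIR imager."""
    defaults = dict(rows=40, cols=42, bands=65, n_classes=7)
    defaults.update(overrides)
    return SceneSpec(**defaults)


def aviris_like_spec(**overrides) -> SceneSpec:
    """166-band, 6-class scene in the style of an AVIRIS subset."""
    defaults = dict(rows=30, cols=36, bands=166, n_classes=6)
    defaults.update(overrides)
    return SceneSpec(**defaults)


@dataclass
class SceneTruth:
    """A rendered scene plus everything needed to score it."""

    cube: HsiCube
    labels: LabelMap
    endmembers: np.ndarray  # (n_classes, bands), codes 1..n_classes
    abundances: np.ndarray  # (rows, cols, n_classes), rows sum to 1
    brightness: np.ndarray = None  # (rows, cols) per-pixel scale factor
    spec: SceneSpec = field(repr=False, default=None)

    def __post_init__(self) -> None:
        sums = self.abundances.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-12):
            raise ValueError("per-pixel abundances must sum to 1")
        if np.any(self.abundances < 0):
            raise ValueError("abundances must be non-negative")
        if self.brightness is None:
            self.brightness = np.ones(self.abundances.shape[:2])

    def clean_signal(self) -> np.ndarray:
        """The noise-free scene: brightness-scaled abundance mixtures."""
        return self.brightness[:, :, None] * (self.abundances @ self.endmembers)


def _default_bumps(spec: SceneSpec) -> tuple[BumpSpec, ...]:
    """Smooth, strongly correlated spectra: a continuum shared by every
    class plus one moderate class-specific feature.  Real ground covers
    (different vegetation types especially) have pairwise spectral
    cosines well above 0.9 — class separability comes from modest local
    features riding on a common shape, which is exactly the regime where
    small training sets and noise hurt."""
    bands, k = spec.bands, spec.n_classes
    continuum = (
        (bands * 0.35, bands * 0.25, 0.9),
        (bands * 0.75, bands * 0.30, 0.7),
    )
    out = []
    for c in range(k):
        center = (c + 0.5) * bands / k
        width = max(1.5, bands / (2.0 * k))
        out.append(continuum + ((center, width, 0.45),))
    return tuple(out)


def make_endmembers(spec: SceneSpec) -> np.ndarray:
    """Per-class endmember spectra on the band grid, peak-normalized to 1.

    Each class spectrum is the sum of its Gaussian bumps; classes must be
    distinct (pairwise cosine similarity < 0.999).
    """
    bumps = spec.endmember_spec or _default_bumps(spec)
    grid = np.arange(spec.bands, dtype=float)
    endmembers = np.zeros((spec.n_classes, spec.bands))
    for c, bump_list in enumerate(bumps):
        s = np.zeros(spec.bands)
        for center, width, amp in bump_list:
            s += amp * np.exp(-0.5 * ((grid - center) / width) ** 2)
        peak = s.max()
        if peak <= 0:
            raise ValueError(f"class {c + 1} endmember is identically zero")
        endmembers[c] = s / peak
    unit = endmembers / np.linalg.norm(endmembers, axis=1, keepdims=True)
    cos = unit @ unit.T
    np.fill_diagonal(cos, 0.0)
    if cos.max() >= 0.999:
        i, j = np.unravel_index(np.argmax(cos), cos.shape)
        raise ValueError(
            f"classes {i + 1} and {j + 1} are spectrally indistinct "
            f"(cosine {cos[i, j]:.6f})"
        )
    return endmembers


def _block_layout(spec: SceneSpec) -> np.ndarray:
    """One rectangular patch (vertical strip of columns) per class."""
    if spec.cols < spec.n_classes:
        raise ValueError(
            f"{spec.cols} columns cannot host {spec.n_classes} class patches"
        )
    labels = np.zeros((spec.rows, spec.cols), dtype=int)
    for c, cols in enumerate(np.array_split(np.arange(spec.cols), spec.n_classes)):
        labels[:, cols] = c + 1
    return labels


def render_scene(spec: SceneSpec) -> SceneTruth:
    """Render a scene: block layout, linear mixing, brightness
    variability, calibrated noise.

    Each pixel's composition is scaled by a lognormal per-pixel
    brightness factor (mean 1, coefficient of variation brightness_cv)
    modelling illumination/geometry variability — the dominant
    within-class variance of real scenes.  Noise sigma then solves
    mean(signal^2) / sigma^2 = 10^(snr_db/10) on the brightness-scaled
    signal.  The mixed subset draws 2-component weights from a flat
    Dirichlet, sorted so the labeled class keeps the larger abundance
    (ground truth stays the majority cover).
    """
    rng = np.random.default_rng(spec.seed)
    endmembers = make_endmembers(spec)
    labels = _block_layout(spec)
    rows, cols, k = spec.rows, spec.cols, spec.n_classes

    abundances = np.zeros((rows, cols, k))
    own = labels - 1
    abundances[np.arange(rows)[:, None], np.arange(cols)[None, :], own] = 1.0

    if spec.mix_fraction > 0:
        flat = np.flatnonzero(labels.ravel() > 0)
        n_mix = int(round(spec.mix_fraction * flat.size))
        chosen = rng.choice(flat, size=n_mix, replace=False)
        w = np.sort(rng.dirichlet((1.0, 1.0), size=n_mix), axis=1)[:, ::-1]
        for (idx, (w_own, w_other)) in zip(chosen, w):
            r, c = divmod(int(idx), cols)
            c_own = labels[r, c] - 1
            neighbors = [c_own - 1, c_own + 1]
            neighbors = [n for n in neighbors if 0 <= n < k]
            c_other = int(rng.choice(neighbors))
            abundances[r, c, :] = 0.0
            abundances[r, c, c_own] = w_own
            abundances[r, c, c_other] = w_other

    if spec.brightness_cv > 0:
        s_ln = np.sqrt(np.log1p(spec.brightness_cv**2))
        brightness = rng.lognormal(mean=-0.5 * s_ln**2, sigma=s_ln, size=(rows, cols))
    else:
        brightness = np.ones((rows, cols))
    signal = brightness[:, :, None] * (abundances @ endmembers)  # (rows, cols, bands)
    p_signal = float(np.mean(signal**2))
    sigma = np.sqrt(p_signal / 10.0 ** (spec.snr_db / 10.0))
    data = signal + rng.normal(0.0, sigma, size=signal.shape)

    cube = HsiCube(data=data)
    class_names = {c + 1: f"class_{c + 1}" for c in range(k)}
    return SceneTruth(
        cube=cube,
        labels=LabelMap(labels=labels, class_names=class_names),
        endmembers=endmembers,
        abundances=abundances,
        brightness=brightness,
        spec=spec,
    )


def empirical_snr_db(truth: SceneTruth) -> float:
    """SNR estimated from the stored clean signal and residual noise."""
    signal = truth.clean_signal()
    noise = truth.cube.data - signal
    return 10.0 * np.log10(np.mean(signal**2) / np.mean(noise**2))


def sample_training(
    truth: SceneTruth,
    ratio_to_bands: float | None = None,
    seed: int = 0,
    per_class_counts: dict[int, int] | None = None,
) -> dict[int, np.ndarray]:
    """Draw labeled training spectra from a rendered scene.

    See :func:`sample_training_map` for the sizing rules.
    """
    return sample_training_map(truth.cube, truth.labels, ratio_to_bands,
                               seed=seed, per_class_counts=per_class_counts)


def sample_training_map(
    cube: HsiCube,
    label_map: LabelMap,
    ratio_to_bands: float | None = None,
    seed: int = 0,
    per_class_counts: dict[int, int] | None = None,
) -> dict[int, np.ndarray]:
    """Draw labeled training spectra, sized relative to the band count.

    Total count = round(ratio_to_bands x bands), split as evenly as
    possible across classes with the remainder going to the lowest class
    codes; sampling is without replacement and reproducible under
    ``seed``.  ``per_class_counts`` overrides the ratio interface to
    reproduce exact per-class designs (e.g. 4 per class on 65 bands,
    14 per class on 166 bands).
    """
    labels = label_map.labels
    codes = label_map.codes()
    if per_class_counts is not None:
        quotas = {c: int(per_class_counts[c]) for c in codes}
    else:
        if ratio_to_bands is None or ratio_to_bands <= 0:
            raise ValueError("ratio_to_bands must be positive")
        total = int(round(ratio_to_bands * cube.bands))
        base, rem = divmod(total, len(codes))
        quotas = {c: base + (1 if i < rem else 0) for i, c in enumerate(codes)}

    rng = np.random.default_rng(seed)
    pixels = cube.pixels()
    out: dict[int, np.ndarray] = {}
    for code in codes:
        pool = np.flatnonzero(labels.ravel() == code)
        quota = quotas[code]
        if quota > pool.size:
            raise ValueError(
                f"class {code} has {pool.size} labeled pixels, quota {quota}"
            )
        chosen = rng.choice(pool, size=quota, replace=False)
        out[code] = pixels[np.sort(chosen)].astype(float)
    return out


def contaminate(
    training: dict[int, np.ndarray],
    fraction: float,
    seed: int = 0,
) -> dict[int, np.ndarray]:
    """Replace a fraction of each class's training spectra with spectra
    drawn from the other classes — impure training bags.

    Exercises the robustness the diverse-density learner is built for:
    a positive bag need only contain *some* true instances.  fraction 0
    returns the input unchanged.
    """
    if not (0 <= fraction < 1):
        raise ValueError("fraction must be in [0, 1)")
    if fraction == 0:
        return {c: np.array(v, copy=True) for c, v in training.items()}
    rng = np.random.default_rng(seed)
    codes = sorted(training)
    out: dict[int, np.ndarray] = {}
    for code in codes:
        samples = np.array(training[code], copy=True)
        n = samples.shape[0]
        n_swap = int(round(fraction * n))
        if n_swap == 0:
            out[code] = samples
            continue
        others = np.concatenate([training[c] for c in codes if c != code], axis=0)
        swap_idx = rng.choice(n, size=n_swap, replace=False)
        donor_idx = rng.choice(others.shape[0], size=n_swap, replace=True)
        samples[swap_idx] = others[donor_idx]
        out[code] = samples
    return out


def write_scene(truth: SceneTruth, out_dir: str | Path) -> dict[str, Path]:
    """Persist a scene via io_hsi: ENVI cube + label grid + endmember table."""
    from . import io_hsi

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cube": out_dir / "scene.hdr",
        "truth": out_dir / "truth.txt",
        "endmembers": out_dir / "endmembers.txt",
    }
    io_hsi.write_envi(truth.cube, paths["cube"])
    io_hsi.write_label_grid(truth.labels, paths["truth"])
    np.savetxt(paths["endmembers"], truth.endmembers)
    return paths
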