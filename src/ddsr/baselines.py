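"""Comparator classifiers: PCA + minimum distance, and an SVM adapter.

PCA_MinD projects spectra onto the principal components of the pooled
training set (enough components to reach a target explained-variance
fraction) and assigns each pixel to the nearest class mean in that
space.  The SVM comparator is a thin adapter over scikit-learn's RBF
SVC; its hyperparameters are exposed but not tuned here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.svm import SVC

from .io_hsi import HsiCube, LabelMap


@dataclass
class PcaMindModel:
    """PCA projection plus per-class means in the projected space."""

    mean_spectrum: np.ndarray  # (bands,)
    components: np.ndarray  # (p, bands), orthonormal rows
    class_means: dict[int, np.ndarray]  # code -> (p,)
    p: int
    explained_variance_ratio: np.ndarray

    def project(self, spectra: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(spectra) - self.mean_spectrum) @ self.components.T


def fit_pca_mind(training: dict[int, np.ndarray], variance_kept: float = 0.99) -> PcaMindModel:
    """Fit PCA on pooled training spectra and class means in PC space.

    p is the smallest component count whose cumulative explained
    variance reaches ``variance_kept``.
    """
    if not (0 < variance_kept <= 1):
        raise ValueError("variance_kept must be in (0, 1]")
    codes = sorted(training)
    pooled = np.concatenate([np.atleast_2d(training[c]) for c in codes], axis=0)
    if pooled.shape[0] < 2:
        raise ValueError("need at least 2 training spectra")
    if np.allclose(pooled, pooled[0]):
        raise ValueError("training spectra have zero variance")

    pca = PCA(n_components=min(pooled.shape))
    pca.fit(pooled)
    ratios = pca.explained_variance_ratio_
    cum = np.cumsum(ratios)
    # drop numerically-zero tail components before thresholding
    rank = int(np.sum(pca.explained_variance_ > 1e-12 * pca.explained_variance_[0]))
    p = int(np.searchsorted(cum, variance_kept - 1e-12) + 1)
    p = max(1, min(p, rank))

    model = PcaMindModel(
        mean_spectrum=pca.mean_,
        components=pca.components_[:p],
        class_means={},
        p=p,
        explained_variance_ratio=ratios[:p],
    )
    model.class_means = {
        c: model.project(np.atleast_2d(training[c])).mean(axis=0) for c in codes
    }
    return model


def predict_pca_mind(model: PcaMindModel, cube: HsiCube) -> LabelMap:
    """Nearest-class-mean assignment in PC space; ties -> lowest code."""
    if cube.bands != model.mean_spectrum.shape[0]:
        raise ValueError(
            f"cube has {cube.bands} bands, model {model.mean_spectrum.shape[0]}"
        )
    codes = sorted(model.class_means)
    means = np.array([model.class_means[c] for c in codes])  # (K, p)
    proj = model.project(cube.pixels())  # (n, p)
    d2 = ((proj[:, None, :] - means[None, :, :]) ** 2).sum(axis=2)
    winners = np.array(codes)[np.argmin(d2, axis=1)]
    labels = winners.reshape(cube.rows, cube.cols)
    return LabelMap(labels=labels, class_names={c: f"class_{c}" for c in codes})


@dataclass
class SvmModel:
    """Adapter over a fitted scikit-learn SVC."""

    svc: SVC
    codes: list[int]


def fit_svm(training: dict[int, np.ndarray], C: float = 10.0, gamma="scale") -> SvmModel:
    """RBF-kernel SVM on raw training spectra (off-the-shelf comparator)."""
    codes = sorted(training)
    X = np.concatenate([np.atleast_2d(training[c]) for c in codes], axis=0)
    y = np.concatenate([[c] * np.atleast_2d(training[c]).shape[0] for c in codes])
    svc = SVC(C=C, gamma=gamma, kernel="rbf")
    svc.fit(X, y)
    return SvmModel(svc=svc, codes=codes)


def predict_svm(model: SvmModel, cube: HsiCube) -> LabelMap:
    labels = model.svc.predict(cube.pixels()).reshape(cube.rows, cube.cols).astype(int)
    return LabelMap(labels=labels, class_names={c: f"class_{c}" for c in model.codes})
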