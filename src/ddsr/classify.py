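"""Pixel classification from sparse codes: coefficient threshold, then
minimum-residual fallback.

A pixel whose largest finalized coefficient exceeds the threshold
(default 0.5 — a majority of the simplex mass on one atom) is assigned
that atom's class directly.  Otherwise the per-class reconstruction
residual ``r_k(x) = ||x - D_k a_k||^2`` is computed from the stored
coefficients restricted to class ``k`` and the class of minimum residual
wins.  Ties, including the degenerate all-zero code, go to the lowest
class code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_hsi import HsiCube, LabelMap
from .sparse_coding import Dictionary, MPConfig, SparseCode, matching_pursuit, normalize_pixel

logger = logging.getLogger(__name__)


@dataclass
class Decision:
    """One pixel's class assignment and how it was reached."""

    class_code: int
    rule_used: str  # "coefficient" | "residual"
    top_coefficient: float
    per_class_residuals: dict[int, float] | None = None
    degenerate: bool = False


def decide(
    code: SparseCode,
    x: np.ndarray,
    dictionary: Dictionary,
    threshold: float = 0.5,
    per_class_sums: bool = False,
    refit: bool = False,
) -> Decision:
    """Assign a class to a sparse-coded pixel.

    Parameters
    ----------
    threshold : float in (0, 1]
        Coefficient-rule cutoff; "greater than" is strict.
    per_class_sums : bool
        Apply the threshold to per-class coefficient sums instead of
        single atoms (identical when each class has one atom).
    refit : bool
        Recompute each class's coefficients by least squares on its own
        atoms before the residual rule, instead of reusing the pursuit's
        stored coefficients.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    x = np.asarray(x, dtype=float)
    coef = code.coefficients
    codes = dictionary.codes()

    if per_class_sums:
        sums = np.array([coef[dictionary.class_mask(c)].sum() for c in codes])
        top_idx = int(np.argmax(sums))
        top = float(sums[top_idx])
        top_class = int(codes[top_idx])
    else:
        atom_idx = int(np.argmax(coef))
        top = float(coef[atom_idx])
        top_class = int(dictionary.class_codes[atom_idx])

    if top > threshold:
        return Decision(class_code=top_class, rule_used="coefficient", top_coefficient=top)

    residuals: dict[int, float] = {}
    for c in codes:
        mask = dictionary.class_mask(int(c))
        atoms_k = dictionary.atoms[mask]
        if refit:
            alpha_k, *_ = np.linalg.lstsq(atoms_k.T, x, rcond=None)
        else:
            alpha_k = coef[mask]
        recon = atoms_k.T @ alpha_k
        residuals[int(c)] = float(np.sum((x - recon) ** 2))
    r = np.array([residuals[int(c)] for c in codes])
    winner = int(codes[int(np.argmin(r))])  # argmin ties -> lowest code
    degenerate = bool(np.allclose(r, r[0]))
    return Decision(
        class_code=winner,
        rule_used="residual",
        top_coefficient=top,
        per_class_residuals=residuals,
        degenerate=degenerate,
    )


def classify_pixel(
    x: np.ndarray,
    dictionary: Dictionary,
    cfg: MPConfig | None = None,
    per_class_sums: bool = False,
    refit: bool = False,
) -> Decision:
    """normalize -> matching pursuit -> decide, for one raw spectrum."""
    cfg = cfg or MPConfig()
    xn = normalize_pixel(x)
    code = matching_pursuit(xn, dictionary, cfg)
    return decide(code, xn, dictionary, threshold=cfg.coef_threshold,
                  per_class_sums=per_class_sums, refit=refit)


def classify_cube(
    cube: HsiCube,
    dictionary: Dictionary,
    cfg: MPConfig | None = None,
    fill_code: int = 0,
    per_class_sums: bool = False,
    refit: bool = False,
    audit_path=None,
) -> LabelMap:
    """Classify every pixel of a cube; deterministic given its inputs.

    Zero-vector pixels cannot be normalized and receive ``fill_code``
    (logged).  An optional audit file records per-pixel decisions as
    tab-separated text.
    """
    cfg = cfg or MPConfig()
    if cube.bands != dictionary.bands:
        raise ValueError(
            f"cube has {cube.bands} bands, dictionary {dictionary.bands}"
        )
    labels = np.zeros((cube.rows, cube.cols), dtype=int)
    audit_lines = ["row\tcol\trule\tclass\ttop_coefficient"] if audit_path else None
    n_zero = 0
    for r in range(cube.rows):
        for c in range(cube.cols):
            x = cube.data[r, c].astype(float)
            if np.linalg.norm(x) == 0:
                labels[r, c] = fill_code
                n_zero += 1
                continue
            d = classify_pixel(x, dictionary, cfg,
                               per_class_sums=per_class_sums, refit=refit)
            labels[r, c] = d.class_code
            if audit_lines is not None:
                audit_lines.append(
                    f"{r}\t{c}\t{d.rule_used}\t{d.class_code}\t{d.top_coefficient:.6g}"
                )
    if n_zero:
        logger.warning("%d zero-vector pixels assigned fill code %d", n_zero, fill_code)
    if audit_path and audit_lines is not None:
        from pathlib import Path

        Path(audit_path).write_text("\n".join(audit_lines) + "\n")
    return LabelMap(labels=labels, class_names=dict(dictionary.class_names))
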