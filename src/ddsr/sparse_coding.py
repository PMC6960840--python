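"""Sign- and simplex-constrained matching pursuit over a class dictionary.

The sparse model seeks ``min ||a||_0  s.t.  ||x - D a|| <= xi`` with the
physical constraints of linear mixing: coefficients are non-negative and,
once any atom has been selected, sum to one.  The pursuit is greedy: at
each step the residual is projected onto the positively correlated atom
with the largest inner product and that projection is subtracted.  Atoms
anti-correlated with the residual are never selected — a negative
abundance has no physical meaning for a mixed pixel.

Stopping: residual norm <= xi (relaxation factor), accumulated raw
coefficient mass >= 1 (the simplex is full), no positively correlated
atom remains, or the iteration cap.  The raw expansion satisfies the
energy identity ``||x||^2 = sum_m c_m^2 + ||R^M x||^2`` exactly; the
final coefficients are the raw ones rescaled onto the probability
simplex, which preserves their ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

_ATOL = 1e-10
#: inner products at or below this are numerical zero, not positive
#: correlation — keeps the pursuit from chasing roundoff after it has
#: exhausted the genuinely correlated atoms
_IP_EPS = 1e-12


@dataclass
class Dictionary:
    """Ordered unit-norm atoms, grouped contiguously by ascending class code.

    Parameters
    ----------
    atoms : ndarray, shape (m, bands)
        One L2-normalized spectrum per row.
    class_codes : ndarray, shape (m,)
        The class each atom represents; ascending, contiguous groups.
    class_names : dict
        Code -> human-readable name.
    meta : dict
        Provenance (normalization flag, bag size, seed, ...).
    """

    atoms: np.ndarray
    class_codes: np.ndarray
    class_names: dict[int, str] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.atoms = np.atleast_2d(np.asarray(self.atoms, dtype=float))
        self.class_codes = np.asarray(self.class_codes, dtype=int)
        if self.atoms.shape[0] != self.class_codes.shape[0]:
            raise ValueError("one class code per atom required")
        if self.atoms.shape[0] == 0:
            raise ValueError("empty dictionary")
        norms = np.linalg.norm(self.atoms, axis=1)
        if not np.allclose(norms, 1.0, atol=_ATOL):
            raise ValueError("atoms must be unit L2 norm")
        if np.any(np.diff(self.class_codes) < 0):
            raise ValueError("class codes must be ascending")
        if not self.class_names:
            self.class_names = {int(c): f"class_{int(c)}" for c in np.unique(self.class_codes)}

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[0]

    @property
    def bands(self) -> int:
        return self.atoms.shape[1]

    def codes(self) -> np.ndarray:
        """Distinct class codes, ascending."""
        return np.unique(self.class_codes)

    def class_mask(self, code: int) -> np.ndarray:
        return self.class_codes == code

    def save(self, path: str | Path) -> None:
        """Text format: '#' metadata lines, then one atom per line
        (class code, class name, band values)."""
        lines = [f"# ddsr dictionary: {self.n_atoms} atoms, {self.bands} bands"]
        for key in sorted(self.meta):
            lines.append(f"# meta {key} = {self.meta[key]}")
        for code, atom in zip(self.class_codes, self.atoms):
            name = self.class_names.get(int(code), f"class_{int(code)}")
            vals = " ".join(f"{v:.17g}" for v in atom)
            lines.append(f"{int(code)}\t{name}\t{vals}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "Dictionary":
        meta: dict = {}
        codes: list[int] = []
        names: dict[int, str] = {}
        rows: list[np.ndarray] = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ").strip()
                if body.startswith("meta "):
                    key, _, value = body[5:].partition("=")
                    meta[key.strip()] = value.strip()
                continue
            code_s, name, vals = line.split("\t", 2)
            code = int(code_s)
            codes.append(code)
            names[code] = name
            rows.append(np.fromstring(vals, sep=" "))
        return cls(atoms=np.array(rows), class_codes=np.array(codes),
                   class_names=names, meta=meta)


@dataclass
class MPConfig:
    """Matching-pursuit settings.

    xi : residual-norm stopping tolerance (relaxation factor) on
        unit-normalized pixels.
    max_iter : iteration cap; default 4x the number of atoms.
    coef_threshold : the downstream decision threshold on the largest
        finalized coefficient.
    """

    xi: float = 1e-3
    max_iter: int | None = None
    coef_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.xi < 0:
            raise ValueError("xi must be >= 0")
        if self.max_iter is not None and self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not (0 < self.coef_threshold <= 1):
            raise ValueError("coef_threshold must be in (0, 1]")

    def resolve_max_iter(self, n_atoms: int) -> int:
        return self.max_iter if self.max_iter is not None else 4 * n_atoms


@dataclass
class SparseCode:
    """Result of one pursuit.

    ``coefficients`` are the finalized (simplex-rescaled) per-atom
    weights; ``selected`` is the raw expansion trace as
    ``(iteration, atom_index, raw_inner_product)`` tuples, which is what
    the energy identity is stated on.
    """

    coefficients: np.ndarray
    selected: list[tuple[int, int, float]]
    final_residual_norm: float
    terminated_by: str  # simplex_full | no_positive_atom | residual_tol | max_iter
    raw_sum: float

    def raw_coefficients(self) -> np.ndarray:
        out = np.zeros_like(self.coefficients)
        for _, idx, c in self.selected:
            out[idx] += c
        return out


def normalize_pixel(x: np.ndarray) -> np.ndarray:
    """Return ``x / ||x||_2``; rejects the zero vector."""
    x = np.asarray(x, dtype=float)
    norm = np.linalg.norm(x)
    if norm == 0:
        raise ValueError("cannot normalize a zero spectrum")
    return x / norm


def select_atom(residual: np.ndarray, dictionary: Dictionary) -> tuple[int, float] | None:
    """Best positively correlated atom for the residual, or ``None``.

    Returns ``(index, inner_product)`` for the atom maximizing
    ``<residual, d_i>`` when that maximum is strictly positive (above
    numerical zero); ties go to the lowest atom index.  Anti-correlated
    atoms are never selected.
    """
    residual = np.asarray(residual, dtype=float)
    if residual.shape[0] != dictionary.bands:
        raise ValueError(
            f"residual has {residual.shape[0]} bands, dictionary {dictionary.bands}"
        )
    ips = dictionary.atoms @ residual
    idx = int(np.argmax(ips))
    if ips[idx] <= _IP_EPS:
        return None
    return idx, float(ips[idx])


def matching_pursuit(x: np.ndarray, dictionary: Dictionary, cfg: MPConfig | None = None) -> SparseCode:
    """Greedy constrained pursuit of unit-norm pixel ``x`` over the dictionary."""
    cfg = cfg or MPConfig()
    x = np.asarray(x, dtype=float)
    if abs(np.linalg.norm(x) - 1.0) > 1e-8:
        raise ValueError("matching_pursuit expects a unit-normalized pixel")
    max_iter = cfg.resolve_max_iter(dictionary.n_atoms)

    coefficients = np.zeros(dictionary.n_atoms)
    selected: list[tuple[int, int, float]] = []
    residual = x.copy()
    raw_sum = 0.0
    terminated_by = "max_iter"
    for m in range(max_iter):
        hit = select_atom(residual, dictionary)
        if hit is None:
            terminated_by = "no_positive_atom"
            break
        idx, c = hit
        coefficients[idx] += c
        raw_sum += c
        selected.append((m, idx, c))
        residual = residual - c * dictionary.atoms[idx]
        if np.linalg.norm(residual) <= cfg.xi:
            terminated_by = "residual_tol"
            break
        if raw_sum >= 1.0:
            terminated_by = "simplex_full"
            break

    if raw_sum > 0:
        coefficients = coefficients / raw_sum
    return SparseCode(
        coefficients=coefficients,
        selected=selected,
        final_residual_norm=float(np.linalg.norm(residual)),
        terminated_by=terminated_by,
        raw_sum=raw_sum,
    )


def expansion_energy_check(code: SparseCode, x: np.ndarray) -> float:
    """Defect of the pursuit energy identity; ~0 for a correct pursuit.

    Returns ``| ||x||^2 - sum_m c_m^2 - ||R^M x||^2 |`` computed from the
    raw expansion trace (the identity does not hold for the rescaled
    coefficients).
    """
    if code.selected is None:
        raise ValueError("sparse code lacks its expansion trace")
    x = np.asarray(x, dtype=float)
    energy = sum(c * c for _, _, c in code.selected)
    return abs(float(x @ x) - energy - code.final_residual_norm**2)


def dump_trace(code: SparseCode, path: str | Path) -> None:
    """Tab-separated pursuit trace for debugging."""
    lines = ["iteration\tatom_index\tinner_product"]
    for m, idx, c in code.selected:
        lines.append(f"{m}\t{idx}\t{c:.17g}")
    lines.append(f"# terminated_by = {code.terminated_by}")
    lines.append(f"# final_residual_norm = {code.final_residual_norm:.17g}")
    Path(path).write_text("\n".join(lines) + "\n")
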