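"""Diverse-density (multiple-instance) learning of class concept spectra.

A *bag* is a labeled set of pixel spectra: a positive bag for a ground
cover contains at least one true example of it, a negative bag contains
none.  The diverse density of a candidate point ``t`` is

    DD(t) = prod_i Pr(x=t | B_i+) * prod_i Pr(x=t | B_i-)

with the noisy-OR combination for positive bags,

    Pr(x=t | B_i+) = 1 - prod_j (1 - Pr(x=t | B_ij+)),
    Pr(x=t | B_i-) = prod_j (1 - Pr(x=t | B_ij-)),

and the Gaussian-kernel instance probability
``Pr(x=t | B_ij) = exp(-||B_ij - t||^2)`` (squared Euclidean distance).
DD is large where ``t`` sits close to every positive bag and far from
all negative instances; its maximizer is the class's concept point and,
after L2 normalization, a dictionary atom.

All arithmetic is done in the log domain (products of hundreds of
factors underflow); an exact zero factor is represented by a ``-inf``
log-DD sentinel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .sparse_coding import Dictionary

_TINY = 1e-300


@dataclass
class Bag:
    """A labeled set of spectra for one target class."""

    instances: np.ndarray  # (n, bands)
    polarity: str  # "positive" | "negative"
    target_class: int = 0

    def __post_init__(self) -> None:
        self.instances = np.atleast_2d(np.asarray(self.instances, dtype=float))
        if self.instances.shape[0] < 1:
            raise ValueError("a bag needs at least one instance")
        if not np.all(np.isfinite(self.instances)):
            raise ValueError("bag instances must be finite")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"unknown polarity {self.polarity!r}")


@dataclass
class Concept:
    """The DD maximizer for one class.

    ``seed_point`` is the winning candidate instance before any local
    refinement (equal to ``point`` in candidate mode).
    """

    point: np.ndarray
    dd_value: float
    log_dd: float
    seed_point: np.ndarray | None = None


@dataclass
class BagSpec:
    """How training spectra are grouped into bags."""

    bag_size: int = 1
    n_positive_bags: int | None = None
    n_negative_bags: int | None = None

    def __post_init__(self) -> None:
        if self.bag_size < 1:
            raise ValueError("bag_size must be >= 1")


def instance_prob(instance: np.ndarray, t: np.ndarray) -> float:
    """Gaussian-kernel probability ``exp(-||instance - t||^2)`` in (0, 1]."""
    instance = np.asarray(instance, dtype=float)
    t = np.asarray(t, dtype=float)
    if instance.shape != t.shape:
        raise ValueError(f"band counts differ: {instance.shape} vs {t.shape}")
    d2 = float(np.sum((instance - t) ** 2))
    return float(np.exp(-d2))


def _log_one_minus_probs(instances: np.ndarray, t: np.ndarray) -> np.ndarray:
    """log(1 - exp(-d^2)) per instance; -inf where the instance equals t."""
    d2 = np.sum((instances - t) ** 2, axis=1)
    with np.errstate(divide="ignore"):
        return np.log1p(-np.exp(-d2))


def _log_positive_bag_prob(bag: Bag, t: np.ndarray) -> float:
    lq = float(np.sum(_log_one_minus_probs(bag.instances, t)))
    if lq == -np.inf:  # an instance coincides with t: noisy-OR absorbs to 1
        return 0.0
    p = -np.expm1(lq)  # 1 - prod(1 - p_j)
    if p <= 0.0:
        return -np.inf
    return float(np.log(p))


def positive_bag_prob(bag: Bag, t: np.ndarray) -> float:
    """Noisy-OR probability that positive ``bag`` supports concept ``t``."""
    if bag.polarity != "positive":
        raise ValueError("positive_bag_prob requires a positive bag")
    t = np.asarray(t, dtype=float)
    _check_bands(bag, t)
    return float(np.exp(_log_positive_bag_prob(bag, t)))


def negative_bag_prob(bag: Bag, t: np.ndarray) -> float:
    """Probability that negative ``bag`` is consistent with concept ``t``."""
    if bag.polarity != "negative":
        raise ValueError("negative_bag_prob requires a negative bag")
    t = np.asarray(t, dtype=float)
    _check_bands(bag, t)
    return float(np.exp(np.sum(_log_one_minus_probs(bag.instances, t))))


def _check_bands(bag: Bag, t: np.ndarray) -> None:
    if bag.instances.shape[1] != t.shape[0]:
        raise ValueError(
            f"bag has {bag.instances.shape[1]} bands, t has {t.shape[0]}"
        )


def log_dd(bags: Sequence[Bag], t: np.ndarray) -> float:
    """Log diverse density at ``t``; ``-inf`` iff some factor is exactly 0."""
    t = np.asarray(t, dtype=float)
    if not any(b.polarity == "positive" for b in bags):
        raise ValueError("diverse density needs at least one positive bag")
    total = 0.0
    for bag in bags:
        _check_bands(bag, t)
        if bag.polarity == "positive":
            term = _log_positive_bag_prob(bag, t)
        else:
            term = float(np.sum(_log_one_minus_probs(bag.instances, t)))
        if term == -np.inf:
            return -np.inf
        total += term
    return total


def dd_value(bags: Sequence[Bag], t: np.ndarray) -> tuple[float, float]:
    """(DD, log DD) at ``t``.

    The log value is a sum of per-bag log factors (never the log of the
    linear product), so DD may underflow to 0 while log DD stays finite.
    """
    ld = log_dd(bags, t)
    return float(np.exp(ld)), ld


def _neg_log_dd_and_grad(t: np.ndarray, bags: Sequence[Bag]) -> tuple[float, np.ndarray]:
    """Objective and analytic gradient for the local-ascent refinement.

    d log(1-p)/dt = -2 p (b - t) / (1 - p) per instance with
    p = exp(-||b - t||^2); positive-bag gradients use leave-one-out
    products so the p -> 1 limit stays finite.
    """
    value = 0.0
    grad = np.zeros_like(t)
    for bag in bags:
        diff = bag.instances - t  # (n, bands)
        d2 = np.sum(diff**2, axis=1)
        p = np.exp(-d2)
        q = 1.0 - p
        if bag.polarity == "negative":
            if np.any(q <= 0):
                return 1e12, np.zeros_like(t)  # t collides with a negative instance
            value += float(np.sum(np.log(q)))
            grad += (-2.0 * p / q) @ diff
        else:
            prod_q = float(np.prod(q))
            big_p = 1.0 - prod_q
            if big_p <= 0:
                return 1e12, np.zeros_like(t)  # all instances too far: DD factor 0
            value += float(np.log(big_p))
            # d big_p/dt = sum_j 2 p_j diff_j * prod_{k!=j} q_k
            n = len(q)
            loo = np.array([np.prod(np.delete(q, j)) for j in range(n)])
            grad += (2.0 * p * loo / big_p) @ diff
    return -value, -grad


def maximize_dd(
    bags: Sequence[Bag],
    refine: bool = False,
    exclude: np.ndarray | None = None,
) -> Concept:
    """Maximize diverse density over the positive-bag instances.

    The candidate set is every instance of every positive bag; DD is
    evaluated at each and the argmax returned (ties broken by first
    occurrence in bag order, then instance order).  With ``refine``, a
    quasi-Newton local ascent is started from the best candidate and the
    better of the two points is returned — the true DD argmax lives in
    the continuous spectral space, not necessarily on an instance.
    ``exclude`` removes specific points from the candidate set (used for
    repeated maximization when learning several atoms per class).
    """
    positives = [b for b in bags if b.polarity == "positive"]
    if not positives:
        raise ValueError("maximize_dd needs at least one positive bag")
    candidates = np.concatenate([b.instances for b in positives], axis=0)
    if exclude is not None and len(exclude) > 0:
        keep = ~np.any(
            np.all(candidates[:, None, :] == np.atleast_2d(exclude)[None, :, :], axis=2),
            axis=1,
        )
        if not np.any(keep):
            raise ValueError("every candidate excluded")
        candidates = candidates[keep]
    scores = np.array([log_dd(bags, c) for c in candidates])
    best = int(np.argmax(scores))  # first occurrence wins ties
    best_point = candidates[best].copy()
    seed_point = candidates[best].copy()
    best_score = float(scores[best])

    if refine and np.isfinite(best_score):
        # near-saturated noisy-OR bags leave the objective O(1e-4) flat,
        # so the default stopping tolerances quit long before the optimum
        res = minimize(
            _neg_log_dd_and_grad,
            best_point,
            args=(bags,),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-15, "gtol": 1e-12},
        )
        refined_score = log_dd(bags, res.x)
        if refined_score > best_score:
            best_point, best_score = np.asarray(res.x), float(refined_score)

    dd = float(np.exp(best_score))
    return Concept(point=best_point, dd_value=dd, log_dd=best_score,
                   seed_point=seed_point)


def _partition(rows: np.ndarray, bag_size: int) -> list[np.ndarray]:
    """Sequential split into chunks of bag_size; last chunk may be short."""
    return [rows[i : i + bag_size] for i in range(0, len(rows), bag_size)]


def make_bags(
    training: dict[int, np.ndarray],
    target_class: int,
    bag_size: int = 1,
) -> list[Bag]:
    """Positive bags from the target class, negative bags from all others."""
    bags: list[Bag] = []
    for code in sorted(training):
        polarity = "positive" if code == target_class else "negative"
        for chunk in _partition(np.atleast_2d(training[code]), bag_size):
            bags.append(Bag(instances=chunk, polarity=polarity, target_class=target_class))
    return bags


def learn_dictionary(
    training: dict[int, np.ndarray],
    bag_spec: BagSpec | None = None,
    seed: int = 0,
    refine: bool = False,
    normalize: bool = False,
    atoms_per_class: int = 1,
    class_names: dict[int, str] | None = None,
) -> Dictionary:
    """Learn one unit-norm dictionary atom per class by DD maximization.

    Parameters
    ----------
    training : dict
        Class code -> (n_c, bands) training spectra.
    bag_spec : BagSpec
        Bag construction; default groups each spectrum as its own bag.
    normalize : bool
        L2-normalize spectra before DD.  The exp(-d^2) kernel is
        scale-sensitive: it resolves structure at squared distances of
        order 1.  On raw reflectance (default) class separations sit in
        that range; on unit-normalized spectra of correlated covers all
        pairwise distances collapse far below the kernel bandwidth and
        the DD landscape goes flat, so pre-normalization is off unless
        the data's natural scale is itself degenerate.
    atoms_per_class : int
        Learn k atoms per class by repeated maximization, excluding
        previously chosen candidate points from later rounds.
    """
    bag_spec = bag_spec or BagSpec()
    codes = sorted(training)
    if len(codes) < 2:
        raise ValueError("dictionary learning needs at least 2 classes")
    prepared: dict[int, np.ndarray] = {}
    for code in codes:
        samples = np.atleast_2d(np.asarray(training[code], dtype=float))
        if samples.shape[0] == 0:
            raise ValueError(f"class {code} has no training spectra")
        if normalize:
            norms = np.linalg.norm(samples, axis=1, keepdims=True)
            if np.any(norms == 0):
                raise ValueError(f"class {code} contains a zero spectrum")
            samples = samples / norms
        prepared[code] = samples

    if atoms_per_class < 1:
        raise ValueError("atoms_per_class must be >= 1")
    atoms = []
    atom_codes = []
    for code in codes:
        bags = make_bags(prepared, code, bag_spec.bag_size)
        chosen: list[np.ndarray] = []
        for _ in range(atoms_per_class):
            concept = maximize_dd(
                bags, refine=refine,
                exclude=np.array(chosen) if chosen else None,
            )
            chosen.append(concept.seed_point)
            atoms.append(concept.point / np.linalg.norm(concept.point))
            atom_codes.append(code)

    names = class_names or {c: f"class_{c}" for c in codes}
    return Dictionary(
        atoms=np.array(atoms),
        class_codes=np.array(atom_codes),
        class_names={c: names.get(c, f"class_{c}") for c in codes},
        meta={
            "normalize": normalize,
            "bag_size": bag_spec.bag_size,
            "seed": seed,
            "refine": refine,
            "atoms_per_class": atoms_per_class,
        },
    )
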