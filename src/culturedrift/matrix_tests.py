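"""Mantel and partial Mantel permutation tests.

Pairwise-distance entries are not independent observations — every group
takes part in n−1 of them — so ordinary correlation inference does not apply
to flattened matrices.  The Mantel test keeps the Pearson correlation of the
off-diagonal vectors as its statistic but builds its null distribution by
simultaneously permuting the rows and columns of one matrix, which preserves
the within-matrix dependence structure exactly.  The partial variant tests
the association of two matrices after removing the linear effect of a third
(first-order partial correlation), with the same permutation null.

Conventions, chosen once and logged:

* the FIRST matrix argument is the one permuted;
* sampled p-values use the add-one rule
  ``p = (1 + #extreme) / (n_perm + 1)`` so that p > 0 always;
* the default tail is two-sided on \\|r\\|;
* every sampling call takes an explicit seed; an omitted seed is drawn
  from the OS and logged so the run stays reproducible after the fact.

``mantel_exact`` enumerates all n! relabelings and exists chiefly as an
oracle for the sampler on small matrices.
"""

from __future__ import annotations

import enum
import itertools
import logging
import math
import secrets
from dataclasses import dataclass

import numpy as np

from .trait_matrix import PairwiseMatrix

__all__ = ["Tail", "MantelResult", "mantel", "mantel_exact", "partial_mantel"]

logger = logging.getLogger(__name__)

_EPS = 1e-12  # float slop when counting permutations as extreme


class Tail(str, enum.Enum):
    TWO_SIDED = "two-sided"
    GREATER = "greater"
    LESS = "less"


@dataclass(frozen=True)
class MantelResult:
    """Outcome of a (partial) Mantel test."""

    r_observed: float
    p_value: float
    n_permutations: int
    tail: Tail
    exact: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.r_observed <= 1.0 + 1e-9:
            raise ValueError("correlation outside [-1, 1]")
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p-value outside (0, 1]")


def _resolve_seed(seed: int | None) -> int:
    if seed is None:
        seed = secrets.randbelow(2**31)
        logger.info("no seed supplied; drew seed=%d", seed)
    return int(seed)


def _check_labels(*mats: PairwiseMatrix) -> None:
    ref = mats[0].labels
    for m in mats[1:]:
        if m.labels != ref:
            raise ValueError(
                "matrices must carry identical labels in identical order; "
                f"got {ref} vs {m.labels} (use .reorder() to align)"
            )


def _offdiag_checked(m: PairwiseMatrix, name: str) -> np.ndarray:
    v = m.offdiag()
    if np.ptp(v) == 0:
        raise ValueError(
            f"off-diagonal of {name} is constant; correlation undefined"
        )
    return v


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc)))


def _count_extreme(null: np.ndarray, observed: float, tail: Tail) -> int:
    if tail is Tail.TWO_SIDED:
        return int(np.sum(np.abs(null) >= abs(observed) - _EPS))
    if tail is Tail.GREATER:
        return int(np.sum(null >= observed - _EPS))
    return int(np.sum(null <= observed + _EPS))


def mantel(
    A: PairwiseMatrix,
    B: PairwiseMatrix,
    n_perm: int = 10_000,
    tail: Tail = Tail.TWO_SIDED,
    seed: int | None = None,
) -> MantelResult:
    """Sampled Mantel test of the association between two pairwise matrices.

    ``r_observed`` is the Pearson correlation of the two off-diagonal
    vectors; the null is built from ``n_perm`` random simultaneous
    row+column permutations of ``A`` with ``B`` held fixed.
    """
    _check_labels(A, B)
    tail = Tail(tail)
    n = A.n
    if n < 3:
        raise ValueError("Mantel test needs at least 3 groups")
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    va = _offdiag_checked(A, "first matrix")
    vb = _offdiag_checked(B, "second matrix")
    r_obs = _pearson(va, vb)
    seed = _resolve_seed(seed)
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    null = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(n)
        null[k] = _pearson(A.values[np.ix_(perm, perm)][iu], vb)
    count = _count_extreme(null, r_obs, tail)
    return MantelResult(
        r_observed=r_obs,
        p_value=(1 + count) / (n_perm + 1),
        n_permutations=n_perm,
        tail=tail,
        exact=False,
        seed=seed,
    )


def mantel_exact(
    A: PairwiseMatrix,
    B: PairwiseMatrix,
    tail: Tail = Tail.TWO_SIDED,
    max_n: int = 8,
) -> MantelResult:
    """Exact Mantel test by enumeration of all n! relabelings of ``A``.

    The identity permutation is part of the enumeration, so the smallest
    attainable p is 1/n!.  Feasible only for small matrices; larger inputs
    should use the sampled :func:`mantel`.
    """
    _check_labels(A, B)
    tail = Tail(tail)
    n = A.n
    if n < 3:
        raise ValueError("Mantel test needs at least 3 groups")
    if n > max_n:
        raise ValueError(
            f"n = {n} too large for {math.factorial(n)}-permutation enumeration; "
            "use the sampled mantel()"
        )
    va = _offdiag_checked(A, "first matrix")
    vb = _offdiag_checked(B, "second matrix")
    r_obs = _pearson(va, vb)
    iu = np.triu_indices(n, k=1)
    null = np.empty(math.factorial(n))
    for k, perm in enumerate(itertools.permutations(range(n))):
        p = np.asarray(perm)
        null[k] = _pearson(A.values[np.ix_(p, p)][iu], vb)
    count = _count_extreme(null, r_obs, tail)
    return MantelResult(
        r_observed=r_obs,
        p_value=count / null.size,
        n_permutations=null.size,
        tail=tail,
        exact=True,
        seed=None,
    )


def _partial_r(r_ab: float, r_ac: float, r_bc: float) -> float:
    denom = (1.0 - r_ac**2) * (1.0 - r_bc**2)
    return (r_ab - r_ac * r_bc) / math.sqrt(denom)


def partial_mantel(
    A: PairwiseMatrix,
    B: PairwiseMatrix,
    C: PairwiseMatrix,
    n_perm: int = 10_000,
    tail: Tail = Tail.TWO_SIDED,
    seed: int | None = None,
) -> MantelResult:
    """Partial Mantel test of A × B controlling for C.

    The statistic is the first-order partial correlation
    ``r_AB·C = (r_AB − r_AC·r_BC) / sqrt((1 − r_AC²)(1 − r_BC²))`` over the
    off-diagonal vectors.  The null permutes ``A`` (rows and columns
    simultaneously) with ``B`` and ``C`` fixed and recomputes the partial
    statistic, so ``r_BC`` is constant across the null while ``r_AC``
    varies with the permutation.
    """
    _check_labels(A, B, C)
    tail = Tail(tail)
    n = A.n
    if n < 4:
        raise ValueError("partial Mantel test needs at least 4 groups")
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    va = _offdiag_checked(A, "first matrix")
    vb = _offdiag_checked(B, "second matrix")
    vc = _offdiag_checked(C, "control matrix")
    r_ab, r_ac, r_bc = _pearson(va, vb), _pearson(va, vc), _pearson(vb, vc)
    if min(1.0 - abs(r_ac), 1.0 - abs(r_bc)) < 1e-12:
        raise ValueError(
            "control matrix is perfectly collinear with a tested matrix; "
            "partial correlation undefined"
        )
    r_obs = _partial_r(r_ab, r_ac, r_bc)
    seed = _resolve_seed(seed)
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    null = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(n)
        vap = A.values[np.ix_(perm, perm)][iu]
        r_ab_p, r_ac_p = _pearson(vap, vb), _pearson(vap, vc)
        if 1.0 - abs(r_ac_p) < 1e-12:
            null[k] = np.inf  # degenerate permutation counts as extreme
        else:
            null[k] = _partial_r(r_ab_p, r_ac_p, r_bc)
    count = _count_extreme(null, r_obs, tail)
    return MantelResult(
        r_observed=r_obs,
        p_value=(1 + count) / (n_perm + 1),
        n_permutations=n_perm,
        tail=tail,
        exact=False,
        seed=seed,
    )
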