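"""Diversity-contrast screen for cultural selection.

Two trait systems scored over the same groups yield two paired sets of
intergroup distances.  If one system tracks neutral, geographically mediated
transmission, a second system whose distances are *significantly lower* is a
candidate for purifying (negative) selection — some bias suppresses
between-group variation — while significantly *higher* distances point to
diversifying (positive) selection.  The contrast is screened with three
conservative nonparametric tests on the paired off-diagonal vectors:

* a Wilcoxon signed-ranks test with a Monte Carlo sign-flip null,
* an exact-binomial sign test,
* a Mann-Whitney U test with a Monte Carlo reassignment null.

The distance pairs share groups and are therefore not independent; the
battery is a heuristic screen, not proof of selection, and every run logs
that caveat.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .matrix_tests import _resolve_seed
from .trait_matrix import PairwiseMatrix, Polarity

__all__ = [
    "RankMethod",
    "SelectionCall",
    "DecisionRule",
    "RankTestResult",
    "SelectionVerdict",
    "wilcoxon_signed_mc",
    "sign_test",
    "mann_whitney_mc",
    "diversity_selection_test",
]

logger = logging.getLogger(__name__)

_EPS = 1e-12


class RankMethod(str, enum.Enum):
    WILCOXON_SIGNED_MC = "wilcoxon_signed_mc"
    SIGN_EXACT = "sign_exact"
    MANN_WHITNEY_MC = "mann_whitney_mc"


class SelectionCall(str, enum.Enum):
    PURIFYING = "purifying"
    DIVERSIFYING = "diversifying"
    NOT_DETECTED = "not_detected"


class DecisionRule(str, enum.Enum):
    """How many of the three tests must be significant to make a call."""

    ALL = "all"
    MAJORITY = "majority"
    ANY = "any"


@dataclass(frozen=True)
class RankTestResult:
    method: RankMethod
    statistic: float
    p_value: float
    n_randomizations: int  # 0 for exact tests
    seed: int | None
    n_pairs_used: int

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p-value outside (0, 1]")
        if self.statistic < 0:
            raise ValueError("rank statistic must be non-negative")


@dataclass(frozen=True)
class SelectionVerdict:
    tests: tuple[RankTestResult, ...]
    focal_mean: float
    focal_median: float
    reference_mean: float
    reference_median: float
    call: SelectionCall
    alpha: float


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired samples must be 1-d and equal length")
    return x, y


def wilcoxon_signed_mc(
    x, y, n_rand: int = 99_999, seed: int | None = None
) -> RankTestResult:
    """Wilcoxon signed-ranks test with a Monte Carlo sign-flip null.

    W is the sum of ranks of |x−y| over the positive differences (zero
    differences dropped, tied magnitudes midranked).  The null randomly
    flips the sign of each difference; the two-sided p compares |W − S/2|,
    S the total rank sum, against ``n_rand`` flips with the add-one rule.
    """
    x, y = _paired(x, y)
    if x.size < 2:
        raise ValueError("need at least two pairs")
    d = x - y
    d = d[d != 0]
    m = d.size
    if m == 0:
        warnings.warn("all paired differences are zero; test degenerate", stacklevel=2)
        return RankTestResult(
            RankMethod.WILCOXON_SIGNED_MC, 0.0, 1.0, 0, None, 0
        )
    ranks = stats.rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    center = ranks.sum() / 2.0
    seed = _resolve_seed(seed)
    rng = np.random.default_rng(seed)
    count = 0
    remaining = n_rand
    while remaining > 0:  # chunked so 99 999 flips stay within modest memory
        chunk = min(remaining, 20_000)
        w_null = (ranks * (rng.random((chunk, m)) < 0.5)).sum(axis=1)
        count += int(np.sum(np.abs(w_null - center) >= abs(w_obs - center) - _EPS))
        remaining -= chunk
    return RankTestResult(
        RankMethod.WILCOXON_SIGNED_MC,
        w_obs,
        (1 + count) / (n_rand + 1),
        n_rand,
        seed,
        m,
    )


def sign_test(x, y) -> RankTestResult:
    """Exact two-sided sign test for paired observations.

    The statistic is the count of pairs with x > y among the m untied
    pairs; p doubles the smaller Binomial(m, 1/2) tail and caps at 1.
    """
    x, y = _paired(x, y)
    if x.size < 1:
        raise ValueError("need at least one pair")
    d = x - y
    d = d[d != 0]
    m = d.size
    if m == 0:
        warnings.warn("all pairs tied; sign test degenerate", stacklevel=2)
        return RankTestResult(RankMethod.SIGN_EXACT, 0.0, 1.0, 0, None, 0)
    k = int(np.sum(d > 0))
    lower = stats.binom.cdf(k, m, 0.5)
    upper = stats.binom.sf(k - 1, m, 0.5)
    p = min(1.0, 2.0 * min(lower, upper))
    return RankTestResult(RankMethod.SIGN_EXACT, float(k), float(p), 0, None, m)


def mann_whitney_mc(
    x, y, n_rand: int = 10_000, seed: int | None = None
) -> RankTestResult:
    """Mann-Whitney U test with a Monte Carlo reassignment null.

    The reported statistic is min(U_x, U_y) from midrank-based rank sums,
    so small values are extreme in either direction and the reassignment
    p-value is inherently two-sided.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_x = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)
    u_obs = min(u_x, nx * ny - u_x)
    seed = _resolve_seed(seed)
    rng = np.random.default_rng(seed)
    count = 0
    remaining = n_rand
    while remaining > 0:
        chunk = min(remaining, 20_000)
        # argsort of uniforms = a uniform random assignment of pooled ranks
        pick = np.argsort(rng.random((chunk, nx + ny)), axis=1)[:, :nx]
        u_null_x = ranks[pick].sum(axis=1) - nx * (nx + 1) / 2.0
        u_null = np.minimum(u_null_x, nx * ny - u_null_x)
        count += int(np.sum(u_null <= u_obs + _EPS))
        remaining -= chunk
    return RankTestResult(
        RankMethod.MANN_WHITNEY_MC,
        float(u_obs),
        (1 + count) / (n_rand + 1),
        n_rand,
        seed,
        nx + ny,
    )


def diversity_selection_test(
    focal: PairwiseMatrix,
    reference: PairwiseMatrix,
    alpha: float = 0.05,
    n_rand_wilcoxon: int = 99_999,
    n_rand_mannwhitney: int = 10_000,
    seed: int | None = None,
    rule: DecisionRule = DecisionRule.ALL,
) -> SelectionVerdict:
    """Run the three-test battery and classify the direction of selection.

    Both matrices must be DISTANCE polarity over identical labels.  The
    verdict is PURIFYING when the required tests (default: all three) are
    significant at ``alpha`` and the focal mean distance is below the
    reference mean; DIVERSIFYING when significant with the focal mean
    above; NOT_DETECTED otherwise.
    """
    if focal.polarity is not Polarity.DISTANCE or reference.polarity is not Polarity.DISTANCE:
        raise ValueError(
            "diversity contrast requires DISTANCE polarity for both matrices "
            "(convert similarities explicitly with .as_distance())"
        )
    if focal.labels != reference.labels:
        raise ValueError("focal and reference matrices must share label order")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    rule = DecisionRule(rule)
    logger.info(
        "diversity contrast: paired intergroup distances are not independent "
        "(shared groups); treat this battery as a heuristic screen, not "
        "standalone evidence of selection"
    )
    x = focal.offdiag()
    y = reference.offdiag()
    seed = _resolve_seed(seed)
    ss = np.random.SeedSequence(seed).spawn(2)
    tests = (
        wilcoxon_signed_mc(
            x, y, n_rand=n_rand_wilcoxon, seed=int(ss[0].generate_state(1)[0] % 2**31)
        ),
        sign_test(x, y),
        mann_whitney_mc(
            x, y, n_rand=n_rand_mannwhitney, seed=int(ss[1].generate_state(1)[0] % 2**31)
        ),
    )
    n_sig = sum(t.p_value < alpha for t in tests)
    required = {DecisionRule.ALL: len(tests), DecisionRule.MAJORITY: 2, DecisionRule.ANY: 1}[rule]
    focal_mean, reference_mean = float(x.mean()), float(y.mean())
    if n_sig >= required and focal_mean != reference_mean:
        call = (
            SelectionCall.PURIFYING
            if focal_mean < reference_mean
            else SelectionCall.DIVERSIFYING
        )
    else:
        call = SelectionCall.NOT_DETECTED
    return SelectionVerdict(
        tests=tests,
        focal_mean=focal_mean,
        focal_median=float(np.median(x)),
        reference_mean=reference_mean,
        reference_median=float(np.median(y)),
        call=call,
        alpha=alpha,
    )
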