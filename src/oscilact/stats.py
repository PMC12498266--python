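"""Group statistics for oscillation-presence fractions and repeated measures.

The centrepiece is a from-scratch two-sided Fisher exact test on 2x2
contingency tables, computed in exact integer arithmetic by enumerating all
tables with the observed margins under the hypergeometric null. The
two-sided rule is the classical Fisher convention: sum the probabilities of
all tables no more probable than the observed one. With the presence counts
1/7 vs 11/11, 7/13 vs 11/11 and 7/13 vs 0/11 this rule yields p = 0.0004,
0.016 and 0.006 at display precision.

Repeated-measures designs use the Friedman rank test (ties share mean
ranks, tie-corrected statistic) followed by Conover's pairwise post-hoc
comparisons on treatment rank sums; conventional two-sample tests are
dispatched to scipy.stats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import comb

import numpy as np
from scipy import stats as sps

from .errors import InputError, ParameterError
from .traces import ContingencyTable2x2

__all__ = [
    "FisherResult",
    "FriedmanConoverResult",
    "StatTestResult",
    "fisher_exact_two_sided",
    "percent_reduction",
    "friedman_with_durbin_conover",
    "standard_tests",
]

FISHER_CONVENTION = "two-sided: sum of hypergeometric probabilities <= P(observed)"


@dataclass(frozen=True)
class FisherResult:
    p_value: float
    degenerate: bool = False  # a zero margin: the test carries no information
    convention: str = FISHER_CONVENTION


def fisher_exact_two_sided(table: ContingencyTable2x2) -> FisherResult:
    """Exact two-sided Fisher test on a 2x2 table.

    With margins fixed, the count ``a`` in cell (group1, positive) follows a
    hypergeometric law. All admissible tables are enumerated; the p-value is
    the exact rational sum of P(a') over tables with P(a') <= P(a_observed),
    evaluated with integer binomial coefficients (no floating-point
    comparisons). A zero margin gives p = 1 with ``degenerate=True``.
    """
    a = table.group1_positive
    r1 = table.group1_positive + table.group1_negative
    r2 = table.group2_positive + table.group2_negative
    c1 = table.group1_positive + table.group2_positive
    n = table.total
    if table.has_zero_margin():
        return FisherResult(p_value=1.0, degenerate=True)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {k: comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)}
    observed = weights[a]
    numerator = sum(w for w in weights.values() if w <= observed)
    p = Fraction(numerator, comb(n, c1))
    return FisherResult(p_value=float(p))


def percent_reduction(f1: float, f2: float) -> float:
    """Percent reduction of fraction ``f1`` relative to reference ``f2``:
    100 * (1 - f1/f2). Unrounded; report formatters round to integer."""
    if f2 == 0:
        raise ParameterError("reference fraction f2 must be > 0")
    return 100.0 * (1.0 - f1 / f2)


@dataclass
class FriedmanConoverResult:
    statistic: float  # tie-corrected Friedman chi-square
    df: int
    p_value: float
    rank_sums: np.ndarray  # per-condition rank sums R_j
    pairwise_p: np.ndarray  # k x k symmetric, unit diagonal
    pairwise_t: np.ndarray  # Conover t statistics (signed, antisymmetric)
    holm_adjusted: bool = False
    params: dict = field(default_factory=dict)


def friedman_with_durbin_conover(
    blocks: np.ndarray, holm_adjust: bool = False
) -> FriedmanConoverResult:
    """Friedman test with Conover (Durbin-Conover) pairwise post-hoc.

    ``blocks`` is an (n subjects x k conditions) matrix with no missing
    cells. Within-subject ranks share mean ranks on ties. The reported
    statistic is the tie-corrected Friedman chi-square

        T1 = (k-1) * sum_j (R_j - n(k+1)/2)^2 / (A - C),

    with A the sum of squared ranks and C = n k (k+1)^2 / 4, referred to a
    chi-square with k-1 df. Pairwise comparisons use Conover's

        t_ij = (R_i - R_j) / sqrt( 2n (A - C) (1 - T1/(n(k-1))) / ((n-1)(k-1)) )

    on Student's t with (n-1)(k-1) df, two-sided and unadjusted by default
    (``holm_adjust=True`` applies a Holm correction).
    """
    blocks = np.asarray(blocks, dtype=float)
    if blocks.ndim != 2:
        raise InputError("blocks must be an (n subjects x k conditions) matrix")
    n, k = blocks.shape
    if n < 2 or k < 2:
        raise InputError("need at least 2 subjects and 2 conditions")
    if not np.all(np.isfinite(blocks)):
        raise InputError("missing or non-finite cells are not supported (no imputation)")

    ranks = np.apply_along_axis(sps.rankdata, 1, blocks)
    rank_sums = ranks.sum(axis=0)
    a = float(np.sum(ranks**2))
    c = n * k * (k + 1) ** 2 / 4.0
    denom = a - c

    if denom <= 0:  # every subject ranks all conditions identically (all ties)
        statistic, p_value = 0.0, 1.0
        pairwise_t = np.zeros((k, k))
        pairwise_p = np.ones((k, k))
    else:
        statistic = (k - 1) * float(np.sum((rank_sums - n * (k + 1) / 2.0) ** 2)) / denom
        df = k - 1
        p_value = float(sps.chi2.sf(statistic, df))
        df_t = (n - 1) * (k - 1)
        scale = 1.0 - statistic / (n * (k - 1))
        se2 = 2.0 * n * denom * max(scale, 0.0) / df_t
        diff = rank_sums[:, None] - rank_sums[None, :]
        if se2 > 0:
            pairwise_t = diff / np.sqrt(se2)
            pairwise_p = 2.0 * sps.t.sf(np.abs(pairwise_t), df_t)
        else:  # Friedman statistic at its maximum: rank sums separate perfectly
            pairwise_t = np.where(diff == 0, 0.0, np.inf * np.sign(diff))
            pairwise_p = np.where(diff == 0, 1.0, 0.0)
        np.fill_diagonal(pairwise_p, 1.0)

    holm = bool(holm_adjust)
    if holm and k > 1:
        iu = np.triu_indices(k, 1)
        raw = pairwise_p[iu]
        order = np.argsort(raw)
        m = raw.size
        adj = np.empty(m)
        running = 0.0
        for rank_i, idx in enumerate(order):
            running = max(running, (m - rank_i) * raw[idx])
            adj[idx] = min(running, 1.0)
        pairwise_p = pairwise_p.copy()
        pairwise_p[iu] = adj
        pairwise_p[(iu[1], iu[0])] = adj

    return FriedmanConoverResult(
        statistic=float(statistic),
        df=k - 1,
        p_value=float(p_value),
        rank_sums=rank_sums,
        pairwise_p=pairwise_p,
        pairwise_t=pairwise_t if denom > 0 else np.zeros((k, k)),
        holm_adjusted=holm,
        params={"n": n, "k": k, "tie_corrected": True},
    )


@dataclass(frozen=True)
class StatTestResult:
    name: str
    statistic: float
    p_value: float


_DESIGNS = ("unpaired_t", "mann_whitney", "paired_t", "wilcoxon", "shapiro_wilk")


def standard_tests(
    sample_a: np.ndarray, sample_b: np.ndarray | None, design: str
) -> StatTestResult:
    """Conventional two-sided tests, dispatched to scipy.stats.

    ``design`` is one of unpaired_t, mann_whitney, paired_t, wilcoxon (all
    two-sample; paired designs require equal lengths) or shapiro_wilk
    (one-sample normality; ``sample_b`` ignored).
    """
    if design not in _DESIGNS:
        raise ParameterError(f"unknown design {design!r}; choose from {_DESIGNS}")
    a = np.asarray(sample_a, dtype=float)
    if a.size < 3:
        raise InputError("sample sizes must be >= 3")

    if design == "shapiro_wilk":
        res = sps.shapiro(a)
        return StatTestResult("shapiro_wilk", float(res.statistic), float(res.pvalue))

    b = np.asarray(sample_b, dtype=float)
    if b.size < 3:
        raise InputError("sample sizes must be >= 3")
    if design in ("paired_t", "wilcoxon") and a.size != b.size:
        raise InputError(f"paired design requires equal lengths, got {a.size} and {b.size}")

    if design == "unpaired_t":
        res = sps.ttest_ind(a, b)
    elif design == "mann_whitney":
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
    elif design == "paired_t":
        if np.allclose(a, b):  # zero-variance differences: no evidence of a shift
            return StatTestResult("paired_t", 0.0, 1.0)
        res = sps.ttest_rel(a, b)
    else:  # wilcoxon
        if np.allclose(a, b):
            return StatTestResult("wilcoxon", 0.0, 1.0)
        res = sps.wilcoxon(a, b)
    return StatTestResult(design, float(res.statistic), float(res.pvalue))
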