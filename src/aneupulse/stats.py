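"""Exact small-sample statistics for 2x2 tables and group comparisons.

Every routine here targets the sparse-cell regime of a pilot cohort
(~10 examinations): exact combinatorics wherever enumeration is feasible,
conditional (margin-fixed) inference for odds ratios, and effect sizes
with confidence intervals rather than bare p-values.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.optimize import brentq
from scipy.stats import nchypergeom_fisher
from statsmodels.stats.proportion import confint_proportions_2indep

__all__ = [
    "ContingencyTable2x2",
    "EffectEstimate",
    "fisher_exact_two_sided",
    "conditional_or",
    "risk_difference",
    "hedges_g",
    "spearman_rho",
    "mann_whitney_u",
]

@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for exposure (rows: present/absent) vs event (columns: yes/no).

    Layout matches the cohort tables: ``a`` = exposed with event,
    ``b`` = exposed without, ``c`` = unexposed with event, ``d`` = unexposed
    without.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in counts):
            raise ValueError(f"counts must be non-negative integers, got {counts}")
        if sum(counts) < 1:
            raise ValueError("table is empty")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass(frozen=True)
class EffectEstimate:
    """A point estimate with a two-sided confidence interval.

    Unbounded sides are encoded as ``-inf``/``+inf``; a structurally
    infinite point estimate (empty off-diagonal cell) is ``+inf``.
    """

    point: float
    ci_low: float
    ci_high: float
    level: float
    method: str

    def __post_init__(self) -> None:
        if math.isfinite(self.point) and math.isfinite(self.ci_low) and math.isfinite(self.ci_high):
            if not (self.ci_low <= self.point + 1e-12 and self.point - 1e-12 <= self.ci_high):
                raise ValueError(
                    f"interval ({self.ci_low}, {self.ci_high}) does not contain point {self.point}"
                )


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value by the point-probability rule.

    Sums the hypergeometric probabilities of all tables with the observed
    margins that are no more probable than the observed one. Degenerate
    margins (an empty row or column) give p = 1 by convention.
    """
    t = table.as_array()
    if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
        return 1.0
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def conditional_or(table: ContingencyTable2x2, level: float = 0.95) -> EffectEstimate:
    """Conditional-MLE odds ratio with an exact (test-inversion) CI.

    The point estimate solves ``E_psi[A | margins] = a`` under the Fisher
    noncentral hypergeometric model; the CI inverts one-sided exact
    conditional tests at (1 - level)/2 per side (the construction used by
    R's ``fisher.test``). Tables where ``a`` sits at the boundary of its
    conditional support yield 0 or +inf with a one-sided interval.
    """
    M = table.n
    n1 = table.a + table.c  # column-1 total
    N1 = table.a + table.b  # row-1 total
    if n1 == 0 or n1 == M or N1 == 0 or N1 == M:
        raise ValueError("degenerate margins: odds ratio undefined")
    lo = max(0, n1 + N1 - M)
    hi = min(n1, N1)
    a = table.a
    alpha = (1.0 - level) / 2.0

    def mean_at(log_psi: float) -> float:
        return float(nchypergeom_fisher.mean(M, n1, N1, math.exp(log_psi)))

    # Point estimate.
    if a == hi:
        point = math.inf
    elif a == lo:
        point = 0.0
    else:
        point = math.exp(brentq(lambda lg: mean_at(lg) - a, -40.0, 40.0, xtol=1e-12))

    # Lower bound: psi with P_psi(A >= a) = alpha (0 if a at support minimum).
    if a == lo:
        ci_low = 0.0
    else:
        def upper_tail(lg: float) -> float:
            return float(nchypergeom_fisher.sf(a - 1, M, n1, N1, math.exp(lg))) - alpha

        ci_low = math.exp(brentq(upper_tail, -40.0, 40.0, xtol=1e-12))

    # Upper bound: psi with P_psi(A <= a) = alpha (inf if a at support maximum).
    if a == hi:
        ci_high = math.inf
    else:
        def lower_tail(lg: float) -> float:
            return float(nchypergeom_fisher.cdf(a, M, n1, N1, math.exp(lg))) - alpha

        ci_high = math.exp(brentq(lower_tail, -40.0, 40.0, xtol=1e-12))

    return EffectEstimate(point, ci_low, ci_high, level, "conditional MLE / exact inversion")


def risk_difference(table: ContingencyTable2x2, level: float = 0.95) -> EffectEstimate:
    """Risk difference p1 - p2 with the Newcombe hybrid-score CI.

    The Newcombe (Wilson-score based) interval stays inside [-1, 1] and
    behaves sensibly with zero cells, unlike the Wald interval.
    """
    n1 = table.a + table.b
    n2 = table.c + table.d
    if n1 == 0 or n2 == 0:
        raise ValueError("both row totals must be >= 1")
    point = table.a / n1 - table.c / n2
    lowhigh = confint_proportions_2indep(
        table.a, n1, table.c, n2, method="newcomb", compare="diff", alpha=1.0 - level
    )
    return EffectEstimate(point, float(lowhigh[0]), float(lowhigh[1]), level, "Newcombe hybrid score")


def hedges_g(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int, level: float = 0.95
) -> EffectEstimate:
    """Bias-corrected standardized mean difference (Hedges' g) with normal CI.

    g = J * (m1 - m2) / s_pooled with the small-sample correction
    J = 1 - 3 / (4(n1 + n2 - 2) - 1); the CI uses the standard
    large-sample variance of the standardized difference.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    df = n1 + n2 - 2
    sp = math.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df)
    if sp == 0:
        raise ValueError("pooled SD is zero: effect size undefined")
    d = (m1 - m2) / sp
    J = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = J * d
    se = J * math.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2.0 * (n1 + n2)))
    z = sps.norm.ppf(0.5 + level / 2.0)
    return EffectEstimate(g, g - z * se, g + z * se, level, "Hedges g (normal CI)")


def spearman_rho(x, y, exact_max_n: int = 9) -> dict:
    """Spearman rank correlation with average ranks for ties.

    For n <= ``exact_max_n`` the two-sided p-value is exact, from full
    enumeration of all n! permutations of one rank vector (tie-aware);
    above that the usual t-approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length 1-D vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"rho": math.nan, "p": math.nan, "status": "undefined: constant input"}
    n = len(x)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        # Null distribution: correlation of rx against every permutation of ry.
        perms = np.array(list(itertools.permutations(ry)))
        rx_c = rx - rx.mean()
        p_c = perms - ry.mean()
        num = p_c @ rx_c
        denom = math.sqrt(float(rx_c @ rx_c)) * np.sqrt(np.einsum("ij,ij->i", p_c, p_c))
        rhos = num / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        method = "exact permutation"
    else:
        t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho**2)) if abs(rho) < 1 else math.inf
        p = float(2.0 * sps.t.sf(abs(t), n - 2)) if math.isfinite(t) else 0.0
        method = "t approximation"
    return {"rho": rho, "p": min(p, 1.0), "status": "ok", "method": method}


def mann_whitney_u(x, y, exact_max_total: int = 12) -> dict:
    """Two-sided Mann-Whitney U test.

    Exact tie-aware p by enumeration of all C(n1+n2, n1) group assignments
    when the combined sample size is <= ``exact_max_total``; otherwise the
    normal approximation with tie correction (no continuity correction is
    applied in the exact branch, which IS the reference distribution).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    mean_u = n1 * n2 / 2.0
    if n1 + n2 <= exact_max_total:
        idx = np.arange(n1 + n2)
        stat_obs = abs(u1 - mean_u)
        count = 0
        total = 0
        for comb in itertools.combinations(idx, n1):
            u = float(ranks[list(comb)].sum() - n1 * (n1 + 1) / 2.0)
            if abs(u - mean_u) >= stat_obs - 1e-9:
                count += 1
            total += 1
        p = count / total
        method = "exact enumeration"
    else:
        p = float(sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")[1])
        method = "normal approximation (tie-corrected)"
    return {"U": u1, "p": min(p, 1.0), "method": method}
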