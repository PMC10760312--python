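"""Exact inference on 2x2 tables.

Three quantities, all computed on the distribution of the top-left cell
conditional on both margins:

* the two-sided Fisher exact p-value (probability-ordering rule over the
  central hypergeometric support);
* the conditional maximum-likelihood odds ratio, maximizing the Fisher
  noncentral hypergeometric likelihood in the odds parameter psi;
* exact confidence bounds by tail inversion, i.e. the psi at which the
  one-sided tail probability of the observed cell equals (1-gamma)/2.

This construction reproduces the zero-cell behaviour of R's
``fisher.test`` (odds ratio +inf with a finite exact lower bound), which
is how tables with carriers only in the case group are reported. All
support weights are computed in log space, so margins up to ~1e5 are safe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln, logsumexp

# relative tolerance on the probability-ordering comparison, matching the
# convention of widely used implementations
P_ORDER_RTOL = 1e-7

DEFAULT_CONFIDENCE = 0.90


@dataclass(frozen=True)
class Table2x2:
    """Counts (a, b | c, d): exposed/unexposed cases over exposed/unexposed
    comparison subjects."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")

    @property
    def row1(self) -> int:
        return self.a + self.b

    @property
    def row2(self) -> int:
        return self.c + self.d

    @property
    def col1(self) -> int:
        return self.a + self.c

    def support(self) -> tuple[int, int]:
        """Range (inclusive) of the top-left cell given both margins."""
        lo = max(0, self.col1 - self.row2)
        hi = min(self.row1, self.col1)
        return lo, hi

    def transpose(self) -> "Table2x2":
        return Table2x2(self.a, self.c, self.b, self.d)

    def swap_rows(self) -> "Table2x2":
        return Table2x2(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class AssociationResult:
    """Exact-test summary for one 2x2 table."""

    table: Table2x2
    p_two_sided: float
    or_cmle: float
    ci_low: float
    ci_high: float
    confidence: float = DEFAULT_CONFIDENCE
    degenerate: bool = False


def _log_binom(n: int, k) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _support_logweights(t: Table2x2) -> tuple[np.ndarray, np.ndarray]:
    """Unnormalized log hypergeometric weights over the conditional support."""
    lo, hi = t.support()
    ks = np.arange(lo, hi + 1)
    lw = _log_binom(t.row1, ks) + _log_binom(t.row2, t.col1 - ks)
    return ks, lw


def fisher_two_sided(t: Table2x2) -> float:
    """Two-sided Fisher exact p by probability ordering.

    Sums central-hypergeometric probabilities over all tables whose
    probability does not exceed the observed one (relative tolerance
    :data:`P_ORDER_RTOL` on the comparison).
    """
    ks, lw = _support_logweights(t)
    if len(ks) == 1:
        return 1.0
    log_probs = lw - logsumexp(lw)
    log_obs = log_probs[ks == t.a][0]
    # p_k <= p_obs * (1 + rtol)
    include = log_probs <= log_obs + math.log1p(P_ORDER_RTOL)
    return float(min(1.0, math.exp(logsumexp(log_probs[include]))))


def _conditional_mean(ks: np.ndarray, lw: np.ndarray, log_psi: float) -> float:
    logw = lw + ks * log_psi
    logz = logsumexp(logw)
    return float(np.sum(ks * np.exp(logw - logz)))


def conditional_mle_or(t: Table2x2) -> tuple[float, bool]:
    """Conditional-MLE odds ratio; returns (psi_hat, degenerate_flag).

    The conditional score equation E_psi[X] = a is solved for log psi by
    bracketed root-finding; observed cells at the support boundary give the
    boundary estimates 0 and +inf.
    """
    lo, hi = t.support()
    if lo == hi:
        return 1.0, True
    if t.a == lo:
        return 0.0, False
    if t.a == hi:
        return math.inf, False
    ks, lw = _support_logweights(t)

    def score(log_psi: float) -> float:
        return _conditional_mean(ks, lw, log_psi) - t.a

    left, right = -1.0, 1.0
    while score(left) > 0:
        left *= 2
    while score(right) < 0:
        right *= 2
    return float(math.exp(brentq(score, left, right, xtol=1e-12))), False


def _upper_tail(ks, lw, log_psi, a) -> float:
    """P_psi(X >= a) on the conditional support."""
    logw = lw + ks * log_psi
    logz = logsumexp(logw)
    return float(math.exp(logsumexp(logw[ks >= a]) - logz))


def _lower_tail(ks, lw, log_psi, a) -> float:
    logw = lw + ks * log_psi
    logz = logsumexp(logw)
    return float(math.exp(logsumexp(logw[ks <= a]) - logz))


def exact_ci(t: Table2x2, confidence: float = DEFAULT_CONFIDENCE) -> tuple[float, float]:
    """Exact tail-inversion confidence bounds for the conditional odds ratio.

    The lower bound solves P_psi(X >= a) = alpha/2 and the upper bound
    P_psi(X <= a) = alpha/2, alpha = 1 - confidence. Cells at the support
    boundary yield 0 / +inf on the corresponding side.
    """
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0,1)")
    alpha = 1.0 - confidence
    lo, hi = t.support()
    if lo == hi:
        return 0.0, math.inf
    ks, lw = _support_logweights(t)

    def solve(tail, target) -> float:
        def f(log_psi: float) -> float:
            return tail(ks, lw, log_psi, t.a) - target

        left, right = -1.0, 1.0
        while f(left) * f(right) > 0 and (right - left) < 200:
            left *= 2
            right *= 2
        return float(math.exp(brentq(f, left, right, xtol=1e-10, rtol=1e-12)))

    # upper tail P(X >= a) increases in psi -> lower bound root
    ci_low = 0.0 if t.a == lo else solve(_upper_tail, alpha / 2)
    ci_high = math.inf if t.a == hi else solve(_lower_tail, alpha / 2)
    return ci_low, ci_high


def associate(t: Table2x2, confidence: float = DEFAULT_CONFIDENCE) -> AssociationResult:
    """Full exact summary: two-sided p, conditional-MLE OR, exact CI."""
    or_cmle, degenerate = conditional_mle_or(t)
    if degenerate:
        return AssociationResult(t, 1.0, 1.0, 0.0, math.inf, confidence, True)
    ci_low, ci_high = exact_ci(t, confidence)
    return AssociationResult(
        t, fisher_two_sided(t), or_cmle, ci_low, ci_high, confidence, False
    )
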