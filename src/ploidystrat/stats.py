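"""Exact tail probabilities and multiple-testing helpers.

Tail probabilities are accumulated in log space (``logsumexp`` over log
probability masses), so a result remains meaningful far below the smallest
positive double: the linear-scale ``p`` may underflow to ``0.0`` but the
``log10_p`` field stays finite and accurate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special
from scipy import stats as sps

from .errors import ValidationError

_LN10 = np.log(10.0)


@dataclass(frozen=True)
class TailProbability:
    """A one-sided tail probability with its base-10 logarithm."""

    p: float
    log10_p: float

    def __float__(self) -> float:  # pragma: no cover - convenience
        return self.p


def _from_log(log_p: float) -> TailProbability:
    log_p = min(float(log_p), 0.0)
    return TailProbability(p=float(np.exp(log_p)), log10_p=log_p / _LN10)


def binom_tail(k: int, n: int, p0: float, alternative: str = "greater") -> TailProbability:
    """Exact binomial tail ``P(X >= k)`` (or ``<=``) for ``X ~ Binomial(n, p0)``.

    Parameters
    ----------
    k, n : int
        Observed count and number of trials, ``0 <= k <= n``.
    p0 : float
        Null success probability in ``[0, 1]``.
    alternative : {"greater", "less"}
        Tail direction.
    """
    if not 0 <= k <= n:
        raise ValidationError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 <= p0 <= 1.0:
        raise ValidationError(f"p0 must be in [0, 1], got {p0}")
    if alternative not in ("greater", "less"):
        raise ValidationError(f"alternative must be 'greater' or 'less', got {alternative!r}")

    if alternative == "greater":
        if k == 0:
            return TailProbability(1.0, 0.0)
        ks = np.arange(k, n + 1)
    else:
        if k == n:
            return TailProbability(1.0, 0.0)
        ks = np.arange(0, k + 1)

    with np.errstate(divide="ignore"):
        log_pmf = sps.binom.logpmf(ks, n, p0)
    finite = log_pmf > -np.inf
    if not finite.any():
        # Impossible observation under the null (e.g. k > 0 with p0 = 0).
        return TailProbability(0.0, -np.inf)
    return _from_log(special.logsumexp(log_pmf[finite]))


def hypergeom_tail(k: int, n: int, K: int, N: int, alternative: str = "greater") -> TailProbability:
    """Exact hypergeometric tail for ``k`` marked among ``n`` drawn from ``N`` with ``K`` marked.

    ``alternative="greater"`` gives the over-representation tail ``P(X >= k)``.
    """
    if not 0 <= K <= N:
        raise ValidationError(f"need 0 <= K <= N, got K={K}, N={N}")
    if not 0 <= n <= N:
        raise ValidationError(f"need 0 <= n <= N, got n={n}, N={N}")
    if not 0 <= k <= min(n, K):
        raise ValidationError(f"need 0 <= k <= min(n, K), got k={k}, n={n}, K={K}")
    if alternative not in ("greater", "less"):
        raise ValidationError(f"alternative must be 'greater' or 'less', got {alternative!r}")

    lo = max(0, n + K - N)
    hi = min(n, K)
    if alternative == "greater":
        if k <= lo:
            return TailProbability(1.0, 0.0)
        ks = np.arange(k, hi + 1)
    else:
        if k >= hi:
            return TailProbability(1.0, 0.0)
        ks = np.arange(lo, k + 1)

    with np.errstate(divide="ignore"):
        log_pmf = sps.hypergeom.logpmf(ks, N, K, n)
    return _from_log(special.logsumexp(log_pmf))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, mapped back to input order.

    ``q_(i) = min_{j >= i} p_(j) * m / j`` over the p-values sorted ascending,
    capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return np.maximum(q, p)  # guard the q >= p invariant against rounding
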