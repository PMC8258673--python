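"""Small shared statistical helpers."""

from __future__ import annotations

from scipy.stats import binom

__all__ = ["binomial_two_sided"]


def binomial_two_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial test p-value (doubled smaller tail, capped at 1).

    At p0 = 0.5 the binomial is symmetric, so doubling the smaller tail
    coincides with the minimum-likelihood two-sided construction.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 <= k <= n):
        raise ValueError("k must lie in [0, n]")
    lower = float(binom.cdf(k, n, p0))
    upper = float(binom.sf(k - 1, n, p0))
    return min(1.0, 2.0 * min(lower, upper))
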