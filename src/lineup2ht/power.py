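"""Chi-square sensitivity and power analysis (Cohen's w, noncentral chi-square).

The asymptotic power of a chi-square test with ``df`` degrees of freedom,
significance level alpha and effect size w on N observations is

    power = P( X > q ),   X ~ noncentral chi-square(df, lambda = N * w^2),

with q the (1 - alpha) quantile of the central chi-square at ``df``.  These
are generic categorical-data computations (the G*Power conventions), not
model-specific ones: for the lineup design N counts *decisions*, i.e.
participants times lineups per participant.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, stats

__all__ = [
    "cohens_w",
    "power_noncentral_chi2",
    "minimal_detectable_w",
    "required_noncentrality",
]

#: Upper bracket for effect-size root finding; categorical effects beyond
#: w = 3 do not arise in practice.
W_MAX = 3.0


def cohens_w(p_null, p_alt) -> float:
    """Cohen's effect size w = sqrt( Σ (p_alt - p_null)² / p_null ).

    Both arguments are probability vectors over the same cells; ``p_null``
    must be strictly positive.
    """
    p0 = np.asarray(p_null, dtype=float)
    p1 = np.asarray(p_alt, dtype=float)
    if p0.shape != p1.shape or p0.ndim != 1:
        raise ValueError(f"mismatched probability vectors: {p0.shape} vs {p1.shape}")
    if (p0 <= 0).any():
        raise ValueError("p_null must be strictly positive in every cell")
    for name, p in (("p_null", p0), ("p_alt", p1)):
        if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
            raise ValueError(f"{name} is not a probability vector (sum {p.sum()})")
    return float(np.sqrt(((p1 - p0) ** 2 / p0).sum()))


def _validate(n_observations: int, df: int, alpha: float) -> None:
    if n_observations < 1:
        raise ValueError(f"n_observations must be positive, got {n_observations}")
    if df < 1:
        raise ValueError(f"df must be a positive integer, got {df}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")


def power_noncentral_chi2(
    w: float, n_observations: int, df: int, alpha: float
) -> float:
    """Power of the chi-square test at effect size w and N observations."""
    _validate(n_observations, df, alpha)
    if w < 0:
        raise ValueError(f"effect size w must be nonnegative, got {w}")
    crit = stats.chi2.ppf(1.0 - alpha, df)
    lam = n_observations * w**2
    if lam == 0:
        return float(alpha)
    return float(stats.ncx2.sf(crit, df, lam))


def required_noncentrality(df: int, alpha: float, power: float) -> float:
    """Noncentrality λ* at which the test first reaches the requested power."""
    if not alpha < power < 1:
        raise ValueError(f"power must lie in ({alpha}, 1), got {power}")
    crit = stats.chi2.ppf(1.0 - alpha, df)

    def gap(lam: float) -> float:
        return stats.ncx2.sf(crit, df, lam) - power

    hi = 4.0
    while gap(hi) < 0:
        hi *= 2.0
        if hi > 1e7:
            raise RuntimeError("required noncentrality bracket exhausted")
    return float(optimize.brentq(gap, 0.0, hi, xtol=1e-10))


def minimal_detectable_w(
    n_observations: int, df: int, alpha: float, power: float
) -> float:
    """Smallest Cohen's w detectable with the requested power.

    Solves power_noncentral_chi2(w, N, df, alpha) = power for w; since the
    power is monotone in the noncentrality λ = N·w², this is
    sqrt(λ* / N) with λ* the required noncentrality, and the bisection on
    w in [0, 3] confirms it.
    """
    _validate(n_observations, df, alpha)
    if not alpha < power < 1:
        raise ValueError(f"power must lie in ({alpha}, 1), got {power}")

    def gap(w: float) -> float:
        return power_noncentral_chi2(w, n_observations, df, alpha) - power

    if gap(W_MAX) < 0:
        raise ValueError(
            f"power {power} is unattainable with N = {n_observations} even at "
            f"w = {W_MAX}"
        )
    return float(optimize.brentq(gap, 0.0, W_MAX, xtol=1e-8))
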