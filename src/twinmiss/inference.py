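"""Likelihood-ratio tests and profile-likelihood interval machinery."""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import chi2

# chi-square(1) 95% quantile: the -2LL rise defining a 95% profile interval
CHI2_1_95 = float(chi2.ppf(0.95, 1))


@dataclass(frozen=True)
class LRTResult:
    """A likelihood-ratio test: -2 * (LL_nested - LL_full) against chi2_df.

    ``statistic`` is clipped at zero (tiny negative values arise from
    optimiser noise); ``raw_statistic`` keeps the unclipped value.
    """

    statistic: float
    df: int
    p: float
    raw_statistic: float = None

    def __post_init__(self):
        if self.raw_statistic is None:
            object.__setattr__(self, "raw_statistic", self.statistic)


def lrt(loglik_full: float, loglik_nested: float, df: int) -> LRTResult:
    """LRT of a nested model against the model containing it."""
    if df < 1:
        raise ValueError("LRT needs at least one constrained parameter")
    raw = 2.0 * (loglik_full - loglik_nested)
    stat = max(0.0, raw)
    return LRTResult(statistic=stat, df=df, p=float(chi2.sf(stat, df)), raw_statistic=raw)


def profile_bound(
    objective,
    mle: float,
    loglik_max: float,
    lo: float,
    hi: float,
    side: str,
    cutoff: float = CHI2_1_95,
    tol: float = 1e-4,
) -> float:
    """One endpoint of a profile-likelihood interval by bisection.

    ``objective(x)`` is the constrained-refit log-likelihood with the
    parameter fixed at ``x``; the bound is where ``2*(loglik_max -
    objective(x))`` crosses ``cutoff``.  ``side`` is "lower" or "upper";
    ``lo``/``hi`` bracket the admissible parameter range.  If the deviance
    at the range limit stays below the cutoff, the limit itself is
    returned (a boundary-truncated interval).
    """
    def deviance(x):
        return 2.0 * (loglik_max - objective(x))

    limit = lo if side == "lower" else hi
    if deviance(limit) <= cutoff:
        return limit
    a, b = (limit, mle) if side == "lower" else (mle, limit)
    # invariant: deviance crosses the cutoff inside [a, b]
    while b - a > tol:
        m = 0.5 * (a + b)
        d = deviance(m)
        above = d > cutoff
        if side == "lower":
            if above:
                a = m
            else:
                b = m
        else:
            if above:
                b = m
            else:
                a = m
    return 0.5 * (a + b)
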