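"""Trial-level score transformation and small descriptive statistics.

Trial-availability counts are ceiling-clustered (most infants contribute
close to the maximum number of valid trials), i.e. left-skewed.  Prior to
twin modelling they are passed through a power transform — quadratic
first — until the absolute sample skewness falls below a target (default
0.3), then standardised to mean 0, sd 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.inter_rater import cohens_kappa as _sm_cohens_kappa

from .exceptions import DegenerateInputError, TransformFailureError

__all__ = ["TransformReport", "sample_skewness", "quadratic_transform", "cohen_kappa"]

# Quadratic power applied first; fallback grid tried in this order.
POWER_GRID = (2.0, 1.5, 2.5, 3.0)


@dataclass(frozen=True)
class TransformReport:
    """What the power transform did: power chosen, skewness before/after,
    and the mean/sd used for standardisation (sample sd, ddof=1)."""

    power_applied: float
    skew_before: float
    skew_after: float
    scale_mean: float
    scale_sd: float


def sample_skewness(values) -> float:
    """Adjusted Fisher-Pearson standardised third moment.

    Requires at least 3 finite values with non-zero variance.
    """
    x = np.asarray(values, float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise DegenerateInputError("skewness needs at least 3 finite values")
    if np.ptp(x) == 0:
        raise DegenerateInputError("skewness undefined for zero-variance input")
    sk = float(stats.skew(x, bias=False))
    if not np.isfinite(sk):
        raise DegenerateInputError("skewness numerically undefined (variance underflow)")
    return sk


def quadratic_transform(values, target_abs_skew: float = 0.3):
    """Power-transform non-negative scores to near-symmetry, then standardise.

    Applies ``y = x ** p`` with p = 2 first; if the absolute skewness still
    reaches ``target_abs_skew``, the remaining powers in :data:`POWER_GRID`
    are tried in order.  The accepted transform is standardised to mean 0,
    sd 1 (pooled across zygosities).  Returns ``(transformed, report)``.

    Raises :class:`TransformFailureError` (carrying the best-achieved
    power/skew) when no grid power reaches the target.
    """
    x = np.asarray(values, float)
    finite = x[np.isfinite(x)]
    if np.any(finite < 0):
        raise ValueError("power transform expects non-negative scores")
    skew_before = sample_skewness(finite)

    best = None
    for p in POWER_GRID:
        y = np.power(x, p)
        try:
            sk = sample_skewness(y[np.isfinite(y)])
        except DegenerateInputError:
            continue
        if best is None or abs(sk) < abs(best[1]):
            best = (p, sk)
        if abs(sk) < target_abs_skew:
            mean = float(np.nanmean(y))
            sd = float(np.nanstd(y, ddof=1))
            if sd == 0:
                raise DegenerateInputError("transformed values have zero variance")
            z = (y - mean) / sd
            report = TransformReport(
                power_applied=p,
                skew_before=skew_before,
                skew_after=sk,
                scale_mean=mean,
                scale_sd=sd,
            )
            return z, report
    raise TransformFailureError(
        f"no power in {POWER_GRID} achieved |skewness| < {target_abs_skew}; "
        f"best was p={best[0]} with skewness {best[1]:.4f}",
        best_power=best[0],
        best_skew=best[1],
    )


def cohen_kappa(table):
    """Cohen's kappa and observed agreement from a 2x2 agreement table.

    ``kappa = (p_o - p_e) / (1 - p_e)`` with chance agreement ``p_e`` from
    the marginal products.  Returns ``(kappa, observed_agreement)``.
    """
    t = np.asarray(table, float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or np.any(t != np.round(t)):
        raise ValueError("table cells must be non-negative integers")
    n = t.sum()
    if n == 0:
        raise DegenerateInputError("kappa undefined for an all-zero table")
    p_o = float(np.trace(t) / n)
    p_e = float((t.sum(axis=1) * t.sum(axis=0)).sum() / n**2)
    if abs(1.0 - p_e) < 1e-15:
        raise DegenerateInputError("kappa undefined when chance agreement is 1")
    kappa = float(_sm_cohens_kappa(t, return_results=False))
    return kappa, p_o
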