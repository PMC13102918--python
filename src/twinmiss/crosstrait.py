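"""Cross-trait correlations: phenotypic and cross-twin cross-trait.

Phenotypic correlations are Pearson correlations over individuals; because
twins within a pair are not independent, confidence intervals and p-values
come from a cluster bootstrap that resamples whole pairs.  Cross-twin
cross-trait correlations (one twin's trait X against the co-twin's trait
Y) use the double-entry estimator — both orderings stacked — which makes
the estimate symmetric in twin order.
"""

from __future__ import annotations

import numpy as np

from .data import TwinDataset
from .exceptions import SampleSizeError

__all__ = ["phenotypic_correlation", "cross_twin_cross_trait"]

DEFAULT_RESAMPLES = 2000


def _pearson(x, y):
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 3 or x[ok].std() == 0 or y[ok].std() == 0:
        return np.nan
    return float(np.corrcoef(x[ok], y[ok])[0, 1])


def _bootstrap(pairs_x, pairs_y, estimator, n_resamples, seed):
    """Cluster bootstrap over pairs; returns (ci, p) for the estimator."""
    n = len(pairs_x)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    stats = np.empty(n_resamples)
    for b in range(n_resamples):
        idx = rng.integers(0, n, n)
        stats[b] = estimator(pairs_x[idx], pairs_y[idx])
    stats = stats[~np.isnan(stats)]
    if stats.size == 0:
        return (np.nan, np.nan), np.nan
    lo, hi = np.percentile(stats, [2.5, 97.5])
    # two-sided bootstrap p for H0: r = 0 (add-one correction keeps p > 0)
    m = stats.size
    p = 2.0 * min(
        (np.sum(stats <= 0) + 1) / (m + 1), (np.sum(stats >= 0) + 1) / (m + 1)
    )
    return (float(lo), float(hi)), float(min(p, 1.0))


def phenotypic_correlation(
    data: TwinDataset,
    trait_x: str,
    trait_y: str,
    n_resamples: int = DEFAULT_RESAMPLES,
    seed: int = 0,
):
    """Within-person correlation between two traits across all twins.

    Returns ``(r, (ci_lo, ci_hi), p)``; CI and p by pair-cluster bootstrap.
    """
    px = data.pairs(trait_x)
    py = data.pairs(trait_y)
    x = np.concatenate([px[:, 0], px[:, 1]])
    y = np.concatenate([py[:, 0], py[:, 1]])
    n_overlap = int((~np.isnan(x) & ~np.isnan(y)).sum())
    if n_overlap < 10:
        raise SampleSizeError(
            f"only {n_overlap} individuals with both traits present (need >= 10)"
        )
    r = _pearson(x, y)

    def estimator(bx, by):
        return _pearson(
            np.concatenate([bx[:, 0], bx[:, 1]]), np.concatenate([by[:, 0], by[:, 1]])
        )

    ci, p = _bootstrap(px, py, estimator, n_resamples, seed)
    return r, ci, p


def _double_entry_r(px, py):
    """Correlation of twin-i X with co-twin Y, both orderings stacked."""
    x = np.concatenate([px[:, 0], px[:, 1]])
    y = np.concatenate([py[:, 1], py[:, 0]])
    return _pearson(x, y)


def cross_twin_cross_trait(
    data: TwinDataset,
    trait_x: str,
    trait_y: str,
    zygosity: str,
    n_resamples: int = DEFAULT_RESAMPLES,
    seed: int = 0,
):
    """Cross-twin cross-trait correlation for one zygosity group.

    Double-entry estimate of the correlation between one twin's
    ``trait_x`` and the co-twin's ``trait_y``; CI and p by pair-cluster
    bootstrap.  Returns ``(r, (ci_lo, ci_hi), p)``.
    """
    px = data.pairs(trait_x, zygosity)
    py = data.pairs(trait_y, zygosity)
    usable = (
        (~np.isnan(px[:, 0]) & ~np.isnan(py[:, 1]))
        | (~np.isnan(px[:, 1]) & ~np.isnan(py[:, 0]))
    )
    if usable.sum() < 10:
        raise SampleSizeError(
            f"{zygosity}: only {int(usable.sum())} pairs with a usable "
            "cross-twin trait combination (need >= 10)"
        )
    r = _double_entry_r(px, py)
    ci, p = _bootstrap(px, py, _double_entry_r, n_resamples, seed)
    return r, ci, p
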