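"""Saturated twin models: unconstrained moments/thresholds per zygosity.

The saturated model places no etiological structure on the data: for a
continuous trait it estimates a mean and variance per zygosity and twin
order plus a within-pair correlation per zygosity (10 parameters with both
zygosities present); for a binary trait it estimates a threshold per
zygosity and order plus a liability (tetrachoric) correlation per zygosity
(6 parameters).  Equality constraints across twin order and across
zygosity turn it into the nested models used to test the twin-design
assumptions, and fixing a correlation at zero gives the significance test
for a twin correlation.

Continuous fits use full-information maximum likelihood: pairs with one
absent member contribute a univariate normal term.  Threshold fits give
incomplete pairs a marginal Bernoulli term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import ndtr, ndtri

from ._bvn import cell_probabilities
from .data import DZ, MZ, TwinDataset
from .exceptions import OptimizationError, SampleSizeError
from .inference import lrt, profile_bound

__all__ = [
    "SaturatedTwinModel",
    "SaturatedContinuousResults",
    "SaturatedThresholdResults",
    "twin_correlation_zero_test",
    "assumption_tests",
    "CONTINUOUS_CONSTRAINTS",
    "THRESHOLD_CONSTRAINTS",
]

CONTINUOUS_CONSTRAINTS = (
    "means_equal_order",
    "vars_equal_order",
    "means_equal_zyg",
    "vars_equal_zyg",
    "r_equal_zyg",
)
THRESHOLD_CONSTRAINTS = (
    "thresholds_equal_order",
    "thresholds_equal_zyg",
    "r_equal_zyg",
)

_R_BOUND = 0.999  # declared bound for boundary (degenerate-table) solutions
_LOG2PI = np.log(2.0 * np.pi)
_PENALTY = 1e15  # finite stand-in for an inadmissible parameter point


def _merge_classes(labels, pairs_to_merge):
    """Union-find over labels; returns {label: class_index} with stable order."""
    parent = {lab: lab for lab in labels}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in pairs_to_merge:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    classes = {}
    mapping = {}
    for lab in labels:
        root = find(lab)
        if root not in classes:
            classes[root] = len(classes)
        mapping[lab] = classes[root]
    return mapping, len(classes)


@dataclass
class _GroupData:
    """Per-zygosity sufficient data for the continuous likelihood."""

    complete: np.ndarray  # (n, 2)
    single1: np.ndarray  # twin-1 observed, co-twin absent
    single2: np.ndarray


class SaturatedTwinModel:
    """Saturated model for one trait of a :class:`TwinDataset`.

    Parameters
    ----------
    data : TwinDataset
    trait : str
        Trait name; its declared kind selects the continuous or the
        threshold engine.
    constraints : iterable of str
        Equality constraints from :data:`CONTINUOUS_CONSTRAINTS` or
        :data:`THRESHOLD_CONSTRAINTS`.
    fix_r : dict, optional
        Map zygosity -> fixed within-pair correlation (e.g. ``{"MZ": 0.0}``
        for the zero-correlation significance test).
    """

    def __init__(self, data: TwinDataset, trait: str, constraints=(), fix_r=None):
        self.data = data
        self.trait = trait
        self.kind = data.trait_spec(trait).kind
        self.constraints = frozenset(constraints)
        self.fix_r = dict(fix_r or {})
        allowed = (
            set(CONTINUOUS_CONSTRAINTS)
            if self.kind == "continuous"
            else set(THRESHOLD_CONSTRAINTS)
        )
        unknown = self.constraints - allowed
        if unknown:
            raise ValueError(f"unknown constraint(s) for {self.kind} trait: {sorted(unknown)}")
        if "r_equal_zyg" in self.constraints and self.fix_r:
            raise ValueError("cannot combine r_equal_zyg with fix_r")

        self.zygosities = [z for z in (MZ, DZ) if data.n_pairs(z) > 0]
        if not self.zygosities:
            raise SampleSizeError("dataset contains no pairs")
        self._groups = {}
        for z in self.zygosities:
            arr = data.pairs(trait, z)
            obs1, obs2 = ~np.isnan(arr[:, 0]), ~np.isnan(arr[:, 1])
            self._groups[z] = _GroupData(
                complete=arr[obs1 & obs2],
                single1=arr[obs1 & ~obs2, 0],
                single2=arr[~obs1 & obs2, 1],
            )
        if self.kind == "continuous":
            for z in self.zygosities:
                if len(self._groups[z].complete) < 2:
                    raise SampleSizeError(
                        f"{z}: need at least 2 complete pairs for a saturated fit"
                    )

    # -- shared parameter bookkeeping ---------------------------------

    def _build_layout(self):
        """Index maps from (zygosity, order) cells / zygosity to free slots."""
        cells = [(z, j) for z in self.zygosities for j in (1, 2)]
        loc_merges, sca_merges = [], []
        eq_order = (
            "means_equal_order" if self.kind == "continuous" else "thresholds_equal_order"
        )
        eq_zyg = (
            "means_equal_zyg" if self.kind == "continuous" else "thresholds_equal_zyg"
        )
        if eq_order in self.constraints:
            loc_merges += [((z, 1), (z, 2)) for z in self.zygosities]
        if eq_zyg in self.constraints and len(self.zygosities) == 2:
            loc_merges += [((MZ, j), (DZ, j)) for j in (1, 2)]
        if "vars_equal_order" in self.constraints:
            sca_merges += [((z, 1), (z, 2)) for z in self.zygosities]
        if "vars_equal_zyg" in self.constraints and len(self.zygosities) == 2:
            sca_merges += [((MZ, j), (DZ, j)) for j in (1, 2)]
        loc_map, n_loc = _merge_classes(cells, loc_merges)
        sca_map, n_sca = _merge_classes(cells, sca_merges)

        free_r = [z for z in self.zygosities if z not in self.fix_r]
        if "r_equal_zyg" in self.constraints and len(free_r) == 2:
            r_map = {z: 0 for z in free_r}
            n_r = 1
        else:
            r_map = {z: i for i, z in enumerate(free_r)}
            n_r = len(free_r)
        return cells, loc_map, n_loc, sca_map, n_sca, r_map, n_r

    # -- continuous engine --------------------------------------------

    def _cont_loglik(self, mu, var, r):
        """mu/var: {(z, j): value}; r: {z: value}."""
        ll = 0.0
        for z in self.zygosities:
            g = self._groups[z]
            m1, m2 = mu[(z, 1)], mu[(z, 2)]
            v1, v2 = var[(z, 1)], var[(z, 2)]
            rho = r[z]
            if v1 <= 0 or v2 <= 0 or not -1 < rho < 1:
                return -_PENALTY
            if len(g.complete):
                z1 = (g.complete[:, 0] - m1) / np.sqrt(v1)
                z2 = (g.complete[:, 1] - m2) / np.sqrt(v2)
                q = (z1 * z1 - 2 * rho * z1 * z2 + z2 * z2) / (1 - rho * rho)
                ll += np.sum(
                    -_LOG2PI - 0.5 * np.log(v1 * v2 * (1 - rho * rho)) - 0.5 * q
                )
            for x, m, v in ((g.single1, m1, v1), (g.single2, m2, v2)):
                if len(x):
                    ll += np.sum(
                        -0.5 * _LOG2PI - 0.5 * np.log(v) - 0.5 * (x - m) ** 2 / v
                    )
        return float(ll)

    def _cont_moments(self):
        mu, var, r = {}, {}, {}
        for z in self.zygosities:
            g = self._groups[z]
            for j, single in ((1, g.single1), (2, g.single2)):
                x = np.concatenate([g.complete[:, j - 1], single])
                mu[(z, j)] = float(np.mean(x))
                var[(z, j)] = float(np.var(x))  # ML (1/n) variance
            c = g.complete
            if len(c) >= 2 and c[:, 0].std() > 0 and c[:, 1].std() > 0:
                r[z] = float(np.clip(np.corrcoef(c[:, 0], c[:, 1])[0, 1], -0.95, 0.95))
            else:
                r[z] = 0.0
        return mu, var, r

    def _fit_continuous(self):
        cells, loc_map, n_loc, sca_map, n_sca, r_map, n_r = self._build_layout()
        mu0, var0, r0 = self._cont_moments()
        no_missing = all(
            len(self._groups[z].single1) == 0 and len(self._groups[z].single2) == 0
            for z in self.zygosities
        )
        closed_form = (
            not self.constraints
            and no_missing
            and all(v == 0.0 for v in self.fix_r.values())
        )
        if closed_form:
            # unconstrained FIML-free case: sample moments are the MLE
            # (and with r fixed at 0 the likelihood factorises per margin)
            r_full = {
                z: float(np.corrcoef(self._groups[z].complete.T)[0, 1])
                if z not in self.fix_r
                else 0.0
                for z in self.zygosities
            }
            llf = self._cont_loglik(mu0, var0, r_full)
            return self._cont_results(mu0, var0, r_full, llf, n_loc + n_sca + n_r, True)

        def unpack(theta):
            mu = {c: theta[loc_map[c]] for c in cells}
            var = {c: np.exp(theta[n_loc + sca_map[c]]) for c in cells}
            r = {}
            for z in self.zygosities:
                if z in self.fix_r:
                    r[z] = self.fix_r[z]
                else:
                    r[z] = np.tanh(theta[n_loc + n_sca + r_map[z]])
            return mu, var, r

        theta0 = np.zeros(n_loc + n_sca + n_r)
        for c in cells:  # later cells overwrite; class members share moments anyway
            theta0[loc_map[c]] = mu0[c]
            theta0[n_loc + sca_map[c]] = np.log(max(var0[c], 1e-12))
        for z, i in r_map.items():
            theta0[n_loc + n_sca + i] = np.arctanh(r0[z])

        def nll(theta):
            return -self._cont_loglik(*unpack(theta))

        res = optimize.minimize(
            nll,
            theta0,
            method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 40000, "maxfev": 40000},
        )
        res2 = optimize.minimize(
            nll,
            res.x,
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000, "maxfev": 20000},
        )
        best = res2 if res2.fun <= res.fun else res
        if not np.isfinite(best.fun):
            raise OptimizationError(f"saturated continuous fit diverged: {best.message}")
        mu, var, r = unpack(best.x)
        return self._cont_results(
            mu, var, r, -best.fun, n_loc + n_sca + n_r, bool(best.success or res.success)
        )

    def _cont_results(self, mu, var, r, llf, n_params, converged):
        return SaturatedContinuousResults(
            model=self,
            means={z: (mu[(z, 1)], mu[(z, 2)]) for z in self.zygosities},
            variances={z: (var[(z, 1)], var[(z, 2)]) for z in self.zygosities},
            corr={z: float(r[z]) for z in self.zygosities},
            llf=float(llf),
            n_params=int(n_params),
            converged=converged,
        )

    # -- threshold engine ---------------------------------------------

    def _threshold_counts(self):
        counts = {}
        for z in self.zygosities:
            g = self._groups[z]
            c = g.complete.astype(int)
            tab = np.zeros(4)
            if len(c):
                idx = 2 * c[:, 0] + c[:, 1]  # (p00, p01, p10, p11) order
                tab = np.bincount(idx, minlength=4).astype(float)
            s1 = np.array(
                [np.sum(g.single1 == 0), np.sum(g.single1 == 1)], float
            )
            s2 = np.array(
                [np.sum(g.single2 == 0), np.sum(g.single2 == 1)], float
            )
            counts[z] = (tab, s1, s2)
            if np.count_nonzero(tab) < 3:
                warnings.warn(
                    f"{z}: 2x2 table has fewer than 3 occupied cells; the "
                    f"tetrachoric correlation may sit at the +/-{_R_BOUND} bound",
                    RuntimeWarning,
                )
        return counts

    def _thr_loglik(self, tau, r, counts):
        ll = 0.0
        for z in self.zygosities:
            tab, s1, s2 = counts[z]
            cells = cell_probabilities(tau[(z, 1)], tau[(z, 2)], r[z])
            ll += float(np.dot(tab, np.log(cells)))
            for s, t in ((s1, tau[(z, 1)]), (s2, tau[(z, 2)])):
                if s.sum():
                    p0 = min(max(ndtr(t), 1e-300), 1 - 1e-16)
                    ll += s[0] * np.log(p0) + s[1] * np.log1p(-p0)
        return ll

    def _fit_threshold(self):
        cells_lab, loc_map, n_loc, _, _, r_map, n_r = self._build_layout()
        counts = self._threshold_counts()

        tau0 = {}
        for z in self.zygosities:
            tab, s1, s2 = counts[z]
            for j in (1, 2):
                if j == 1:
                    n0 = tab[0] + tab[1] + s1[0]
                    n1 = tab[2] + tab[3] + s1[1]
                else:
                    n0 = tab[0] + tab[2] + s2[0]
                    n1 = tab[1] + tab[3] + s2[1]
                tot = max(n0 + n1, 1.0)
                p0 = np.clip(n0 / tot, 0.5 / tot, 1 - 0.5 / tot)
                tau0[(z, j)] = float(ndtri(p0))

        def unpack(theta):
            tau = {c: theta[loc_map[c]] for c in cells_lab}
            r = {}
            for z in self.zygosities:
                if z in self.fix_r:
                    r[z] = self.fix_r[z]
                else:
                    r[z] = _R_BOUND * np.tanh(theta[n_loc + r_map[z]])
            return tau, r

        def nll(theta):
            tau, r = unpack(theta)
            return -self._thr_loglik(tau, r, counts)

        best = None
        for r_start in (0.0, 0.5, -0.5):
            theta0 = np.zeros(n_loc + n_r)
            for c in cells_lab:
                theta0[loc_map[c]] = tau0[c]
            for z, i in r_map.items():
                theta0[n_loc + i] = np.arctanh(r_start / _R_BOUND)
            res = optimize.minimize(
                nll,
                theta0,
                method="Nelder-Mead",
                options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 20000, "maxfev": 20000},
            )
            if best is None or res.fun < best.fun:
                best = res
        res2 = optimize.minimize(
            nll,
            best.x,
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000, "maxfev": 20000},
        )
        if res2.fun <= best.fun:
            best = res2
        if not np.isfinite(best.fun):
            raise OptimizationError(f"saturated threshold fit diverged: {best.message}")
        tau, r = unpack(best.x)
        for z, val in r.items():
            if abs(val) >= _R_BOUND - 1e-6 and z not in self.fix_r:
                warnings.warn(
                    f"{z}: tetrachoric correlation at the +/-{_R_BOUND} bound",
                    RuntimeWarning,
                )
        return SaturatedThresholdResults(
            model=self,
            thresholds={z: (tau[(z, 1)], tau[(z, 2)]) for z in self.zygosities},
            corr={z: float(r[z]) for z in self.zygosities},
            llf=float(-best.fun),
            n_params=int(n_loc + n_r),
            converged=bool(best.success),
        )

    def fit(self):
        """Maximum-likelihood fit; returns the kind-appropriate Results."""
        if self.kind == "continuous":
            return self._fit_continuous()
        return self._fit_threshold()


@dataclass
class SaturatedContinuousResults:
    """ML means/variances per (zygosity, twin order) and correlations."""

    model: SaturatedTwinModel
    means: dict
    variances: dict
    corr: dict
    llf: float
    n_params: int
    converged: bool

    def summary(self) -> str:
        lines = [
            "Saturated continuous twin model",
            f"  trait: {self.model.trait}   log-likelihood: {self.llf:.4f}"
            f"   free parameters: {self.n_params}",
        ]
        for z in self.model.zygosities:
            m, v = self.means[z], self.variances[z]
            lines.append(
                f"  {z}: mean1={m[0]:.4f} mean2={m[1]:.4f} "
                f"var1={v[0]:.4f} var2={v[1]:.4f} r={self.corr[z]:.4f}"
            )
        return "\n".join(lines)


@dataclass
class SaturatedThresholdResults:
    """ML thresholds per (zygosity, twin order) and tetrachoric correlations."""

    model: SaturatedTwinModel
    thresholds: dict
    corr: dict
    llf: float
    n_params: int
    converged: bool

    def summary(self) -> str:
        lines = [
            "Saturated liability-threshold twin model",
            f"  trait: {self.model.trait}   log-likelihood: {self.llf:.4f}"
            f"   free parameters: {self.n_params}",
        ]
        for z in self.model.zygosities:
            t = self.thresholds[z]
            lines.append(
                f"  {z}: tau1={t[0]:.4f} tau2={t[1]:.4f} r={self.corr[z]:.4f}"
            )
        return "\n".join(lines)


def twin_correlation_zero_test(data: TwinDataset, trait: str, zygosity: str):
    """Twin correlation with likelihood-based 95% CI and LRT against r = 0.

    Fits the saturated model, refits with the requested zygosity's
    correlation fixed at zero (df = 1 LRT), and profiles the correlation
    for the confidence interval.  Returns ``(estimate, (lo, hi), LRTResult)``.
    """
    full = SaturatedTwinModel(data, trait).fit()
    null = SaturatedTwinModel(data, trait, fix_r={zygosity: 0.0}).fit()
    test = lrt(full.llf, null.llf, df=1)
    r_hat = full.corr[zygosity]

    def objective(x):
        return SaturatedTwinModel(data, trait, fix_r={zygosity: float(x)}).fit().llf

    lo = profile_bound(objective, r_hat, full.llf, -_R_BOUND, r_hat, "lower")
    hi = profile_bound(objective, r_hat, full.llf, r_hat, _R_BOUND, "upper")
    return r_hat, (lo, hi), test


def assumption_tests(data: TwinDataset, trait: str):
    """Twin-design assumption checks: equality of location/scale parameters.

    Applies the equality constraints cumulatively — across twin order
    first, then across zygosity — and tests each step against the
    unconstrained saturated model.  Returns a list of
    ``(constraint_set, LRTResult)`` in testing order.
    """
    kind = data.trait_spec(trait).kind
    if kind == "continuous":
        steps = [
            ("means_equal_order",),
            ("means_equal_order", "vars_equal_order"),
            ("means_equal_order", "vars_equal_order", "means_equal_zyg"),
            ("means_equal_order", "vars_equal_order", "means_equal_zyg", "vars_equal_zyg"),
        ]
    else:
        steps = [
            ("thresholds_equal_order",),
            ("thresholds_equal_order", "thresholds_equal_zyg"),
        ]
    full = SaturatedTwinModel(data, trait).fit()
    out = []
    for constraints in steps:
        nested = SaturatedTwinModel(data, trait, constraints=constraints).fit()
        out.append(
            (constraints, lrt(full.llf, nested.llf, df=full.n_params - nested.n_params))
        )
    return out
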