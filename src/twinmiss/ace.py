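"""Maximum-likelihood ACE variance decomposition for twin data.

The classical twin model writes a trait's variance as the sum of additive
genetics (A), shared environment (C) and unique environment (E).  Under
the standard assumptions the implied within-pair covariances are::

    Cov_MZ = a^2 + c^2          Cov_DZ = 0.5 * a^2 + c^2

(times the total variance for a continuous trait; the liability scale of a
binary trait has total variance fixed at 1 and a single threshold).  The
nested AE, CE and E models drop components.  Fitting is by direct
likelihood maximisation over unconstrained path coefficients from five
deterministic starting points (a moment-based start plus near-corners and
centroid of the share simplex), so shares stay non-negative without
boundary penalties; reported components are squared paths standardised by
the total variance.

Pairs with one absent twin contribute a univariate normal (continuous) or
marginal Bernoulli (threshold) likelihood term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import expit, ndtr, ndtri

from ._bvn import cell_probabilities
from .data import DZ, MZ, TwinDataset
from .exceptions import OptimizationError, SampleSizeError
from .inference import CHI2_1_95, profile_bound

__all__ = [
    "ACEModel",
    "ACEResults",
    "VarianceComponents",
    "MODEL_COMPONENTS",
    "N_PARAMS",
    "implied_twin_correlations",
]

MODEL_COMPONENTS = {
    "ACE": ("a2", "c2", "e2"),
    "AE": ("a2", "e2"),
    "CE": ("c2", "e2"),
    "E": ("e2",),
}

# Free-parameter counts used for AIC and LRT degrees of freedom.
N_PARAMS = {
    "continuous": {"ACE": 5, "AE": 4, "CE": 4, "E": 3},
    "binary": {"ACE": 3, "AE": 2, "CE": 2, "E": 1},
}

_DZ_A_WEIGHT = 0.5
_LOG2PI = np.log(2.0 * np.pi)
_BOUNDARY_EPS = 1e-4
_PENALTY = 1e15  # finite stand-in for an inadmissible parameter point


@dataclass
class VarianceComponents:
    """Standardised variance shares with paths and optional profile CIs."""

    a2: float
    c2: float
    e2: float
    a: float = None
    c: float = None
    e: float = None
    ci_a2: tuple | None = None
    ci_c2: tuple | None = None
    ci_e2: tuple | None = None

    def __post_init__(self):
        # paths normalised non-negative (their sign is unidentified)
        if self.a is None:
            self.a = float(np.sqrt(max(self.a2, 0.0)))
        if self.c is None:
            self.c = float(np.sqrt(max(self.c2, 0.0)))
        if self.e is None:
            self.e = float(np.sqrt(max(self.e2, 0.0)))

    def share(self, component: str) -> float:
        return getattr(self, component)

    def ci(self, component: str):
        return getattr(self, f"ci_{component}")


def _share_starts(r_mz, r_dz):
    """Five deterministic starting shares: moment-based, near-corners, centroid."""
    if r_mz is not None and r_dz is not None:
        a2 = 2.0 * (r_mz - r_dz)
        c2 = 2.0 * r_dz - r_mz
        s = np.clip([a2, c2, 1.0 - a2 - c2], 0.05, 0.9)
        falconer = s / s.sum()
    else:
        falconer = np.array([1 / 3, 1 / 3, 1 / 3])
    return [
        falconer,
        np.array([0.8, 0.1, 0.1]),
        np.array([0.1, 0.8, 0.1]),
        np.array([0.1, 0.1, 0.8]),
        np.array([1 / 3, 1 / 3, 1 / 3]),
    ]


def _project_shares(shares, components):
    """Restrict a (a2, c2, e2) start onto a model's components, renormalised."""
    keys = ("a2", "c2", "e2")
    kept = np.array(
        [max(shares[i], 0.05) if keys[i] in components else 0.0 for i in range(3)]
    )
    kept /= kept.sum()
    return {k: kept[i] for i, k in enumerate(keys)}


class ACEModel:
    """ACE / AE / CE / E model for one trait of a :class:`TwinDataset`.

    The trait's declared kind selects the engine: continuous traits use
    the pair-normal FIML likelihood with free mean and total variance;
    binary traits use the liability-threshold multinomial likelihood with
    a single threshold and unit liability variance.
    """

    def __init__(self, data: TwinDataset, trait: str, model: str = "ACE"):
        if model not in MODEL_COMPONENTS:
            raise ValueError(f"unknown model {model!r}; choose from {list(MODEL_COMPONENTS)}")
        self.data = data
        self.trait = trait
        self.model = model
        self.kind = data.trait_spec(trait).kind
        self.components = MODEL_COMPONENTS[model]
        self.zygosities = [z for z in (MZ, DZ) if data.n_pairs(z) > 0]
        if not self.zygosities:
            raise SampleSizeError("dataset contains no pairs")

        self._complete, self._single = {}, {}
        for z in self.zygosities:
            arr = data.pairs(trait, z)
            obs1, obs2 = ~np.isnan(arr[:, 0]), ~np.isnan(arr[:, 1])
            self._complete[z] = arr[obs1 & obs2]
            self._single[z] = np.concatenate([arr[obs1 & ~obs2, 0], arr[~obs1 & obs2, 1]])
            if len(self._complete[z]) < 2:
                raise SampleSizeError(f"{z}: need at least 2 complete pairs")
        if self.kind == "binary":
            self._tables = {}
            for z in self.zygosities:
                c = self._complete[z].astype(int)
                self._tables[z] = (
                    np.bincount(2 * c[:, 0] + c[:, 1], minlength=4).astype(float),
                    np.array(
                        [np.sum(self._single[z] == 0), np.sum(self._single[z] == 1)],
                        float,
                    ),
                )

    # -- likelihoods ---------------------------------------------------

    def _pair_r(self, a2, c2):
        return {MZ: a2 + c2, DZ: _DZ_A_WEIGHT * a2 + c2}

    def _cont_loglik(self, mu, var_total, a2_abs, c2_abs):
        """Absolute (unstandardised) variance components; var_total = their sum + e2."""
        if var_total <= 0:
            return -_PENALTY
        ll = 0.0
        sd = np.sqrt(var_total)
        covs = {MZ: a2_abs + c2_abs, DZ: _DZ_A_WEIGHT * a2_abs + c2_abs}
        for z in self.zygosities:
            rho = covs[z] / var_total
            if not -1 < rho < 1:
                return -_PENALTY
            c = self._complete[z]
            if len(c):
                z1 = (c[:, 0] - mu) / sd
                z2 = (c[:, 1] - mu) / sd
                q = (z1 * z1 - 2 * rho * z1 * z2 + z2 * z2) / (1 - rho * rho)
                ll += np.sum(
                    -_LOG2PI - 0.5 * np.log(var_total**2 * (1 - rho * rho)) - 0.5 * q
                )
            s = self._single[z]
            if len(s):
                ll += np.sum(
                    -0.5 * _LOG2PI - 0.5 * np.log(var_total) - 0.5 * (s - mu) ** 2 / var_total
                )
        return float(ll)

    def _thr_loglik(self, tau, a2, c2):
        e2 = 1.0 - a2 - c2
        if e2 <= 1e-12 or a2 < 0 or c2 < 0:
            return -_PENALTY
        rs = self._pair_r(a2, c2)
        ll = 0.0
        for z in self.zygosities:
            tab, singles = self._tables[z]
            cells = cell_probabilities(tau, tau, rs[z])
            ll += float(np.dot(tab, np.log(cells)))
            if singles.sum():
                p0 = min(max(ndtr(tau), 1e-300), 1 - 1e-16)
                ll += singles[0] * np.log(p0) + singles[1] * np.log1p(-p0)
        return ll

    # -- moments for starts --------------------------------------------

    def _sample_correlations(self):
        out = {}
        for z in (MZ, DZ):
            if z in self.zygosities and len(self._complete[z]) >= 3:
                c = self._complete[z]
                if c[:, 0].std() > 0 and c[:, 1].std() > 0:
                    out[z] = float(np.corrcoef(c[:, 0], c[:, 1])[0, 1])
                    continue
            out[z] = None
        return out

    # -- fitting -------------------------------------------------------

    def fit(self, want_ci: bool = False) -> "ACEResults":
        """Maximise the likelihood; optionally attach 95% profile CIs."""
        if self.kind == "continuous":
            res = self._fit_continuous()
        else:
            res = self._fit_threshold()
        if want_ci:
            for comp in self.components:
                setattr(res.components, f"ci_{comp}", res.conf_int(comp))
        return res

    def _fit_continuous(self):
        obs = np.concatenate(
            [self._complete[z].ravel() for z in self.zygosities]
            + [self._single[z] for z in self.zygosities]
        )
        mu0, v0 = float(np.mean(obs)), float(np.var(obs))

        if self.model == "E":
            # independence: the pooled mean and ML variance are the MLE
            llf = self._cont_loglik(mu0, v0, 0.0, 0.0)
            return self._results(
                mu=mu0, sigma2_total=v0, shares={"a2": 0.0, "c2": 0.0, "e2": 1.0},
                llf=llf, converged=True,
            )

        free = [c for c in self.components if c != "e2"]  # paths a and/or c
        rs = self._sample_correlations()

        def unpack(theta):
            mu = theta[0]
            paths = dict(zip(free, theta[1:1 + len(free)]))
            e = theta[-1]
            a2_abs = paths.get("a2", 0.0) ** 2
            c2_abs = paths.get("c2", 0.0) ** 2
            var_total = a2_abs + c2_abs + e * e
            return mu, var_total, a2_abs, c2_abs

        def nll(theta):
            return -self._cont_loglik(*unpack(theta))

        best = None
        for shares in _share_starts(rs[MZ], rs[DZ]):
            s = _project_shares(shares, self.components)
            theta0 = np.concatenate(
                [[mu0], [np.sqrt(s[c] * v0) for c in free], [np.sqrt(s["e2"] * v0)]]
            )
            res = optimize.minimize(
                nll, theta0, method="Nelder-Mead",
                options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 20000, "maxfev": 20000},
            )
            if best is None or res.fun < best.fun - 1e-8 or (
                abs(res.fun - best.fun) <= 1e-8
                and unpack(res.x)[2] < unpack(best.x)[2]
            ):
                best = res
        res2 = optimize.minimize(
            nll, best.x, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000, "maxfev": 20000},
        )
        if res2.fun <= best.fun:
            best = res2
        if not np.isfinite(best.fun):
            raise OptimizationError("continuous ACE fit diverged")
        mu, var_total, a2_abs, c2_abs = unpack(best.x)
        shares = {
            "a2": a2_abs / var_total,
            "c2": c2_abs / var_total,
            "e2": max(var_total - a2_abs - c2_abs, 0.0) / var_total,
        }
        return self._results(
            mu=mu, sigma2_total=var_total, shares=shares,
            llf=-best.fun, converged=bool(best.success),
        )

    def _fit_threshold(self):
        n0 = sum(self._tables[z][0][0] * 2 + self._tables[z][0][1]
                 + self._tables[z][0][2] + self._tables[z][1][0]
                 for z in self.zygosities)
        n1 = sum(self._tables[z][0][3] * 2 + self._tables[z][0][1]
                 + self._tables[z][0][2] + self._tables[z][1][1]
                 for z in self.zygosities)
        tot = n0 + n1
        p0 = np.clip(n0 / tot, 0.5 / tot, 1 - 0.5 / tot)
        tau0 = float(ndtri(p0))

        if self.model == "E":
            # independence: pooled threshold is the MLE
            llf = self._thr_loglik(tau0, 0.0, 0.0)
            return self._results(
                tau=tau0, sigma2_total=1.0, shares={"a2": 0.0, "c2": 0.0, "e2": 1.0},
                llf=llf, converged=True,
            )

        free = [c for c in self.components if c != "e2"]
        rs = self._sample_correlations()

        def unpack(theta):
            tau = theta[0]
            paths = dict(zip(free, theta[1:]))
            a2 = paths.get("a2", 0.0) ** 2
            c2 = paths.get("c2", 0.0) ** 2
            return tau, a2, c2

        def nll(theta):
            tau, a2, c2 = unpack(theta)
            e2 = 1.0 - a2 - c2
            if e2 <= 1e-12:
                return _PENALTY
            # tiny log-barrier keeps e2 strictly positive without moving
            # interior optima at any reported precision
            return -self._thr_loglik(tau, a2, c2) - 1e-9 * np.log(e2)

        best = None
        for shares in _share_starts(rs[MZ], rs[DZ]):
            s = _project_shares(shares, self.components)
            theta0 = np.concatenate([[tau0], [np.sqrt(s[c]) for c in free]])
            res = optimize.minimize(
                nll, theta0, method="Nelder-Mead",
                options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 20000, "maxfev": 20000},
            )
            if best is None or res.fun < best.fun - 1e-8 or (
                abs(res.fun - best.fun) <= 1e-8 and unpack(res.x)[1] < unpack(best.x)[1]
            ):
                best = res
        res2 = optimize.minimize(
            nll, best.x, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000, "maxfev": 20000},
        )
        if res2.fun <= best.fun:
            best = res2
        if not np.isfinite(best.fun):
            raise OptimizationError("threshold ACE fit diverged")
        tau, a2, c2 = unpack(best.x)
        shares = {"a2": a2, "c2": c2, "e2": max(1.0 - a2 - c2, 0.0)}
        return self._results(
            tau=tau, sigma2_total=1.0, shares=shares,
            llf=self._thr_loglik(tau, a2, c2), converged=bool(best.success),
        )

    def _results(self, shares, llf, converged, sigma2_total, mu=None, tau=None):
        # components outside the model are exactly zero
        for comp in ("a2", "c2", "e2"):
            if comp not in self.components:
                shares[comp] = 0.0
        total = shares["a2"] + shares["c2"] + shares["e2"]
        shares = {k: v / total for k, v in shares.items()}
        boundary = any(
            shares[c] < _BOUNDARY_EPS for c in self.components if c != "e2"
        )
        n_params = N_PARAMS[self.kind if self.kind == "continuous" else "binary"][self.model]
        return ACEResults(
            model_obj=self,
            model=self.model,
            components=VarianceComponents(**{k: float(v) for k, v in shares.items()}),
            mu=mu,
            tau=tau,
            sigma2_total=float(sigma2_total),
            llf=float(llf),
            n_params=n_params,
            aic=float(-2.0 * llf + 2.0 * n_params),
            converged=converged,
            boundary=boundary,
        )

    # -- profile likelihood -------------------------------------------

    def _constrained_llf(self, component: str, value: float) -> float:
        """Max log-likelihood with one standardised share fixed at ``value``."""
        if component not in self.components:
            raise ValueError(f"component {component!r} not in model {self.model}")
        others = [c for c in self.components if c != component]
        n_logit = max(len(others) - 1, 0)
        x = float(np.clip(value, 0.0, 1.0))
        if not others:
            # single-component model: the standardised share is structurally 1
            return self.fit().llf if abs(x - 1.0) < 1e-9 else -_PENALTY

        def shares_from(logits):
            rest = 1.0 - x
            out = {component: x}
            if not others:
                return out
            if n_logit == 0:
                out[others[0]] = rest
            else:
                t = expit(logits[0])
                out[others[0]] = rest * t
                out[others[1]] = rest * (1.0 - t)
            return out

        if self.kind == "continuous":
            def nll(theta):
                mu, logv = theta[0], theta[1]
                v = np.exp(logv)
                s = shares_from(theta[2:])
                return -self._cont_loglik(
                    mu, v, s.get("a2", 0.0) * v, s.get("c2", 0.0) * v
                )

            obs = np.concatenate(
                [self._complete[z].ravel() for z in self.zygosities]
                + [self._single[z] for z in self.zygosities]
            )
            theta0 = np.concatenate(
                [[np.mean(obs), np.log(max(np.var(obs), 1e-12))], np.zeros(n_logit)]
            )
        else:
            def nll(theta):
                tau = theta[0]
                s = shares_from(theta[1:])
                return -self._thr_loglik(tau, s.get("a2", 0.0), s.get("c2", 0.0))

            tab_n0 = sum(self._tables[z][0][0] * 2 + self._tables[z][0][1]
                         + self._tables[z][0][2] + self._tables[z][1][0]
                         for z in self.zygosities)
            tab_n = sum(self._tables[z][0].sum() * 2 + self._tables[z][1].sum()
                        for z in self.zygosities)
            p0 = np.clip(tab_n0 / tab_n, 0.5 / tab_n, 1 - 0.5 / tab_n)
            theta0 = np.concatenate([[ndtri(p0)], np.zeros(n_logit)])

        res = optimize.minimize(
            nll, theta0, method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 20000, "maxfev": 20000},
        )
        return float(-res.fun)

    def profile_ci(self, fit_results: "ACEResults", component: str, level: float = 0.95):
        """Likelihood-based CI: share values whose constrained-refit -2LL is
        within the chi2(1) cutoff of the minimum; truncated to [0, 1]."""
        if level != 0.95:
            raise NotImplementedError("only 95% profile intervals are supported")
        mle = fit_results.components.share(component)
        llf = fit_results.llf

        def objective(x):
            return self._constrained_llf(component, x)

        lo = profile_bound(objective, mle, llf, 0.0, mle, "lower", cutoff=CHI2_1_95)
        hi = profile_bound(objective, mle, llf, mle, 1.0, "upper", cutoff=CHI2_1_95)
        return (float(lo), float(hi))


@dataclass
class ACEResults:
    """A fitted ACE-family model: estimates, fit statistics, profile CIs."""

    model_obj: ACEModel
    model: str
    components: VarianceComponents
    mu: float | None
    tau: float | None
    sigma2_total: float
    llf: float
    n_params: int
    aic: float
    converged: bool
    boundary: bool = False

    def implied_correlations(self):
        """Model-implied twin correlations (rMZ, rDZ)."""
        return implied_twin_correlations(self)

    def conf_int(self, component: str):
        """95% profile-likelihood CI for one standardised share."""
        return self.model_obj.profile_ci(self, component)

    def summary(self) -> str:
        c = self.components
        loc = (
            f"mu = {self.mu:.4f}, sigma2 = {self.sigma2_total:.4f}"
            if self.mu is not None
            else f"tau = {self.tau:.4f} (liability variance fixed at 1)"
        )
        rmz, rdz = self.implied_correlations()
        lines = [
            f"{self.model} twin model ({self.model_obj.kind} trait "
            f"{self.model_obj.trait!r})",
            f"  log-likelihood = {self.llf:.4f}   AIC = {self.aic:.2f}"
            f"   parameters = {self.n_params}",
            f"  {loc}",
            f"  a2 = {c.a2:.4f}  c2 = {c.c2:.4f}  e2 = {c.e2:.4f}",
            f"  implied rMZ = {rmz:.4f}, rDZ = {rdz:.4f}",
        ]
        for comp in self.model_obj.components:
            ci = c.ci(comp)
            if ci is not None:
                lines.append(f"  95% CI {comp}: [{ci[0]:.4f}; {ci[1]:.4f}]")
        if self.boundary:
            lines.append("  note: solution at a share boundary (component ~ 0)")
        return "\n".join(lines)


def implied_twin_correlations(fit: ACEResults):
    """Falconer expectations from fitted shares: rMZ = a2 + c2, rDZ = a2/2 + c2."""
    c = fit.components
    return (c.a2 + c.c2, _DZ_A_WEIGHT * c.a2 + c.c2)
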