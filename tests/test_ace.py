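"""ACE-family fits against brute-force grid oracles and recovery checks."""

import numpy as np
import pytest

from twinmiss import (
    ACEModel,
    SimulationSpec,
    implied_twin_correlations,
    simulate_binary_liability,
    simulate_continuous,
)
from twinmiss._bvn import cell_probabilities
from twinmiss.recovery import recover_ace, replicate_seeds

_LOG2PI = np.log(2.0 * np.pi)


def _share_grid(step=0.005):
    a2 = np.arange(0.0, 1.0 + step / 2, step)
    pts = []
    for a in a2:
        c = np.arange(0.0, 1.0 - a + step / 2, step)
        pts.append(np.column_stack([np.full_like(c, a), c]))
    return np.vstack(pts)


def _continuous_grid_oracle(ds, components):
    """Profile ML over a (a2, c2) share grid with GLS mean/variance closed form.

    For fixed standardised shares the pair correlation matrix R_z is known,
    and the ML mean is the GLS mean while the ML total variance is the
    average Mahalanobis quadratic form — both closed-form.
    """
    grid = _share_grid()
    keep = np.ones(len(grid), bool)
    if "a2" not in components:
        keep &= grid[:, 0] == 0
    if "c2" not in components:
        keep &= grid[:, 1] == 0
    grid = grid[keep]
    grid = grid[grid.sum(axis=1) <= 1 - 1e-9]  # e2 strictly positive

    data = {z: ds.pairs("trait", z) for z in ("MZ", "DZ") if ds.n_pairs(z)}
    best = -np.inf
    for a2, c2 in grid:
        r = {"MZ": a2 + c2, "DZ": 0.5 * a2 + c2}
        num = den = 0.0
        for z, arr in data.items():
            num += (arr[:, 0] + arr[:, 1]).sum() / (1 + r[z])
            den += 2 * len(arr) / (1 + r[z])
        mu = num / den
        q = n_obs = 0.0
        for z, arr in data.items():
            d1, d2 = arr[:, 0] - mu, arr[:, 1] - mu
            q += ((d1**2 - 2 * r[z] * d1 * d2 + d2**2) / (1 - r[z] ** 2)).sum()
            n_obs += 2 * len(arr)
        sigma2 = q / n_obs
        ll = 0.0
        for z, arr in data.items():
            n = len(arr)
            ll += n * (-_LOG2PI - 0.5 * np.log(sigma2**2 * (1 - r[z] ** 2)))
        ll -= 0.5 * q / sigma2
        best = max(best, ll)
    return best


def _threshold_grid_oracle(ds, components):
    """Share grid with the threshold profiled by a two-stage tau grid."""
    grid = _share_grid()
    keep = np.ones(len(grid), bool)
    if "a2" not in components:
        keep &= grid[:, 0] == 0
    if "c2" not in components:
        keep &= grid[:, 1] == 0
    grid = grid[keep]
    grid = grid[grid.sum(axis=1) <= 1 - 1e-9]

    tables = {}
    for z in ("MZ", "DZ"):
        if ds.n_pairs(z):
            arr = ds.pairs("trait", z).astype(int)
            tables[z] = np.bincount(2 * arr[:, 0] + arr[:, 1], minlength=4)

    def ll_at(a2, c2, taus):
        total = np.zeros_like(taus)
        r = {"MZ": a2 + c2, "DZ": 0.5 * a2 + c2}
        for z, tab in tables.items():
            cells = cell_probabilities(taus, taus, np.full_like(taus, r[z]))
            total += (np.log(cells) * tab).sum(axis=-1)
        return total

    best = -np.inf
    coarse = np.linspace(-3, 3, 201)
    for a2, c2 in grid:
        ll_c = ll_at(a2, c2, coarse)
        t0 = coarse[np.argmax(ll_c)]
        fine = np.linspace(t0 - 0.05, t0 + 0.05, 101)
        best = max(best, ll_at(a2, c2, fine).max())
    return best


class TestGridOracleEquivalence:
    @pytest.mark.parametrize("model", ["ACE", "AE", "CE", "E"])
    def test_continuous_fit_matches_grid_search(self, tiny_continuous, model):
        fit = ACEModel(tiny_continuous, "trait", model=model).fit()
        oracle = _continuous_grid_oracle(tiny_continuous, fit.model_obj.components)
        assert fit.llf == pytest.approx(oracle, abs=1e-3)

    @pytest.mark.parametrize("model", ["ACE", "AE", "CE", "E"])
    def test_threshold_fit_matches_grid_search(self, tiny_binary, model):
        fit = ACEModel(tiny_binary, "trait", model=model).fit()
        oracle = _threshold_grid_oracle(tiny_binary, fit.model_obj.components)
        assert fit.llf == pytest.approx(oracle, abs=1e-3)


class TestStructure:
    def test_e_model_equals_independent_univariate_likelihood(self):
        spec = SimulationSpec(
            a2=0, c2=0, e2=1, n_mz_pairs=2000, n_dz_pairs=2000, seed=21
        )
        ds = simulate_continuous(spec)
        fit = ACEModel(ds, "trait", model="E").fit()
        x = ds.individuals("trait")
        mu, v = x.mean(), x.var()
        oracle = np.sum(-0.5 * _LOG2PI - 0.5 * np.log(v) - 0.5 * (x - mu) ** 2 / v)
        assert fit.llf == pytest.approx(oracle, abs=1e-6)

    def test_nesting_chain_monotone_loglik(self, study_continuous, study_binary):
        for ds in (study_continuous, study_binary):
            fits = {m: ACEModel(ds, "trait", model=m).fit() for m in ("ACE", "AE", "CE", "E")}
            assert fits["ACE"].llf >= fits["AE"].llf - 1e-6
            assert fits["ACE"].llf >= fits["CE"].llf - 1e-6
            assert fits["AE"].llf >= fits["E"].llf - 1e-6
            assert fits["CE"].llf >= fits["E"].llf - 1e-6

    def test_aic_identity_and_param_counts(self, study_continuous, study_binary):
        expected_k = {
            "continuous": {"ACE": 5, "AE": 4, "CE": 4, "E": 3},
            "binary": {"ACE": 3, "AE": 2, "CE": 2, "E": 1},
        }
        for ds, kind in ((study_continuous, "continuous"), (study_binary, "binary")):
            for m, k in expected_k[kind].items():
                fit = ACEModel(ds, "trait", model=m).fit()
                assert fit.n_params == k
                assert fit.aic == pytest.approx(-2 * fit.llf + 2 * k, abs=1e-9)

    def test_shares_sum_to_one_and_dropped_are_zero(self, study_continuous):
        for m in ("ACE", "AE", "CE", "E"):
            c = ACEModel(study_continuous, "trait", model=m).fit().components
            assert c.a2 + c.c2 + c.e2 == pytest.approx(1.0, abs=1e-6)
            if m in ("CE", "E"):
                assert c.a2 == 0.0
            if m in ("AE", "E"):
                assert c.c2 == 0.0

    def test_affine_equivariance_of_shares(self, study_continuous):
        fit = ACEModel(study_continuous, "trait", model="AE").fit()
        arr = study_continuous.pairs("trait")
        shifted = study_continuous.with_trait_values("trait", 3.5 * arr - 11.0)
        fit2 = ACEModel(shifted, "trait", model="AE").fit()
        assert fit2.components.a2 == pytest.approx(fit.components.a2, abs=1e-6)
        assert fit2.sigma2_total == pytest.approx(3.5**2 * fit.sigma2_total, rel=1e-5)
        assert fit2.mu == pytest.approx(3.5 * fit.mu - 11.0, abs=1e-5)


class TestImpliedCorrelations:
    def test_e_model_implies_zero(self, study_continuous):
        fit = ACEModel(study_continuous, "trait", model="E").fit()
        assert implied_twin_correlations(fit) == (0.0, 0.0)

    def test_falconer_formula(self):
        from types import SimpleNamespace

        from twinmiss.ace import VarianceComponents

        fit = SimpleNamespace(components=VarianceComponents(a2=0.4, c2=0.2, e2=0.4))
        assert implied_twin_correlations(fit) == pytest.approx((0.6, 0.4))

    def test_ce_model_equates_zygosities(self, study_binary):
        fit = ACEModel(study_binary, "trait", model="CE").fit()
        rmz, rdz = implied_twin_correlations(fit)
        assert rmz == pytest.approx(rdz, abs=1e-12)


class TestRecovery:
    """Mean-bias checks for each generating model (scaled-down replicates)."""

    @pytest.mark.parametrize(
        "model, a2, c2",
        [("AE", 0.5, 0.0), ("CE", 0.0, 0.4), ("ACE", 0.35, 0.25)],
    )
    def test_continuous_recovery_unbiased_at_large_n(self, model, a2, c2):
        out = recover_ace(
            model, a2=a2, c2=c2, n_mz_pairs=2000, n_dz_pairs=2000,
            n_replicates=30, seed=202,
        )
        assert out["a2"] == pytest.approx(a2, abs=0.02)
        assert out["c2"] == pytest.approx(c2, abs=0.02)

    @pytest.mark.parametrize(
        "model, a2, c2",
        [("AE", 0.5, 0.0), ("CE", 0.0, 0.4)],
    )
    def test_binary_recovery_unbiased_at_large_n(self, model, a2, c2):
        out = recover_ace(
            model, a2=a2, c2=c2, n_mz_pairs=2000, n_dz_pairs=2000,
            n_replicates=30, seed=203, trait_kind="binary", prevalence=0.4,
        )
        assert out["a2"] == pytest.approx(a2, abs=0.04)
        assert out["c2"] == pytest.approx(c2, abs=0.04)


class TestProfileCI:
    def test_pure_e_data_gives_tight_e2_interval_at_upper_bound(self):
        spec = SimulationSpec(
            a2=0, c2=0, e2=1, n_mz_pairs=2000, n_dz_pairs=2000, seed=23
        )
        ds = simulate_continuous(spec)
        fit = ACEModel(ds, "trait", model="ACE").fit()
        lo, hi = fit.conf_int("e2")
        assert hi == 1.0
        assert lo > 0.9

    def test_ci_contains_point_estimate(self, study_continuous):
        fit = ACEModel(study_continuous, "trait", model="AE").fit(want_ci=True)
        lo, hi = fit.components.ci_a2
        assert lo <= fit.components.a2 <= hi

    def test_endpoints_match_deviance_scan(self, study_continuous):
        """CI endpoints agree with a fine scan of constrained refits."""
        model = ACEModel(study_continuous, "trait", model="AE")
        fit = model.fit()
        lo, hi = model.profile_ci(fit, "a2")
        xs = np.arange(0.0, 1.0, 0.002)
        dev = np.array(
            [2 * (fit.llf - model._constrained_llf("a2", x)) for x in xs]
        )
        inside = xs[dev <= 3.841]
        assert lo == pytest.approx(inside.min(), abs=0.01)
        assert hi == pytest.approx(inside.max(), abs=0.01)

    def test_ci_excludes_zero_iff_lrt_significant(self):
        """Profile-CI / LRT duality for the familial component (a2, AE model),
        allowing 2 borderline disagreements in 50 datasets."""
        disagreements = 0
        for s in replicate_seeds(301, 50):
            spec = SimulationSpec(
                a2=0.25, c2=0.0, e2=0.75, n_mz_pairs=100, n_dz_pairs=100, seed=int(s)
            )
            ds = simulate_continuous(spec)
            model = ACEModel(ds, "trait", model="AE")
            fit = model.fit()
            e_fit = ACEModel(ds, "trait", model="E").fit()
            from twinmiss.inference import lrt

            p = lrt(fit.llf, e_fit.llf, df=1).p
            lo, _ = model.profile_ci(fit, "a2")
            if (lo > 0) != (p < 0.05):
                disagreements += 1
        assert disagreements <= 2
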