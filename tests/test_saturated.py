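"""Saturated twin models against closed-form and grid-search oracles."""

import numpy as np
import pytest
from scipy.stats import kstest, multivariate_normal

from twinmiss import (
    SaturatedTwinModel,
    SimulationSpec,
    TraitSpec,
    TwinDataset,
    TwinPairRecord,
    simulate_binary_liability,
    simulate_continuous,
    twin_correlation_zero_test,
)
from twinmiss._bvn import cell_probabilities
from twinmiss.exceptions import SampleSizeError
from twinmiss.recovery import replicate_seeds


def _cont_data(seed=0, n_mz=60, n_dz=50, a2=0.4, c2=0.2, missing_rate=0.0):
    spec = SimulationSpec(
        a2=a2, c2=c2, e2=1 - a2 - c2, n_mz_pairs=n_mz, n_dz_pairs=n_dz,
        seed=seed, missing_rate=missing_rate,
    )
    return simulate_continuous(spec)


class TestContinuousUnconstrained:
    def test_matches_closed_form_bivariate_normal_ml(self):
        """Unconstrained fit equals sample means, ML variances, Pearson r,
        and its log-likelihood equals the bivariate-normal value."""
        ds = _cont_data(seed=3)
        res = SaturatedTwinModel(ds, "trait").fit()
        assert res.n_params == 10
        llf_oracle = 0.0
        for z in ("MZ", "DZ"):
            arr = ds.pairs("trait", z)
            mu = arr.mean(axis=0)
            var = arr.var(axis=0)
            r = np.corrcoef(arr[:, 0], arr[:, 1])[0, 1]
            np.testing.assert_allclose(res.means[z], mu, atol=1e-6)
            np.testing.assert_allclose(res.variances[z], var, atol=1e-6)
            assert res.corr[z] == pytest.approx(r, abs=1e-6)
            cov = np.array(
                [
                    [var[0], r * np.sqrt(var[0] * var[1])],
                    [r * np.sqrt(var[0] * var[1]), var[1]],
                ]
            )
            llf_oracle += multivariate_normal(mean=mu, cov=cov).logpdf(arr).sum()
        assert res.llf == pytest.approx(llf_oracle, abs=1e-6)

    def test_fiml_uses_incomplete_pairs(self):
        """Dropping half-pairs changes the likelihood; FIML keeps them."""
        ds = _cont_data(seed=4, missing_rate=0.15)
        res = SaturatedTwinModel(ds, "trait").fit()
        arr = ds.pairs("trait")
        n_half = int((np.isnan(arr).sum(axis=1) == 1).sum())
        assert n_half > 0
        complete_only = ds.with_trait_values(
            "trait", np.where(np.isnan(arr).any(axis=1, keepdims=True), np.nan, arr)
        )
        res_c = SaturatedTwinModel(complete_only, "trait").fit()
        assert res.llf < res_c.llf  # extra marginal terms lower the total

    def test_independent_twins_have_near_zero_correlation(self):
        ds = _cont_data(seed=5, n_mz=5000, n_dz=5000, a2=0.0, c2=0.0)
        res = SaturatedTwinModel(ds, "trait").fit()
        assert abs(res.corr["MZ"]) < 0.05
        assert abs(res.corr["DZ"]) < 0.05

    def test_too_few_pairs_rejected(self):
        specs = [TraitSpec("trait", "continuous")]
        ds = TwinDataset(
            [TwinPairRecord("p1", "MZ", {"trait": (1.0, 2.0)})], specs
        )
        with pytest.raises(SampleSizeError):
            SaturatedTwinModel(ds, "trait")


class TestConstraints:
    def test_constraints_never_increase_loglik(self):
        ds = _cont_data(seed=6)
        full = SaturatedTwinModel(ds, "trait").fit()
        chain = [
            ("means_equal_order",),
            ("means_equal_order", "vars_equal_order"),
            ("means_equal_order", "vars_equal_order", "means_equal_zyg"),
            (
                "means_equal_order",
                "vars_equal_order",
                "means_equal_zyg",
                "vars_equal_zyg",
                "r_equal_zyg",
            ),
        ]
        prev = full
        for constraints in chain:
            res = SaturatedTwinModel(ds, "trait", constraints=constraints).fit()
            assert res.llf <= prev.llf + 1e-6
            assert res.n_params < prev.n_params
            prev = res

    def test_equality_assumptions_rarely_rejected_when_true(self):
        """Data generated with equal moments: the full-equality LRT should
        be non-significant at alpha = 0.05 in at least 90% of replicates."""
        from twinmiss.inference import lrt

        constraints = (
            "means_equal_order",
            "vars_equal_order",
            "means_equal_zyg",
            "vars_equal_zyg",
            "r_equal_zyg",
        )
        rejections = 0
        n_rep = 200
        for s in replicate_seeds(101, n_rep):
            ds = _cont_data(seed=int(s), n_mz=80, n_dz=80, a2=0.0, c2=0.4)
            full = SaturatedTwinModel(ds, "trait").fit()
            nested = SaturatedTwinModel(ds, "trait", constraints=constraints).fit()
            test = lrt(full.llf, nested.llf, df=full.n_params - nested.n_params)
            rejections += test.p < 0.05
        assert rejections <= 0.10 * n_rep


class TestThreshold:
    def _table_dataset(self, cells, zygosity="MZ"):
        """Dataset realising exact 2x2 counts (n00, n01, n10, n11)."""
        specs = [TraitSpec("miss", "binary")]
        records = []
        i = 0
        for count, (y1, y2) in zip(cells, [(0, 0), (0, 1), (1, 0), (1, 1)]):
            for _ in range(count):
                records.append(
                    TwinPairRecord(f"p{i}", zygosity, {"miss": (float(y1), float(y2))})
                )
                i += 1
        return TwinDataset(records, specs)

    def test_recovers_generating_tetrachoric_correlation(self):
        spec = SimulationSpec(
            a2=0.41, c2=0.0, e2=0.59, n_mz_pairs=10000, n_dz_pairs=0,
            trait_kind="binary", prevalence=0.396, seed=13,
        )
        ds = simulate_binary_liability(spec)
        res = SaturatedTwinModel(ds, "trait").fit()
        assert res.corr["MZ"] == pytest.approx(0.41, abs=0.03)

    def test_independent_table_gives_near_zero_correlation(self):
        spec = SimulationSpec(
            a2=0.0, c2=0.0, e2=1.0, n_mz_pairs=10000, n_dz_pairs=0,
            trait_kind="binary", prevalence=0.3, seed=14,
        )
        ds = simulate_binary_liability(spec)
        res = SaturatedTwinModel(ds, "trait").fit()
        assert abs(res.corr["MZ"]) < 0.03

    def test_matches_grid_search_oracle_on_fixed_table(self):
        """Order-constrained fit on a fixed table equals an exhaustive
        (r, tau) grid search over the same likelihood."""
        cells = (20, 7, 6, 10)
        ds = self._table_dataset(cells)
        res = SaturatedTwinModel(
            ds, "miss", constraints=("thresholds_equal_order",)
        ).fit()

        r_grid = np.arange(-0.995, 0.9951, 1e-3)
        tau_grid = np.arange(-1.5, 1.5001, 1e-3)
        counts = np.asarray(cells, float)
        best_ll, best_r, best_tau = -np.inf, None, None
        for start in range(0, len(r_grid), 100):  # chunked to bound memory
            r_chunk = r_grid[start:start + 100]
            rr, tt = np.meshgrid(r_chunk, tau_grid, indexing="ij")
            ll = (np.log(cell_probabilities(tt, tt, rr)) * counts).sum(axis=-1)
            idx = np.unravel_index(np.argmax(ll), ll.shape)
            if ll[idx] > best_ll:
                best_ll = ll[idx]
                best_r, best_tau = r_chunk[idx[0]], tau_grid[idx[1]]
        assert res.llf == pytest.approx(best_ll, abs=1e-3)
        assert res.corr["MZ"] == pytest.approx(best_r, abs=2e-3)
        assert res.thresholds["MZ"][0] == pytest.approx(best_tau, abs=2e-3)

    def test_cell_probabilities_sum_to_one_at_fit(self):
        ds = self._table_dataset((15, 5, 7, 12))
        res = SaturatedTwinModel(ds, "miss").fit()
        t1, t2 = res.thresholds["MZ"]
        cells = cell_probabilities(t1, t2, res.corr["MZ"])
        assert cells.sum() == pytest.approx(1.0, abs=1e-10)

    def test_degenerate_table_warns_and_hits_bound(self):
        ds = self._table_dataset((25, 0, 0, 15))  # perfectly concordant
        with pytest.warns(RuntimeWarning):
            res = SaturatedTwinModel(ds, "miss").fit()
        assert res.corr["MZ"] == pytest.approx(0.999, abs=1e-3)


class TestZeroCorrelationTest:
    def test_recovers_strong_mz_correlation(self):
        vals = []
        for s in replicate_seeds(55, 40):
            spec = SimulationSpec(
                a2=0.0, c2=0.55, e2=0.45, n_mz_pairs=165, n_dz_pairs=0, seed=int(s)
            )
            ds = simulate_continuous(spec)
            vals.append(SaturatedTwinModel(ds, "trait").fit().corr["MZ"])
        assert np.mean(vals) == pytest.approx(0.55, abs=0.03)

    def test_null_p_values_are_uniform(self):
        """LRT p-values under r = 0 pass a KS test for uniformity."""
        from twinmiss.inference import lrt

        ps = []
        for s in replicate_seeds(77, 500):
            ds = _cont_data(seed=int(s), n_mz=100, n_dz=100, a2=0.0, c2=0.0)
            full = SaturatedTwinModel(ds, "trait").fit()
            null = SaturatedTwinModel(ds, "trait", fix_r={"MZ": 0.0}).fit()
            ps.append(lrt(full.llf, null.llf, df=1).p)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_ci_and_lrt_agree_on_significance(self):
        """Profile CI excludes 0 iff LRT p < 0.05 (allowing 2 borderline
        disagreements in 50 datasets)."""
        disagreements = 0
        for s in replicate_seeds(88, 50):
            ds = _cont_data(seed=int(s), n_mz=60, n_dz=0, a2=0.0, c2=0.25)
            r, (lo, hi), test = twin_correlation_zero_test(ds, "trait", "MZ")
            excludes = lo > 0 or hi < 0
            if excludes != (test.p < 0.05):
                disagreements += 1
        assert disagreements <= 2
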