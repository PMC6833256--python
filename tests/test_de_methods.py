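import math

import numpy as np
import pytest
import scipy.stats as st
from hypothesis import given, settings
from hypothesis import strategies as hst

from coregnet.de_methods import (
    DispersionModel,
    bh_adjust,
    estimate_dispersion,
    moderated_t,
    nb_exact_test,
    run_deseq_like,
    run_edger_like,
    run_voom_like,
    run_vst_like,
    significant_genes,
    size_factors,
    voom_transform,
    vst_transform,
)
from coregnet.simdata import CountMatrix, SimConfig, simulate_counts


def make_cm(counts, groups=None):
    counts = np.asarray(counts)
    n_genes, n_samples = counts.shape
    if groups is None:
        groups = ["A"] * (n_samples // 2) + ["B"] * (n_samples - n_samples // 2)
    return CountMatrix(
        gene_ids=[f"g{i}" for i in range(n_genes)],
        sample_ids=[f"s{j}" for j in range(n_samples)],
        counts=counts,
        group_labels=groups,
    )


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def oracle_size_factors(counts):
    """Median-of-ratios from first principles (pure python)."""
    counts = [list(map(float, row)) for row in counts]
    rows = [r for r in counts if all(v > 0 for v in r)]
    n_samp = len(counts[0])
    sf = []
    for j in range(n_samp):
        ratios = []
        for r in rows:
            gm = math.exp(sum(math.log(v) for v in r) / len(r))
            ratios.append(r[j] / gm)
        ratios.sort()
        mid = len(ratios) // 2
        med = ratios[mid] if len(ratios) % 2 else 0.5 * (ratios[mid - 1] + ratios[mid])
        sf.append(med)
    return sf


def oracle_nb_logpmf(k, mean, alpha):
    """NB log pmf from the gamma-function formula, no scipy."""
    if alpha <= 1e-12:
        return k * math.log(mean) - mean - math.lgamma(k + 1)
    r = 1.0 / alpha
    p = r / (r + mean)
    return (
        math.lgamma(k + r)
        - math.lgamma(r)
        - math.lgamma(k + 1)
        + r * math.log(p)
        + k * math.log(1.0 - p)
    )


def oracle_exact_test(k_a, k_b, n_a, n_b, alpha):
    """Exhaustive enumeration of all splits of the conditional exact test."""
    ks = k_a + k_b
    if ks == 0:
        return 1.0
    mu0 = ks / (n_a + n_b)
    logs = []
    for a in range(ks + 1):
        la = oracle_nb_logpmf(a, n_a * mu0, alpha / n_a)
        lb = oracle_nb_logpmf(ks - a, n_b * mu0, alpha / n_b)
        logs.append(la + lb)
    obs = logs[k_a]
    total = sum(math.exp(v) for v in logs)
    keep = sum(math.exp(v) for v in logs if v <= obs + 1e-9)
    return keep / total


# ---------------------------------------------------------------------------
# size factors
# ---------------------------------------------------------------------------

class TestSizeFactors:
    def test_identical_columns_give_unity(self):
        cm = make_cm([[5, 5, 5, 5], [9, 9, 9, 9], [2, 2, 2, 2]])
        assert np.allclose(size_factors(cm), 1.0)

    def test_doubled_column_two_samples(self):
        # second column = 2 x first: ratios to the per-gene geometric mean
        cm = make_cm([[10, 20], [7, 14], [3, 6]], groups=["A", "B"])
        expected = [2 ** -0.5, 2 ** 0.5]
        assert np.allclose(size_factors(cm), expected, rtol=1e-12)

    def test_three_by_three_against_oracle(self):
        counts = [[10, 20, 10], [100, 200, 100], [4, 8, 4]]
        cm = make_cm(counts, groups=["A", "A", "B"])
        # frozen from the oracle: ratios are (2^-1/3, 2^2/3, 2^-1/3) per gene
        frozen = [2 ** (-1 / 3), 2 ** (2 / 3), 2 ** (-1 / 3)]
        assert np.allclose(oracle_size_factors(counts), frozen, rtol=1e-12)
        assert np.allclose(size_factors(cm), frozen, rtol=1e-12)

    def test_oracle_agreement_on_random_matrices(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            counts = rng.integers(1, 500, size=(20, 6))
            cm = make_cm(counts)
            assert np.allclose(size_factors(cm), oracle_size_factors(counts))

    def test_error_without_all_positive_gene(self):
        cm = make_cm([[0, 5, 5, 1], [3, 0, 9, 2], [1, 2, 0, 3], [1, 2, 3, 0]])
        with pytest.raises(ValueError, match="all-positive"):
            size_factors(cm)


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------

class TestEstimateDispersion:
    def test_single_sample_per_group_errors(self):
        cm = make_cm([[5, 9], [3, 2]], groups=["A", "B"])
        with pytest.raises(ValueError):
            estimate_dispersion(cm, np.ones(2))

    def test_constant_alpha_recovery(self):
        cfg = SimConfig(
            n_genes=5000, n_tfs=0, n_mirnas=0, n_per_group=10,
            de_fraction=0.0, disp_a0=0.0, disp_a1=0.1, seed=21,
        )
        cm, _ = simulate_counts(cfg)
        model = estimate_dispersion(cm, size_factors(cm))
        assert 0.08 <= model.common_dispersion <= 0.12

    def test_poisson_limit(self):
        cfg = SimConfig(
            n_genes=5000, n_tfs=0, n_mirnas=0, n_per_group=10,
            de_fraction=0.0, disp_a0=0.0, disp_a1=0.0, seed=22,
        )
        cm, _ = simulate_counts(cfg)
        model = estimate_dispersion(cm, size_factors(cm))
        assert model.common_dispersion <= 0.01

    def test_trend_recovery(self):
        cfg = SimConfig(
            n_genes=5000, n_tfs=0, n_mirnas=0, n_per_group=10,
            de_fraction=0.0, disp_a0=1.0, disp_a1=0.05, seed=23,
        )
        cm, _ = simulate_counts(cfg)
        model = estimate_dispersion(cm, size_factors(cm))
        assert abs(model.a0 - 1.0) <= 0.25
        assert abs(model.a1 - 0.05) <= 0.25 * 0.05

    def test_gene_wise_floor(self, small_dataset):
        cm, _, _ = small_dataset
        model = estimate_dispersion(cm, size_factors(cm))
        assert (model.gene_wise > 0).all()
        assert (model.per_gene_dispersion > 0).all()


# ---------------------------------------------------------------------------
# exact test
# ---------------------------------------------------------------------------

class TestNBExactTest:
    def test_symmetric_observation_is_one(self):
        assert nb_exact_test(10, 10, 5, 5, 0.1) == pytest.approx(1.0)

    def test_total_two_equal_groups_enumeration(self):
        # splits (0,2), (1,1), (2,0): implementation matches enumeration
        for alpha in (0.0, 0.5):
            p = nb_exact_test(0, 2, 4, 4, alpha)
            assert p == pytest.approx(oracle_exact_test(0, 2, 4, 4, alpha), rel=1e-9)

    def test_poisson_limit_matches_binomial(self):
        # dispersion 0, equal groups: conditional law is Binomial(ks, 1/2)
        ks, ka = 40, 8
        p_impl = nb_exact_test(ka, ks - ka, 6, 6, 0.0)
        pmf = st.binom.pmf(np.arange(ks + 1), ks, 0.5)
        p_binom = pmf[pmf <= pmf[ka] * (1 + 1e-9)].sum()
        assert p_impl == pytest.approx(p_binom, rel=1e-8)

    def test_zero_total_is_one(self):
        assert nb_exact_test(0, 0, 3, 3, 0.1) == 1.0

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            nb_exact_test(-1, 2, 3, 3, 0.1)

    @pytest.mark.parametrize("alpha", [0.0, 0.01, 0.1, 1.0])
    def test_oracle_agreement_spot_checks(self, alpha):
        rng = np.random.default_rng(3)
        for _ in range(25):
            ks = int(rng.integers(1, 51))
            ka = int(rng.integers(0, ks + 1))
            n_a, n_b = int(rng.integers(2, 8)), int(rng.integers(2, 8))
            got = nb_exact_test(ka, ks - ka, n_a, n_b, alpha)
            want = oracle_exact_test(ka, ks - ka, n_a, n_b, alpha)
            assert got == pytest.approx(want, rel=1e-7), (ks, ka, n_a, n_b, alpha)

    def test_windowed_large_total_close_to_full_enumeration(self):
        # above the full-enumeration cutoff the windowed sum must still match
        ks = 9000
        ka = 4100
        got = nb_exact_test(ka, ks - ka, 5, 5, 0.05)
        want = oracle_exact_test(ka, ks - ka, 5, 5, 0.05)
        assert got == pytest.approx(want, rel=1e-6)


# ---------------------------------------------------------------------------
# exact-test methods
# ---------------------------------------------------------------------------

class TestExactTestMethods:
    def test_shared_core_identity(self, small_dataset):
        cm, _, _ = small_dataset
        sf = size_factors(cm)
        model = estimate_dispersion(cm, sf)
        mu = (cm.counts / sf[None, :]).mean(axis=1)
        disp = model.trend(mu)
        r1 = run_deseq_like(cm, sf=sf, dispersion=disp)
        r2 = run_edger_like(cm, sf=sf, dispersion=disp)
        assert np.allclose(r1.table["p_value"], r2.table["p_value"])

    def test_all_zero_gene_gets_p_one(self):
        counts = np.array([[0, 0, 0, 0], [10, 12, 30, 40], [5, 5, 5, 5]])
        r = run_deseq_like(make_cm(counts))
        assert r.table.loc[0, "p_value"] == 1.0
        assert r.table.loc[0, "log2fc"] == 0.0

    def test_power_on_strong_effects(self):
        cfg = SimConfig(
            n_genes=600, n_tfs=0, n_mirnas=0, n_per_group=20,
            de_fraction=0.2, lfc_min=2.0, lfc_scale=0.5, seed=31,
        )
        cm, truth = simulate_counts(cfg)
        r = run_deseq_like(cm)
        sig = significant_genes(r, 0.05).genes
        de = truth.de_genes
        assert len(sig & de) / len(de) >= 0.6

    def test_one_result_row_per_gene(self, small_dataset):
        cm, _, _ = small_dataset
        for fn in (run_deseq_like, run_edger_like, run_vst_like, run_voom_like):
            r = fn(cm)
            assert list(r.table["gene_id"]) == cm.gene_ids
            assert ((r.table["p_value"] >= 0) & (r.table["p_value"] <= 1)).all()
            assert ((r.table["adj_p_value"] >= 0) & (r.table["adj_p_value"] <= 1)).all()


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

class TestVST:
    def test_poisson_closed_form(self):
        cm = make_cm([[1, 4, 9, 16], [25, 36, 49, 64], [4, 4, 4, 4]])
        model = DispersionModel(0.0, 0.0, 0.0, None)
        tm = vst_transform(cm, model, sf=np.ones(4))
        assert np.allclose(tm.values, 2.0 * np.sqrt(cm.counts))

    def test_constant_alpha_derivative_matches_inverse_sqrt_w(self):
        model = DispersionModel(0.0, 0.1, 0.1, None)
        cmv = np.array([[10.0, 100.0, 1000.0]])
        cm = make_cm([[10, 100, 1000], [10, 100, 1000]], groups=["A", "B", "B"])
        tm = vst_transform(cm, model, sf=np.ones(3))
        for q in (10.0, 100.0, 1000.0):
            h = 1e-4 * q
            def tau(x):
                return 2.0 / np.sqrt(0.1) * np.arcsinh(np.sqrt(0.1 * x))
            deriv = (tau(q + h) - tau(q - h)) / (2 * h)
            w = q + 0.1 * q**2
            assert deriv == pytest.approx(1.0 / math.sqrt(w), rel=1e-6)
        # implementation equals the closed form (up to none: it IS the form)
        assert np.allclose(tm.values[0], 2.0 / np.sqrt(0.1) * np.arcsinh(np.sqrt(0.1 * cmv)))

    def test_monotone(self):
        model = DispersionModel(0.5, 0.05, 0.05, None)
        q = np.array([[1, 5, 20, 100, 2000]])
        cm = make_cm(q.repeat(2, axis=0), groups=["A", "B", "B", "A", "B"])
        tm = vst_transform(cm, model, sf=np.ones(5))
        assert np.all(np.diff(tm.values[0]) > 0)

    def test_non_monotone_fit_errors(self):
        cm = make_cm([[1, 2, 3, 4]])
        with pytest.raises(ValueError):
            vst_transform(cm, DispersionModel(-2.0, 0.1, 0.1, None), sf=np.ones(4))

    def test_variance_flattening(self):
        cfg = SimConfig(
            n_genes=4000, n_tfs=0, n_mirnas=0, n_per_group=10,
            de_fraction=0.0, disp_a0=1.0, disp_a1=0.05, seed=33,
        )
        cm, _ = simulate_counts(cfg)
        sf = size_factors(cm)
        model = estimate_dispersion(cm, sf)
        tm = vst_transform(cm, model, sf=sf)
        sd = tm.values.std(axis=1, ddof=1)
        mu = (cm.counts / sf[None, :]).mean(axis=1)
        deciles = np.quantile(mu, np.linspace(0, 1, 11))
        bin_sd = []
        for lo, hi in zip(deciles[:-1], deciles[1:]):
            sel = (mu >= lo) & (mu < hi)
            if sel.sum() > 10:
                bin_sd.append(sd[sel].mean())
        assert max(bin_sd) / min(bin_sd) < 2.0


class TestVoom:
    def test_libsize_invariance(self):
        # pseudocount effect is ~0.36/count log2 units: negligible from ~50 up
        rng = np.random.default_rng(5)
        counts = rng.integers(50, 2000, size=(50, 6))
        cm1 = make_cm(counts)
        cm2 = make_cm(counts * 2)
        t1 = voom_transform(cm1)
        t2 = voom_transform(cm2)
        assert np.max(np.abs(t1.values - t2.values)) < 0.01

    def test_identical_genes_equal_weights(self):
        counts = np.tile([10, 20, 15, 25, 12, 22], (12, 1))
        tm = voom_transform(make_cm(counts))
        assert np.allclose(tm.weights, tm.weights[0, 0])

    def test_weights_positive_finite(self, small_dataset):
        cm, _, _ = small_dataset
        tm = voom_transform(cm)
        assert np.all(tm.weights > 0)
        assert np.all(np.isfinite(tm.weights))

    def test_too_few_genes_errors(self):
        with pytest.raises(ValueError):
            voom_transform(make_cm(np.ones((5, 4), dtype=int)))


# ---------------------------------------------------------------------------
# moderated t
# ---------------------------------------------------------------------------

class TestModeratedT:
    @staticmethod
    def gaussian_tm(seed=0, n_genes=200, n=10):
        rng = np.random.default_rng(seed)
        from coregnet.de_methods import TransformedMatrix

        return TransformedMatrix(
            values=rng.normal(size=(n_genes, 2 * n)),
            transform_name="vst",
            gene_ids=[f"g{i}" for i in range(n_genes)],
            sample_ids=[f"s{j}" for j in range(2 * n)],
            group_labels=["A"] * n + ["B"] * n,
        )

    def test_d0_zero_is_ordinary_t(self):
        tm = self.gaussian_tm(seed=1)
        res = moderated_t(tm, d0=0.0)
        a = tm.values[:, :10]
        b = tm.values[:, 10:]
        ref = st.ttest_ind(b, a, axis=1).pvalue
        assert np.allclose(res.table["p_value"], ref, atol=1e-10)

    def test_d0_infinite_uses_common_variance(self):
        tm = self.gaussian_tm(seed=2)
        res = moderated_t(tm, d0=np.inf)
        # all genes share one variance: t ∝ effect, p monotone in |effect|
        eff = np.abs(res.table["log2fc"].to_numpy())
        p = res.table["p_value"].to_numpy()
        order = np.argsort(eff)
        assert np.all(np.diff(p[order]) <= 1e-12)

    def test_null_p_uniform(self):
        tm = self.gaussian_tm(seed=3, n_genes=5000)
        res = moderated_t(tm)
        d = st.kstest(res.table["p_value"], "uniform").statistic
        assert d < 0.03

    def test_zero_residual_df_errors(self):
        from coregnet.de_methods import TransformedMatrix

        tm = TransformedMatrix(
            values=np.ones((20, 2)),
            transform_name="vst",
            gene_ids=[f"g{i}" for i in range(20)],
            sample_ids=["s0", "s1"],
            group_labels=["A", "B"],
        )
        with pytest.raises(ValueError):
            moderated_t(tm)


# ---------------------------------------------------------------------------
# BH and thresholding
# ---------------------------------------------------------------------------

class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_hand_computed_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_equal_unchanged(self):
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2, 0.2]), 0.2)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(
        hst.lists(hst.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60)
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_and_dominating(self, pvals):
        p = np.array(pvals)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestSignificantGenes:
    def test_all_one_empty(self, small_dataset):
        cm, _, _ = small_dataset
        r = run_voom_like(cm)
        r.table["adj_p_value"] = 1.0
        r.table["p_value"] = 1.0
        assert significant_genes(r).genes == set()

    def test_strict_inequality_at_one(self, small_dataset):
        cm, _, _ = small_dataset
        r = run_voom_like(cm)
        got = significant_genes(r, alpha=1.0).genes
        expect = set(r.table.loc[r.table["adj_p_value"] < 1.0, "gene_id"])
        assert got == expect

    def test_recovery_band_at_default_config(self):
        cfg = SimConfig(n_genes=1000, n_tfs=80, n_mirnas=30, n_per_group=10, seed=35)
        cm, truth = simulate_counts(cfg)
        r = run_voom_like(cm)
        n_sig = len(significant_genes(r, 0.05).genes)
        planted = int(truth.table["is_de"].sum())
        assert 0.8 * planted <= n_sig <= 1.2 * planted
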