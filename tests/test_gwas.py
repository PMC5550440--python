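"""Mixed-model score test, permutation thresholds, forward selection, RMIP."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hdgwas.genotypes import KinshipMatrix, kinship
from hdgwas.gwas import (
    MODELS,
    recode,
    fit_polygenic,
    score_test_batch,
    permutation_threshold,
    procedure_alpha,
    forward_select,
    resample_rmip,
    significant_snps,
    merge_signals,
)
from hdgwas.phenotypes import normalize_phenotype
from hdgwas.simulate import SimulationConfig, QtlSpec, simulate_diallel
from conftest import make_geno


def ols_score_test(y, X, g):
    """Independent ordinary-least-squares score test (the oracle)."""
    import numpy.linalg as la

    H = X @ la.solve(X.T @ X, X.T)
    ry = y - H @ y
    rg = g - H @ g
    sigma2 = ry @ ry / (len(y) - X.shape[1])
    stat = (rg @ ry) ** 2 / (rg @ rg * sigma2)
    return stats.chi2.sf(stat, 1)


class TestRecode:
    def test_inheritance_model_codings(self):
        calls = np.array([[0, 1, 2]], dtype=np.int8)
        assert recode(calls, "additive").tolist() == [[0, 1, 2]]
        assert recode(calls, "dominance").tolist() == [[0, 0, 2]]
        assert recode(calls, "recessive").tolist() == [[0, 2, 2]]
        assert recode(calls, "overdominance").tolist() == [[0, 1, 0]]

    def test_missing_mean_imputed(self):
        calls = np.array([[0], [2], [-1]], dtype=np.int8)
        col = recode(calls, "additive")[:, 0]
        assert col[2] == pytest.approx(np.mean([0, 2]))


class TestPolygenicFit:
    def test_identity_kinship_no_genetic_variance(self):
        rng = np.random.default_rng(0)
        y = rng.normal(0, 2.0, 500)
        fit = fit_polygenic(y, np.eye(500))
        total = fit.sigma_g2 + fit.sigma_e2
        assert total == pytest.approx(np.var(y), rel=0.1)

    def test_variance_components_scale_quadratically(self):
        rng = np.random.default_rng(1)
        n = 200
        A = rng.normal(size=(n, 40))
        K = A @ A.T / 40
        K /= np.diag(K).mean()
        y = rng.normal(size=n)
        f1 = fit_polygenic(y, K)
        f2 = fit_polygenic(3.0 * y, K)
        assert f2.sigma_g2 == pytest.approx(9.0 * f1.sigma_g2, rel=1e-4, abs=1e-10)
        assert f2.sigma_e2 == pytest.approx(9.0 * f1.sigma_e2, rel=1e-4)

    def test_heritability_recovery(self, small_diallel):
        _, _, _, f1, _, _ = small_diallel
        K = kinship(f1).values
        L = np.linalg.cholesky(K + 1e-8 * np.eye(K.shape[0]))
        h2hats = []
        rng = np.random.default_rng(2)
        for _ in range(12):
            u = L @ rng.standard_normal(K.shape[0])
            u *= np.sqrt(0.5) / u.std()
            y = u + np.sqrt(0.5) * rng.standard_normal(K.shape[0])
            h2hats.append(fit_polygenic(y, K).h2)
        assert abs(np.mean(h2hats) - 0.5) < 0.15


class TestScoreTest:
    def test_matches_ols_oracle_with_identity_kinship(self):
        rng = np.random.default_rng(3)
        n, m = 200, 1000
        y = rng.normal(size=n)
        G = rng.integers(0, 3, size=(n, m)).astype(float)
        X = np.ones((n, 1))
        fit = fit_polygenic(y, np.eye(n))
        pvals, _ = score_test_batch(fit.whiten(y), fit.whiten(X), fit.whiten(G))
        for j in range(0, m, 97):
            assert pvals[j] == pytest.approx(ols_score_test(y, X, G[:, j]), abs=1e-8)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(4)
        n, m = 300, 2000
        y = rng.normal(size=n)
        G = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        X = np.ones((n, 1))
        fit = fit_polygenic(y, np.eye(n))
        pvals, _ = score_test_batch(fit.whiten(y), fit.whiten(X), fit.whiten(G))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_monomorphic_marker_p_one(self):
        rng = np.random.default_rng(5)
        n = 100
        y = rng.normal(size=n)
        G = np.zeros((n, 1))
        fit = fit_polygenic(y, np.eye(n))
        X = np.ones((n, 1))
        pvals, betas = score_test_batch(fit.whiten(y), fit.whiten(X), fit.whiten(G))
        assert pvals[0] == 1.0 and betas[0] == 0.0


class TestPermutationThreshold:
    @staticmethod
    def setup_scan(seed=6, n=150, m=400):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=n)
        G = rng.binomial(2, 0.4, size=(n, m)).astype(np.int8)
        fit = fit_polygenic(y, np.eye(n))
        coded = {mod: recode(G, mod) for mod in MODELS}
        return y, coded, fit

    def test_monotone_in_fdr(self):
        y, coded, fit = self.setup_scan()
        thresholds = [
            permutation_threshold(y, coded, fit, n_perm=100, fdr=f,
                                  rng=np.random.default_rng(7))[0]
            for f in (0.01, 0.05, 0.2)
        ]
        assert thresholds[0] <= thresholds[1] <= thresholds[2]

    def test_deterministic_given_seed(self):
        y, coded, fit = self.setup_scan()
        a = permutation_threshold(y, coded, fit, n_perm=60, rng=np.random.default_rng(8))
        b = permutation_threshold(y, coded, fit, n_perm=60, rng=np.random.default_rng(8))
        assert a[0] == b[0]

    def test_null_minima_calibrated_at_quantile(self):
        # ~fdr of fresh null scans fall below the threshold by construction
        y, coded, fit = self.setup_scan(n=120, m=200)
        thr, minima = permutation_threshold(
            y, coded, fit, n_perm=200, fdr=0.1, rng=np.random.default_rng(9)
        )
        assert (minima < thr).mean() == pytest.approx(0.1, abs=0.03)

    def test_procedure_alpha_below_fdr_and_monotone(self):
        a50 = procedure_alpha(50, 5.0, 0.05)
        a300 = procedure_alpha(300, 5.0, 0.05)
        assert 0 < a50 < 0.05 and 0 < a300 < 0.05
        assert procedure_alpha(50, 5.0, 0.01) < a50


class TestForwardSelect:
    def test_planted_qtls_selected_in_order(self):
        rng = np.random.default_rng(10)
        n, m = 400, 120
        G = rng.binomial(2, 0.5, size=(n, m)).astype(float)
        y = 1.0 * G[:, 17] + 0.6 * G[:, 90] + rng.normal(0, 0.5, n)
        fit = fit_polygenic(y, np.eye(n))
        X = np.ones((n, 1))
        picks = forward_select(fit.whiten(y), fit.whiten(X), fit.whiten(G), threshold=1e-5)
        chosen = [j for j, _, _ in picks]
        assert chosen[0] == 17
        assert 90 in chosen[:2]

    def test_null_selects_nothing_at_strict_threshold(self):
        rng = np.random.default_rng(11)
        n, m = 300, 200
        G = rng.binomial(2, 0.5, size=(n, m)).astype(float)
        y = rng.normal(size=n)
        fit = fit_polygenic(y, np.eye(n))
        X = np.ones((n, 1))
        picks = forward_select(fit.whiten(y), fit.whiten(X), fit.whiten(G), threshold=1e-6)
        assert picks == []


def brute_force_forward_regression(y, G, threshold, max_steps=10):
    """Plain OLS forward selection (the reduction oracle)."""
    n = len(y)
    X = np.ones((n, 1))
    chosen = []
    for _ in range(max_steps):
        best = (1.1, -1)
        for j in range(G.shape[1]):
            if j in chosen:
                continue
            p = ols_score_test(y, X, G[:, j])
            if p < best[0]:
                best = (p, j)
        if best[1] < 0 or best[0] >= threshold:
            break
        chosen.append(best[1])
        X = np.column_stack([X, G[:, best[1]]])
    return chosen


class TestEngine:
    @staticmethod
    def sim(seed=0, qtls=(), **kw):
        base = dict(
            n_maternal=6, n_paternal_families=2, lines_per_family=5,
            n_chromosomes=2, markers_per_chromosome=80,
            h2_polygenic=0.0, residual_sd=0.5, n_replicates=1, seed=seed,
        )
        base.update(kw)
        cfg = SimulationConfig(qtl_specs=list(qtls), **base)
        parents, design, f1, table, truth = simulate_diallel(cfg)
        means = table[table.role == "F1"].groupby("sample")["value"].mean()
        return f1, pd.Series(normalize_phenotype(means), index=means.index), truth

    def test_reduces_to_plain_forward_regression_with_identity_kinship(self):
        f1, y, truth = self.sim(seed=1, qtls=[QtlSpec(1, 10_000_000, 1.2, 0.0)])
        ident = KinshipMatrix(list(f1.samples), np.eye(f1.n_samples))
        thr = 1e-4
        res = resample_rmip(
            y, f1, ident, n_resamples=1, subsample_frac=1.0, models=("additive",),
            threshold=thr, seed=3, loco=False, calibration="scan",
        )
        engine_sel = set(res.rmip.index[res.rmip["additive"] > 0])
        ids = sorted(y.index)
        G = recode(f1.subset_samples(ids).calls, "additive")
        oracle = brute_force_forward_regression(y.reindex(ids).to_numpy(), G, thr)
        oracle_ids = {f1.subset_samples(ids).markers.loc[j, "id"] for j in oracle}
        assert engine_sel == oracle_ids
        assert len(engine_sel) >= 1

    def test_deterministic_phenotype_gives_rmip_100(self):
        f1, y, truth = self.sim(seed=2, qtls=[QtlSpec(1, 10_000_000, 1.0, 0.0)],
                                residual_sd=0.05)
        K = kinship(f1)
        res = resample_rmip(y, f1, K, n_resamples=25, n_permutations=60, seed=5)
        assert res.rmip_max[truth.qtl_markers[0]] == 100.0

    def test_rmip_invariant_to_marker_and_sample_order(self):
        f1, y, truth = self.sim(seed=3, qtls=[QtlSpec(1, 10_000_000, 1.0, 0.0)])
        K = kinship(f1)
        kwargs = dict(n_resamples=20, n_permutations=50, seed=7)
        base = resample_rmip(y, f1, K, **kwargs)
        # reversed sample order
        rev = f1.subset_samples(list(reversed(f1.samples)))
        res_s = resample_rmip(y, rev, K, **kwargs)
        pd.testing.assert_frame_equal(base.rmip, res_s.rmip)
        # marker order scrambled within the container (positions must stay
        # sorted, so scramble by relabeling chromosome blocks)
        perm = np.r_[np.arange(80, 160), np.arange(0, 80)]
        shuf = f1.subset_markers(perm)
        res_m = resample_rmip(y, shuf, K, **kwargs)
        pd.testing.assert_series_equal(
            base.rmip_max.sort_index(), res_m.rmip_max.sort_index()
        )

    def test_f1_covariate_rerun_removes_mediated_signal(self):
        # BPaV built as F1 minus a constant: adding the F1 phenotype as a
        # covariate absorbs every signal (pure mediated pleiotropy)
        f1, y, truth = self.sim(seed=4, qtls=[QtlSpec(1, 10_000_000, 1.5, 0.0)],
                                residual_sd=0.2)
        K = kinship(f1)
        plain = resample_rmip(y, f1, K, n_resamples=25, n_permutations=60, seed=9)
        assert plain.rmip_max.max() >= 50  # signal present without covariate
        cov = pd.DataFrame({"F1": y})
        rerun = resample_rmip(y - 3.0, f1, K, n_resamples=25, n_permutations=60,
                              seed=9, covariates=cov)
        assert rerun.rmip_max.max() == 0.0
        from hdgwas.gwas import disappeared_signals

        gone = disappeared_signals(plain, rerun)
        assert set(gone) == set(plain.rmip_max.index[plain.rmip_max >= 5])


class TestMergeSignals:
    @staticmethod
    def snp_table(rows):
        return pd.DataFrame(rows, columns=["id", "rmip", "best_model", "best_p", "chrom", "pos"])

    def test_distance_rule_separates(self):
        rng = np.random.default_rng(12)
        calls = rng.integers(0, 3, size=(50, 2)).astype(np.int8)
        g = make_geno(calls, positions=[1_000_000, 1_900_000])
        snps = self.snp_table([
            ("mk000", 50.0, "additive", 1e-8, 1, 1_000_000),
            ("mk001", 40.0, "additive", 1e-6, 1, 1_900_000),
        ])
        signals = merge_signals(snps, g, max_distance=800_000, min_r2=0.0)
        assert len(signals) == 2

    def test_correlated_nearby_pair_merges_with_lead_by_rmip(self):
        col = np.array([0, 1, 2] * 20, dtype=np.int8)
        g = make_geno(np.column_stack([col, col]), positions=[1_000_000, 1_100_000])
        snps = self.snp_table([
            ("mk000", 50.0, "additive", 1e-8, 1, 1_000_000),
            ("mk001", 80.0, "additive", 1e-6, 1, 1_100_000),
        ])
        signals = merge_signals(snps, g, 800_000, 0.2)
        assert len(signals) == 1
        assert signals[0].lead == "mk001"
        assert (signals[0].start, signals[0].end) == (1_000_000, 1_100_000)

    def test_transitive_closure_matches_brute_force(self):
        rng = np.random.default_rng(13)
        n, m = 60, 12
        base = rng.integers(0, 3, size=n).astype(np.int8)
        calls = np.column_stack(
            [np.where(rng.random(n) < 0.9, base, rng.integers(0, 3, n)) for _ in range(m)]
        ).astype(np.int8)
        pos = [1_000_000 + 300_000 * j for j in range(m)]
        g = make_geno(calls, positions=pos)
        snps = self.snp_table(
            [(f"mk{j:03d}", 10.0 + j, "additive", 1e-6, 1, pos[j]) for j in range(m)]
        )
        signals = merge_signals(snps, g, 800_000, 0.2)
        # brute-force union-find over the same pair rule
        import itertools

        parent = list(range(m))

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        for i, j in itertools.combinations(range(m), 2):
            if abs(pos[i] - pos[j]) < 800_000:
                r = np.corrcoef(calls[:, i], calls[:, j])[0, 1] ** 2
                if r >= 0.2:
                    parent[find(i)] = find(j)
        expect = {}
        for j in range(m):
            expect.setdefault(find(j), set()).add(f"mk{j:03d}")
        got = {frozenset(s.members) for s in signals}
        assert got == {frozenset(v) for v in expect.values()}


class TestPowerMonotonicity:
    def test_rmip_nondecreasing_in_effect_size(self):
        """Mean RMIP at the planted QTL grows with its additive effect."""
        means = []
        for a in (0.3, 0.7, 1.2):
            rmips = []
            for seed in range(6):
                cfg = SimulationConfig(
                    n_maternal=8, n_paternal_families=2, lines_per_family=6,
                    n_chromosomes=4, markers_per_chromosome=80,
                    qtl_specs=[QtlSpec(2, 15_000_000, a, 0.0)],
                    h2_polygenic=0.2, residual_sd=1.0, n_replicates=2, seed=seed,
                )
                parents, design, f1, table, truth = simulate_diallel(cfg)
                y = pd.Series(
                    normalize_phenotype(
                        table[table.role == "F1"].groupby("sample")["value"].mean()
                    ),
                    index=sorted(set(table[table.role == "F1"]["sample"])),
                )
                res = resample_rmip(
                    y, f1, kinship(f1), n_resamples=20, n_permutations=50, seed=500 + seed
                )
                rmips.append(res.rmip_max.get(truth.qtl_markers[0], 0.0))
            means.append(np.mean(rmips))
        assert means[0] <= means[1] <= means[2]
        assert means[2] > means[0]
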