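"""QTL characterization: class rules, d/a effects, variance, allele origin."""

import numpy as np
import pandas as pd
import pytest

from hdgwas.qtl import (
    genotype_class,
    stuber_class,
    da_effects,
    superiority_class,
    variance_explained,
    superior_allele_accounting,
    favorable_direction,
)
from hdgwas.genotypes import pca
from hdgwas.simulate import SimulationConfig, QtlSpec, simulate_diallel


def class_calls(n0, n1, n2):
    return np.array([0] * n0 + [1] * n1 + [2] * n2)


class TestGenotypeClass:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((100, 200, 100), "three_genotype"),
            ((0, 250, 200), "two_genotype"),
            ((14, 250, 200), "two_genotype"),  # any class below 15 samples
            ((15, 15, 15), "three_genotype"),
        ],
    )
    def test_fifteen_sample_rule(self, counts, expected):
        cls, c = genotype_class(class_calls(*counts))
        assert cls == expected
        assert sum(c.values()) == sum(counts)

    def test_missing_calls_not_counted(self):
        calls = np.concatenate([class_calls(14, 30, 30), [-1] * 5])
        cls, c = genotype_class(calls)
        assert cls == "two_genotype" and sum(c.values()) == 74

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            genotype_class(np.ones(100, dtype=int))


class TestStuberBins:
    def test_bin_boundaries_closed_open_as_printed(self):
        grid = np.concatenate([np.linspace(0, 2.0, 401), [0.2, 0.8, 1.2]])
        for r in grid:
            cls = stuber_class(r)
            if r < 0.2:
                assert cls == "additive"
            elif r <= 0.8:
                assert cls == "partial_dominance"
            elif r <= 1.2:
                assert cls == "dominance"
            else:
                assert cls == "overdominance"
            assert stuber_class(-r) == cls  # bins act on |d/a|


class TestDaEffects:
    def make_pheno(self, means, n=50):
        calls = class_calls(n, n, n)
        y = np.array([means[c] for c in calls], dtype=float)
        return y, calls

    def test_noiseless_additive(self):
        y, g = self.make_pheno({0: 0.0, 1: 1.0, 2: 2.0})
        eff = da_effects(y, g)
        assert eff.a == pytest.approx(1.0, abs=1e-10)
        assert eff.d == pytest.approx(0.0, abs=1e-10)
        assert eff.stuber == "additive"

    def test_noiseless_partial_dominance(self):
        y, g = self.make_pheno({0: 0.0, 1: 1.5, 2: 2.0})
        eff = da_effects(y, g)
        assert eff.a == pytest.approx(1.0, abs=1e-10)
        assert eff.d == pytest.approx(0.5, abs=1e-10)
        assert eff.d_over_a == pytest.approx(0.5, abs=1e-10)
        assert eff.stuber == "partial_dominance"

    def test_noiseless_overdominance(self):
        y, g = self.make_pheno({0: 0.0, 1: 2.0, 2: 1.0})
        eff = da_effects(y, g)
        assert eff.a == pytest.approx(0.5, abs=1e-10)
        assert eff.d == pytest.approx(1.5, abs=1e-10)
        assert eff.d_over_a == pytest.approx(3.0, abs=1e-10)
        assert eff.stuber == "overdominance"

    def test_zero_additive_flagged(self):
        rng = np.random.default_rng(0)
        g = class_calls(60, 60, 60)
        y = (g == 1) * 2.0 + rng.normal(0, 0.1, size=len(g))
        y -= (g / 2) * (y[g == 2].mean() - y[g == 0].mean())  # force a ~ 0
        eff = da_effects(y, g)
        if abs(eff.a) < 1e-8:
            assert eff.flagged and eff.stuber in ("overdominance", "unclassified")

    def test_simulator_recovery_exact_without_noise(self):
        cfg = SimulationConfig(
            n_maternal=8, n_paternal_families=3, lines_per_family=6,
            n_chromosomes=2, markers_per_chromosome=60,
            qtl_specs=[QtlSpec(1, 10_000_000, 1.0, 0.5)],
            h2_polygenic=0.0, residual_sd=0.0, n_replicates=1, seed=5,
        )
        parents, design, f1, table, truth = simulate_diallel(cfg)
        vals = table[table.role == "F1"].set_index("sample")["value"]
        j = f1.markers.index[f1.markers["id"] == truth.qtl_markers[0]][0]
        g = pd.Series(f1.calls[:, j], index=f1.samples).reindex(vals.index)
        eff = da_effects(vals.to_numpy(), g.to_numpy())
        assert eff.a == pytest.approx(1.0, abs=1e-8)
        assert eff.d == pytest.approx(0.5, abs=1e-8)
        assert eff.d_over_a == pytest.approx(0.5, abs=1e-8)

    def test_estimates_nearly_unbiased_with_noise(self):
        das = []
        for seed in range(20):
            cfg = SimulationConfig(
                n_maternal=14, n_paternal_families=3, lines_per_family=13,
                n_chromosomes=2, markers_per_chromosome=40,
                qtl_specs=[QtlSpec(1, 10_000_000, 1.0, 0.5)],
                h2_polygenic=0.0, residual_sd=0.5, n_replicates=1, seed=seed,
            )
            parents, design, f1, table, truth = simulate_diallel(cfg)
            vals = table[table.role == "F1"].set_index("sample")["value"]
            j = f1.markers.index[f1.markers["id"] == truth.qtl_markers[0]][0]
            g = pd.Series(f1.calls[:, j], index=f1.samples).reindex(vals.index)
            das.append(da_effects(vals.to_numpy(), g.to_numpy()).d_over_a)
        assert abs(np.mean(das) - 0.5) < 0.05


class TestSuperiority:
    def test_directional_calls(self):
        g = class_calls(30, 30, 0)
        y = np.where(g == 1, 10.0, 8.0)
        assert superiority_class(y, g, "higher") == ("hetero_superior", False)
        assert superiority_class(y, g, "lower") == ("homo_superior", False)

    def test_tie_is_conservative_homo(self):
        g = class_calls(30, 30, 0)
        y = np.full(60, 5.0)
        cls, tied = superiority_class(y, g)
        assert cls == "homo_superior" and tied

    def test_direction_defaults(self):
        assert favorable_direction("GYPP") == "higher"
        assert favorable_direction("HD") == "lower"


class TestVarianceExplained:
    def test_exact_linear_relation(self):
        g = class_calls(40, 40, 40)
        y = 2.0 * g + 1.0
        assert variance_explained(y, g) == pytest.approx(1.0)

    def test_independent_marker_near_zero(self):
        rng = np.random.default_rng(1)
        g = rng.integers(0, 3, 500)
        y = rng.normal(size=500)
        assert variance_explained(y, g) < 0.02

    def test_aic_drops_collinear_duplicate(self):
        rng = np.random.default_rng(2)
        g1 = rng.integers(0, 3, 300).astype(float)
        g2 = g1.copy()  # perfectly collinear lead SNPs
        y = g1 + rng.normal(0, 0.5, 300)
        r2_pair, kept_pair = variance_explained(y, [g1, g2], multi=True)
        r2_one, kept_one = variance_explained(y, [g1], multi=True)
        assert len(kept_pair) == 1
        assert r2_pair == pytest.approx(r2_one, abs=1e-6)

    def test_too_few_samples_error(self):
        with pytest.raises(ValueError):
            variance_explained(np.arange(8.0), [np.arange(8.0)] * 2, multi=True)


class TestSuperiorAlleleAccounting:
    def test_maternal_fixed_superior_female_only(self):
        # maternal group fixed for the favorable allele, absent in restorers:
        # all superior F1 copies are maternal-derived
        cfg = SimulationConfig(
            n_maternal=6, n_paternal_families=2, lines_per_family=4,
            n_chromosomes=2, markers_per_chromosome=40,
            qtl_specs=[QtlSpec(1, 10_000_000, 1.0, 0.0, fixed_in="paternal")],
            h2_polygenic=0.0, residual_sd=0.0, n_replicates=1, seed=13,
        )
        parents, design, f1, table, truth = simulate_diallel(cfg)
        vals = table[table.role == "F1"].groupby("sample")["value"].mean()
        # fixed_in="paternal": restorers carry only the reference allele;
        # the trait-increasing alternate allele segregates in mothers only
        rep = superior_allele_accounting(
            truth.qtl_markers[0], vals, parents, f1, design, "higher"
        )
        assert rep.ratio_paternal == 0.0
        assert rep.contribution == "female_only"
        assert rep.maternal_derived_fraction == 1.0

    def test_counts_match_brute_force_enumeration(self, small_diallel):
        _, parents, design, f1, table, truth = small_diallel
        vals = table[table.role == "F1"].groupby("sample")["value"].mean()
        lead = truth.qtl_markers[0]
        rep = superior_allele_accounting(lead, vals, parents, f1, design, "higher")
        jp = parents.markers.index[parents.markers["id"] == lead][0]
        lookup = {s: i for i, s in enumerate(parents.samples)}
        mat_c = pat_c = tot = 0
        for _, row in design.crosses.iterrows():
            cm = parents.calls[lookup[row["mother"]], jp]
            cf = parents.calls[lookup[row["father"]], jp]
            mat_c += cm == rep.superior_call
            pat_c += cf == rep.superior_call
            tot += 2
        assert rep.ratio_f1 == pytest.approx((mat_c + pat_c) / tot)
        if mat_c + pat_c:
            assert rep.maternal_derived_fraction == pytest.approx(mat_c / (mat_c + pat_c))

    def test_invariant_to_sample_order(self, small_diallel):
        _, parents, design, f1, table, truth = small_diallel
        vals = table[table.role == "F1"].groupby("sample")["value"].mean()
        lead = truth.qtl_markers[0]
        a = superior_allele_accounting(lead, vals, parents, f1, design)
        shuffled = parents.subset_samples(list(reversed(parents.samples)))
        b = superior_allele_accounting(lead, vals, shuffled, f1, design)
        assert a == b


class TestTwoGenotypeSignature:
    def test_fixed_maternal_het_advantage_recovered(self):
        # the qualitative two-genotype signature: a QTL fixed in the
        # maternal group with heterozygote advantage is two_genotype,
        # hetero-superior, and its superior copies are paternal-derived
        hits = 0
        for seed in range(20):
            cfg = SimulationConfig(
                n_maternal=6, n_paternal_families=2, lines_per_family=5,
                n_chromosomes=2, markers_per_chromosome=40,
                qtl_specs=[QtlSpec(1, 10_000_000, 0.5, 1.5, fixed_in="maternal")],
                h2_polygenic=0.1, residual_sd=0.5, n_replicates=2, seed=seed,
            )
            parents, design, f1, table, truth = simulate_diallel(cfg)
            vals = table[table.role == "F1"].groupby("sample")["value"].mean()
            j = f1.markers.index[f1.markers["id"] == truth.qtl_markers[0]][0]
            g = pd.Series(f1.calls[:, j], index=f1.samples).reindex(vals.index)
            cls, _ = genotype_class(g.to_numpy())
            if cls != "two_genotype":
                continue
            sup, _ = superiority_class(vals.to_numpy(), g.to_numpy(), "higher")
            rep = superior_allele_accounting(
                truth.qtl_markers[0], vals, parents, f1, design, "higher"
            )
            if sup == "hetero_superior" and rep.paternal_derived_fraction == 1.0:
                hits += 1
        assert hits >= 18
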