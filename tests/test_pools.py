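"""Pool construction, association models, and the Fisher fallback."""

import itertools
from math import comb

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import integrate, stats

from famcnv.errors import ValidationError
from famcnv.intervals import GenomicInterval
from famcnv.io import Individual, Pedigree
from famcnv.merge import MergedCnv
from famcnv.mixedlogit import fit_logistic_random_intercept, marginal_loglik
from famcnv.pools import (
    MODELS,
    bonferroni_threshold,
    build_pools,
    enrichment_screen,
    fisher_one_sided,
    pool_association,
)


def mcnv(sample, start, end, cn=3, fid="F1", chrom="1"):
    return MergedCnv(
        sample_id=sample, family_id=fid,
        interval=GenomicInterval(chrom, start, end),
        state="loss" if cn < 2 else "gain", copy_number=cn, n_probes=10,
        sources=(), overlap_fraction=1.0,
    )


class TestBuildPools:
    def test_mutually_overlapping_cnvs_form_one_pool(self):
        cnvs = [mcnv("a", 1, 100), mcnv("b", 50, 150), mcnv("c", 80, 120)]
        (pool,) = build_pools(cnvs)
        assert len(pool.members) == 3

    def test_transitive_chain_closes_into_one_pool(self):
        # a overlaps b, b overlaps c, a does not touch c
        cnvs = [mcnv("a", 1, 100), mcnv("b", 90, 200), mcnv("c", 190, 300)]
        pools = build_pools(cnvs)
        assert len(pools) == 1 and len(pools[0].members) == 3

    def test_chromosomes_split_pools(self):
        cnvs = [mcnv("a", 1, 100, chrom="1"), mcnv("b", 1, 100, chrom="2")]
        assert len(build_pools(cnvs)) == 2

    def test_pools_partition_the_input(self):
        rng = np.random.default_rng(9)
        cnvs = [
            mcnv(f"s{i}", int(s), int(s) + int(rng.integers(10_000, 200_000)))
            for i, s in enumerate(rng.integers(1, 3_000_000, size=60))
        ]
        pools = build_pools(cnvs)
        seen = [m.cnv_id for p in pools for m in p.members]
        assert sorted(seen) == sorted(c.cnv_id for c in cnvs)

    def test_matches_union_find_oracle(self):
        rng = np.random.default_rng(17)
        cnvs = [
            mcnv(f"s{i}", int(s), int(s) + int(rng.integers(10_000, 300_000)))
            for i, s in enumerate(rng.integers(1, 2_000_000, size=40))
        ]
        parent = list(range(len(cnvs)))

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        for i, j in itertools.combinations(range(len(cnvs)), 2):
            if cnvs[i].interval.overlaps(cnvs[j].interval):
                parent[find(i)] = find(j)
        oracle = {}
        for i, c in enumerate(cnvs):
            oracle.setdefault(find(i), set()).add(c.cnv_id)
        got = {frozenset(m.cnv_id for m in p.members) for p in build_pools(cnvs)}
        assert got == {frozenset(v) for v in oracle.values()}


class TestFisherOneSided:
    def test_equals_hypergeometric_tail_sum(self):
        a, b, c, d = 8, 2, 12, 78
        n, r1, c1 = a + b + c + d, a + b, a + c
        exact = sum(
            comb(r1, k) * comb(n - r1, c1 - k) for k in range(a, min(r1, c1) + 1)
        ) / comb(n, c1)
        assert fisher_one_sided(a, b, c, d) == pytest.approx(exact, abs=1e-12)

    def test_matches_scipy_fisher_alternative_greater(self):
        for table in ([3, 7, 2, 8], [0, 5, 5, 0], [10, 0, 0, 10]):
            a, b, c, d = table
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
            assert fisher_one_sided(a, b, c, d) == pytest.approx(p, abs=1e-12)


class TestBonferroni:
    def test_reported_thresholds(self):
        assert float(f"{bonferroni_threshold(0.05, 535):.4g}") == 9.346e-5
        assert float(f"{bonferroni_threshold(0.05, 9):.3g}") == 5.56e-3

    def test_single_test_returns_alpha(self):
        assert bonferroni_threshold(0.013, 1) == 0.013

    def test_zero_tests_rejected(self):
        with pytest.raises(ValidationError):
            bonferroni_threshold(0.05, 0)


class TestMixedLogit:
    def test_marginal_likelihood_matches_quad_oracle(self):
        """Quadrature likelihood equals direct numerical integration."""
        rng = np.random.default_rng(0)
        groups = np.repeat(np.arange(6), 4)
        x = rng.integers(0, 2, size=24).astype(float)
        X = np.column_stack([np.ones(24), x])
        y = rng.integers(0, 2, size=24).astype(float)
        beta, sigma = np.array([-0.3, 0.8]), 0.7

        def family_integral(yf, xf):
            def integrand(u):
                eta = xf @ beta + u
                p = 1.0 / (1.0 + np.exp(-eta))
                lik = np.prod(np.where(yf == 1, p, 1 - p))
                return lik * stats.norm.pdf(u, scale=sigma)

            val, _ = integrate.quad(integrand, -8 * sigma, 8 * sigma)
            return np.log(val)

        oracle = sum(
            family_integral(y[groups == g], X[groups == g]) for g in range(6)
        )
        assert marginal_loglik(y, X, groups, beta, sigma, n_quad=40) == pytest.approx(
            oracle, abs=1e-8
        )

    def test_reduces_to_plain_logistic_without_family_effect(self):
        """With one member per family the fit matches statsmodels Logit."""
        rng = np.random.default_rng(1)
        n = 300
        x = rng.integers(0, 2, size=n).astype(float)
        eta = -0.5 + 1.2 * x
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        groups = np.arange(n)  # singleton families: sigma unidentifiable, ~0
        X = np.column_stack([np.ones(n), x])
        fit = fit_logistic_random_intercept(y, X, groups)
        ref = sm.Logit(y, X).fit(disp=0)
        assert fit.coef == pytest.approx(ref.params, abs=0.05)
        assert fit.wald_p(1) == pytest.approx(ref.pvalues[1], abs=0.02)

    def test_recovers_effect_with_family_clustering(self):
        rng = np.random.default_rng(2)
        n_fam, fam_size = 80, 5
        groups = np.repeat(np.arange(n_fam), fam_size)
        u = rng.normal(0, 1.0, size=n_fam)[groups]
        x = rng.integers(0, 2, size=n_fam * fam_size).astype(float)
        eta = -0.5 + 1.5 * x + u
        y = (rng.random(len(x)) < 1 / (1 + np.exp(-eta))).astype(float)
        X = np.column_stack([np.ones_like(x), x])
        fit = fit_logistic_random_intercept(y, X, groups)
        assert fit.converged
        assert fit.coef[1] == pytest.approx(1.5, abs=0.5)
        assert fit.sigma == pytest.approx(1.0, abs=0.5)


def cohort(n_families=40, fam_size=5, carrier_rate=0.3, seed=0,
           carrier_or=1.0):
    rng = np.random.default_rng(seed)
    individuals, cnvs = [], []
    for f in range(n_families):
        fid = f"F{f}"
        for i in range(fam_size):
            iid = f"{fid}S{i}"
            carrier = rng.random() < carrier_rate
            eta = -0.4 + np.log(carrier_or) * carrier
            affected = rng.random() < 1 / (1 + np.exp(-eta))
            individuals.append(
                Individual(iid, fid, None, None, "male",
                           "affected" if affected else "unaffected")
            )
            if carrier:
                cnvs.append(mcnv(iid, 10_000, 80_000, fid=fid))
    return Pedigree(individuals), cnvs


class TestPoolAssociation:
    def test_degenerate_all_carrier_pool_falls_back_to_fisher(self):
        ped, _ = cohort(n_families=10)
        cnvs = [mcnv(i.individual_id, 1_000, 50_000, fid=i.family_id) for i in ped]
        (pool,) = build_pools(cnvs)
        res = pool_association(pool, ped, "dup_vs_normal")
        assert res.method == "fisher_one_sided" and not res.converged
        assert res.p_value == pytest.approx(1.0)

    def test_planted_enrichment_is_detected(self):
        ped, cnvs = cohort(n_families=60, carrier_or=20.0, seed=3)
        (pool,) = build_pools(cnvs)
        res = pool_association(pool, ped, "dup_vs_normal")
        assert res.p_value < 0.001
        assert res.estimate > 0

    def test_no_phenotype_variation_rejected(self):
        individuals = [Individual(f"S{i}", "F1", None, None, "male", "affected")
                       for i in range(4)]
        ped = Pedigree(individuals)
        cnvs = [mcnv("S0", 1_000, 50_000)]
        with pytest.raises(ValidationError, match="variation"):
            pool_association(build_pools(cnvs)[0], ped, "dup_vs_normal")

    def test_pc_covariate_mode_uses_plain_logistic(self):
        ped, cnvs = cohort(n_families=40, carrier_or=8.0, seed=4)
        rng = np.random.default_rng(8)
        pcs = {i.individual_id: tuple(rng.normal(0, 0.01, size=2)) for i in ped}
        (pool,) = build_pools(cnvs)
        res = pool_association(pool, ped, "dup_vs_normal", covariate_pcs=pcs)
        assert res.method == "pc_adjusted_logistic"
        assert res.p_value < 0.01


class TestEnrichmentScreen:
    def test_zero_pools_gives_empty_table(self):
        ped, _ = cohort(n_families=5)
        table = enrichment_screen([], ped)
        assert table.empty

    def test_all_models_reported_per_pool(self):
        ped, cnvs = cohort(n_families=30, seed=6)
        cnvs.append(mcnv(cnvs[0].sample_id, 5_000_000, 5_100_000, cn=1,
                         fid=cnvs[0].family_id))
        pools = build_pools(cnvs)
        table = enrichment_screen(pools, ped)
        assert len(table) == len(pools) * len(MODELS)
        assert set(table["model"]) == set(MODELS)
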