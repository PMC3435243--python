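"""Rank fusion, SAGE folds, evidence profiles, and gene-set enrichment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famcnv.datasets import candidate_evidence_table
from famcnv.errors import ValidationError
from famcnv.intervals import GenomicInterval
from famcnv.io import Individual, Pedigree, TrackRecord
from famcnv.merge import MergedCnv
from famcnv.prioritize import (
    build_evidence_profiles,
    fuse_rankings,
    geneset_enrichment_test,
    intersect_genes,
    order_statistic_q,
    sage_fold,
    syndromic_overlap_report,
)


def mcnv(sample, start, end, cn=3, fid="F1", chrom="1"):
    return MergedCnv(
        sample_id=sample, family_id=fid,
        interval=GenomicInterval(chrom, start, end),
        state="loss" if cn < 2 else "gain", copy_number=cn, n_probes=10,
        sources=(), overlap_fraction=1.0,
    )


def gene(start, end, name, chrom="1"):
    return TrackRecord(GenomicInterval(chrom, start, end), name)


class TestIntersectGenes:
    def test_contained_gene_pairs(self):
        pairs = intersect_genes([mcnv("s", 1, 1_000_000)],
                                [gene(5_000, 10_000, "G1")])
        assert [(c.sample_id, g.name) for c, g in pairs] == [("s", "G1")]

    def test_single_base_overlap_counts(self):
        pairs = intersect_genes([mcnv("s", 1_000, 2_000)], [gene(2_000, 3_000, "G1")])
        assert len(pairs) == 1

    def test_intergenic_cnv_has_no_pairs(self):
        assert intersect_genes([mcnv("s", 1, 1_000)], [gene(5_000, 6_000, "G1")]) == []


class TestOrderStatisticQ:
    def test_single_source_identity(self):
        assert order_statistic_q([0.37]) == pytest.approx(0.37)

    def test_full_support_gives_one(self):
        for k in (1, 2, 3, 5):
            assert order_statistic_q([1.0] * k) == pytest.approx(1.0)

    def test_matches_monte_carlo_joint_probability(self):
        """Q equals P(U_(i) <= r_i for all i) for iid uniforms."""
        rng = np.random.default_rng(0)
        n = 200_000
        for ratios in ([0.1, 0.2], [0.05, 0.3, 0.6], [0.2, 0.3, 0.5, 0.7, 0.9]):
            k = len(ratios)
            draws = np.sort(rng.uniform(size=(n, k)), axis=1)
            hit = np.all(draws <= np.asarray(ratios), axis=1)
            mc = hit.mean()
            se = np.sqrt(mc * (1 - mc) / n)
            assert abs(order_statistic_q(ratios) - mc) < 3 * se + 1e-9

    @given(
        st.lists(st.floats(0.01, 1.0), min_size=2, max_size=5),
        st.integers(0, 4),
        st.floats(0.1, 0.9),
    )
    @settings(max_examples=150, deadline=None)
    def test_monotone_in_each_ratio(self, ratios, index, shrink):
        index = index % len(ratios)
        smaller = list(ratios)
        smaller[index] = smaller[index] * shrink
        q_small = order_statistic_q(smaller)
        q_big = order_statistic_q(ratios)
        assert q_small <= q_big + 1e-9

    def test_ratio_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError):
            order_statistic_q([0.0, 0.5])
        with pytest.raises(ValidationError):
            order_statistic_q([0.5, 1.5])


def score_frame(scores_by_gene, sources=3):
    rows = []
    for g, vals in scores_by_gene.items():
        for s in range(sources):
            rows.append({"gene": g, "source": f"src{s}", "score": vals[s]})
    return pd.DataFrame(rows)


class TestFuseRankings:
    def test_dominant_gene_has_smallest_p(self):
        rng = np.random.default_rng(1)
        table = {f"g{i}": list(rng.normal(size=3)) for i in range(99)}
        table["winner"] = [10.0, 10.0, 10.0]
        fused = fuse_rankings(score_frame(table), n_null=2000, seed=0)
        best = fused.sort_values("fusion_p").iloc[0]
        assert best["gene"] == "winner"

    def test_null_scores_give_uniform_p(self):
        rng = np.random.default_rng(2)
        table = {f"g{i}": list(rng.normal(size=3)) for i in range(200)}
        fused = fuse_rankings(score_frame(table), n_null=5000, seed=1)
        from scipy import stats

        ks = stats.kstest(fused["fusion_p"], "uniform")
        assert ks.pvalue > 0.01

    def test_tied_genes_share_p(self):
        table = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [0.0, 0.0, 0.0]}
        fused = fuse_rankings(score_frame(table), n_null=1000, seed=2)
        by_gene = fused.set_index("gene")["fusion_p"]
        assert by_gene["a"] == by_gene["b"]

    def test_calibration_floor_enforced(self):
        with pytest.raises(ValidationError, match="floor"):
            fuse_rankings(score_frame({"a": [1, 2, 3], "b": [3, 2, 1]}), n_null=10)


def sage_rows(ot, atrium, ventricle, lib=100_000, gene="g"):
    return pd.DataFrame(
        [
            {"gene": gene, "compartment": "outflow_tract", "tag_count": ot,
             "library_size": lib},
            {"gene": gene, "compartment": "atrium", "tag_count": atrium,
             "library_size": lib},
            {"gene": gene, "compartment": "ventricle", "tag_count": ventricle,
             "library_size": lib},
        ]
    )


class TestSageFold:
    def test_equal_expression_gives_fold_one(self):
        assert sage_fold(sage_rows(50, 50, 50)) == pytest.approx(1.0)

    def test_threefold_boundary_passes_inclusively(self):
        # tpm-with-pseudocount ratio is exactly 3 when (ot+1) = 3 * (chamber+1)
        fold = sage_fold(sage_rows(29, 9, 9))
        assert fold == pytest.approx(3.0)

    def test_zero_tags_handled_by_pseudocount(self):
        assert sage_fold(sage_rows(0, 0, 0)) == pytest.approx(1.0)

    def test_scale_invariance_under_library_size(self):
        f1 = sage_fold(sage_rows(300, 100, 100, lib=100_000))
        f2 = sage_fold(sage_rows(3000, 1000, 1000, lib=1_000_000))
        assert f1 == pytest.approx(f2, rel=0.01)

    def test_missing_compartment_rejected(self):
        rows = sage_rows(10, 10, 10)
        with pytest.raises(ValidationError, match="compartment"):
            sage_fold(rows[rows["compartment"] != "atrium"])

    def test_max_comparator_is_more_conservative(self):
        rows = sage_rows(300, 10, 100)
        assert sage_fold(rows, comparator="max") <= sage_fold(rows, comparator="mean")


class TestEvidenceProfiles:
    def test_two_of_three_rule(self):
        profiles = build_evidence_profiles(
            ["strong", "mixed", "weak"],
            fusion_p={"strong": 0.000122, "mixed": 0.17, "weak": 0.2},
            sage_folds={"strong": 8.15, "mixed": 27.85},
            flags={"strong": "-", "mixed": "+", "weak": "+"},
        )
        by_gene = {p.gene: p for p in profiles}
        assert by_gene["strong"].candidate  # p + SAGE
        assert by_gene["mixed"].candidate  # SAGE + flag
        assert not by_gene["weak"].candidate  # flag only, SAGE absent

    def test_published_candidate_table_verdicts(self):
        table = candidate_evidence_table()
        profiles = build_evidence_profiles(
            list(table["gene"]),
            fusion_p=dict(zip(table["gene"], table["fusion_p"])),
            sage_folds={
                r["gene"]: r["sage_fold"]
                for _, r in table.iterrows()
                if pd.notna(r["sage_fold"])
            },
            flags={
                r["gene"]: r["expression_flag"]
                for _, r in table.iterrows()
                if pd.notna(r["expression_flag"])
            },
            expected_candidate={g: True for g in table["gene"]},
        )
        assert len(profiles) == 25
        assert all(p.candidate for p in profiles)
        assert not any(p.verdict_mismatch for p in profiles)

    def test_contradicted_expectation_is_flagged(self):
        (profile,) = build_evidence_profiles(
            ["g"], {"g": 0.9}, {}, {"g": "+"}, expected_candidate={"g": True}
        )
        assert not profile.candidate and profile.verdict_mismatch


def geneset_cohort(seed, enrich=False, n_families=50, fam_size=4):
    rng = np.random.default_rng(seed)
    genes = [gene(1 + i * 1_000_000, 100_000 + i * 1_000_000, f"G{i}")
             for i in range(40)]
    gene_set = [f"G{i}" for i in range(10)]
    individuals, cnvs = [], []
    for f in range(n_families):
        fid = f"F{f}"
        for i in range(fam_size):
            iid = f"{fid}s{i}"
            affected = rng.random() < 0.4
            individuals.append(
                Individual(iid, fid, None, None, "male",
                           "affected" if affected else "unaffected")
            )
            rate = 2.0
            n_set = rng.poisson(rate * (2.0 if (enrich and affected) else 1.0) * 0.5)
            n_other = rng.poisson(rate)
            for _ in range(n_set):
                g = int(rng.integers(0, 10))
                cnvs.append(mcnv(iid, 1 + g * 1_000_000, 90_000 + g * 1_000_000,
                                 fid=fid))
            for _ in range(n_other):
                g = int(rng.integers(10, 40))
                cnvs.append(mcnv(iid, 1 + g * 1_000_000, 90_000 + g * 1_000_000,
                                 fid=fid))
    return Pedigree(individuals), cnvs, genes, gene_set


class TestGenesetEnrichment:
    def test_disjoint_set_gives_null_result(self):
        ped, cnvs, genes, _ = geneset_cohort(3)
        with pytest.warns(UserWarning, match="absent"):
            res = geneset_enrichment_test(
                cnvs, ped, ["NOT_A_GENE"], genes, n_perm=50, seed=0
            )
        assert res["coef"] == 0.0 and res["p_empirical"] == pytest.approx(1.0)

    def test_planted_enrichment_detected(self):
        ped, cnvs, genes, gene_set = geneset_cohort(4, enrich=True)
        res = geneset_enrichment_test(cnvs, ped, gene_set, genes,
                                      n_perm=500, seed=1)
        assert res["p_empirical"] < 0.05
        assert res["direction"] > 0

    def test_null_set_not_flagged(self):
        ped, cnvs, genes, gene_set = geneset_cohort(5, enrich=False)
        res = geneset_enrichment_test(cnvs, ped, gene_set, genes,
                                      n_perm=300, seed=2)
        assert res["p_empirical"] > 0.05


class TestSyndromicOverlap:
    def test_contained_cnv_reports_full_fraction(self):
        cnv = mcnv("s", 10_000, 20_000)
        locus = TrackRecord(GenomicInterval("1", 1, 1_000_000), "syndromeA")
        table = syndromic_overlap_report([cnv], [locus])
        assert table.loc[0, "of_cnv"] == pytest.approx(1.0)

    def test_no_overlap_gives_empty_table(self):
        cnv = mcnv("s", 10_000, 20_000)
        locus = TrackRecord(GenomicInterval("2", 1, 1_000_000), "syndromeA")
        assert syndromic_overlap_report([cnv], [locus]).empty

    def test_cnv_spanning_two_loci_yields_two_rows(self):
        cnv = mcnv("s", 1, 3_000_000)
        loci = [TrackRecord(GenomicInterval("1", 10, 20), "a"),
                TrackRecord(GenomicInterval("1", 2_000_000, 2_500_000), "b")]
        assert len(syndromic_overlap_report([cnv], loci)) == 2
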