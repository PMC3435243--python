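"""Pooled CNV region association.

Overlapping merged CNVs are pooled into loci (connected components of the
>=1 bp interval-overlap graph, one pool per component), and each pool is
tested for enrichment of carriers among affected individuals under three
copy-state models: duplications versus the normal state, deletions versus
normal, and either versus normal.  The primary test is a logistic regression
of affection on a carrier indicator with a family random intercept
(:mod:`famcnv.mixedlogit`); pools where the fit does not converge fall back
to a one-sided Fisher exact test on the 2x2 carrier-by-phenotype table.  When
per-sample principal-component coordinates are supplied (the external
control-cohort contrast), the family random effect is replaced by the two
fixed PC covariates in a plain logistic regression.

Multiple testing is reported at the nominal 0.05 level and at the Bonferroni
threshold over the number of pools; the ``pools x models`` denominator is
printed alongside because the test-count convention is ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ValidationError
from .intervals import GenomicInterval, chrom_sort_key
from .io import Pedigree
from .merge import MergedCnv
from .mixedlogit import fit_logistic_random_intercept

Model = Literal["dup_vs_normal", "del_vs_normal", "any_vs_normal"]
MODELS: tuple[Model, ...] = ("dup_vs_normal", "del_vs_normal", "any_vs_normal")
_MODEL_STATES = {"dup_vs_normal": {"gain"}, "del_vs_normal": {"loss"},
                 "any_vs_normal": {"gain", "loss"}}


@dataclass
class CnvPool:
    pool_id: str
    envelope: GenomicInterval
    members: list[MergedCnv]

    def carriers(self, model: Model) -> set[str]:
        states = _MODEL_STATES[model]
        return {m.sample_id for m in self.members if m.state in states}


@dataclass
class EnrichmentResult:
    pool_id: str
    model: Model
    estimate: float
    p_value: float
    method: Literal["random_effect_logistic", "pc_adjusted_logistic", "fisher_one_sided"]
    converged: bool
    n_carriers: int = 0
    n_affected_carriers: int = 0


def build_pools(cnvs: Sequence[MergedCnv]) -> list[CnvPool]:
    """Group CNVs into pools of transitively overlapping segments.

    Implemented as a per-chromosome sweep: sorting by start, a new pool begins
    whenever a segment starts beyond the running envelope end, which yields
    exactly the connected components of the >=1 bp overlap graph.
    """
    by_chrom: dict[str, list[MergedCnv]] = {}
    for c in cnvs:
        by_chrom.setdefault(c.interval.chrom, []).append(c)
    pools: list[CnvPool] = []
    for chrom in sorted(by_chrom, key=chrom_sort_key):
        segs = sorted(by_chrom[chrom], key=lambda c: (c.interval.start, c.interval.end))
        current: list[MergedCnv] = []
        env_end = -1
        for seg in segs:
            if current and seg.interval.start > env_end:
                pools.append(_finalize_pool(current, len(pools)))
                current = []
                env_end = -1
            current.append(seg)
            env_end = max(env_end, seg.interval.end)
        if current:
            pools.append(_finalize_pool(current, len(pools)))
    return pools


def _finalize_pool(members: list[MergedCnv], index: int) -> CnvPool:
    chrom = members[0].interval.chrom
    envelope = GenomicInterval(
        chrom, min(m.interval.start for m in members), max(m.interval.end for m in members)
    )
    return CnvPool(pool_id=f"P{index + 1:04d}", envelope=envelope, members=list(members))


def fisher_one_sided(a: int, b: int, c: int, d: int) -> float:
    """One-sided Fisher exact p for enrichment of carriers among affecteds.

    Table rows are carriers/non-carriers, columns affected/unaffected:
    ``[[a, b], [c, d]]``; the alternative is that carriers are enriched in the
    affected column, i.e. the upper hypergeometric tail P(X >= a).
    """
    a = np.asarray(a)
    total = a + b + c + d
    return stats.hypergeom.sf(a - 1, total, a + b, a + c)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Bonferroni-corrected per-test significance threshold ``alpha / m``."""
    if not 0 < alpha <= 1:
        raise ValidationError("alpha must be in (0, 1]")
    if m < 1:
        raise ValidationError("number of tests must be >= 1")
    return alpha / m


def pool_association(
    pool: CnvPool,
    pedigree: Pedigree,
    model: Model,
    covariate_pcs: Mapping[str, tuple[float, float]] | None = None,
    use_lrt: bool = False,
) -> EnrichmentResult:
    """Test one pool under one copy-state model.

    Returns a Wald p-value from the random-effects fit (or a likelihood-ratio
    p when ``use_lrt``); when the fit fails to converge, or the carrier
    indicator is constant, the one-sided Fisher exact fallback is used (a
    fully degenerate table yields p = 1).
    """
    phenotyped = pedigree.phenotyped()
    if not phenotyped:
        raise ValidationError("no phenotyped samples")
    y = np.array([1.0 if i.phenotype == "affected" else 0.0 for i in phenotyped])
    if y.min() == y.max():
        raise ValidationError("no variation in phenotype")
    carriers = pool.carriers(model)
    x = np.array([1.0 if i.individual_id in carriers else 0.0 for i in phenotyped])
    groups = np.array([i.family_id for i in phenotyped])

    a = int(((x == 1) & (y == 1)).sum())
    b = int(((x == 1) & (y == 0)).sum())
    c = int(((x == 0) & (y == 1)).sum())
    d = int(((x == 0) & (y == 0)).sum())

    def fisher_result() -> EnrichmentResult:
        return EnrichmentResult(
            pool_id=pool.pool_id, model=model, estimate=np.nan,
            p_value=float(fisher_one_sided(a, b, c, d)), method="fisher_one_sided",
            converged=False, n_carriers=a + b, n_affected_carriers=a,
        )

    if x.min() == x.max():  # no variation in the predictor
        return fisher_result()

    if covariate_pcs is not None:
        pcs = np.array(
            [covariate_pcs.get(i.individual_id, (0.0, 0.0)) for i in phenotyped]
        )
        X = np.column_stack([np.ones_like(x), x, pcs])
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
            ok = bool(fit.mle_retvals.get("converged", False)) and np.all(
                np.isfinite(fit.bse)
            ) and abs(fit.params[1]) < 15.0
        except Exception:
            ok = False
        if not ok:
            return fisher_result()
        return EnrichmentResult(
            pool_id=pool.pool_id, model=model, estimate=float(fit.params[1]),
            p_value=float(fit.pvalues[1]), method="pc_adjusted_logistic",
            converged=True, n_carriers=a + b, n_affected_carriers=a,
        )

    X = np.column_stack([np.ones_like(x), x])
    fit = fit_logistic_random_intercept(y, X, groups)
    if not fit.converged:
        return fisher_result()
    if use_lrt:
        null_fit = fit_logistic_random_intercept(y, X[:, :1], groups)
        lr = max(0.0, 2.0 * (fit.loglik - null_fit.loglik))
        p = float(stats.chi2.sf(lr, df=1))
    else:
        p = fit.wald_p(1)
    return EnrichmentResult(
        pool_id=pool.pool_id, model=model, estimate=float(fit.coef[1]),
        p_value=p, method="random_effect_logistic", converged=True,
        n_carriers=a + b, n_affected_carriers=a,
    )


def enrichment_screen(
    pools: Sequence[CnvPool],
    pedigree: Pedigree,
    covariate_pcs: Mapping[str, tuple[float, float]] | None = None,
    alpha: float = 0.05,
    use_lrt: bool = False,
) -> pd.DataFrame:
    """All three models for every pool, ranked by p-value.

    The significance columns use the Bonferroni threshold over the number of
    pools (``sig_bonferroni_pools``) and over pools x models
    (``sig_bonferroni_tests``).
    """
    rows = []
    for pool in pools:
        for model in MODELS:
            r = pool_association(pool, pedigree, model, covariate_pcs, use_lrt)
            rows.append(
                {
                    "pool_id": r.pool_id,
                    "chrom": pool.envelope.chrom,
                    "start": pool.envelope.start,
                    "end": pool.envelope.end,
                    "model": r.model,
                    "estimate": r.estimate,
                    "p_value": r.p_value,
                    "method": r.method,
                    "converged": r.converged,
                    "n_carriers": r.n_carriers,
                    "n_affected_carriers": r.n_affected_carriers,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "pool_id", "chrom", "start", "end", "model", "estimate", "p_value",
            "method", "converged", "n_carriers", "n_affected_carriers",
        ],
    )
    if table.empty:
        for col in ("sig_nominal", "sig_bonferroni_pools", "sig_bonferroni_tests"):
            table[col] = pd.Series(dtype=bool)
        return table
    thr_pools = bonferroni_threshold(alpha, max(1, len(pools)))
    thr_tests = bonferroni_threshold(alpha, max(1, len(pools) * len(MODELS)))
    table["sig_nominal"] = table["p_value"] < alpha
    table["sig_bonferroni_pools"] = table["p_value"] < thr_pools
    table["sig_bonferroni_tests"] = table["p_value"] < thr_tests
    return table.sort_values("p_value", kind="stable").reset_index(drop=True)
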