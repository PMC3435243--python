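"""Affected-versus-unaffected CNV burden with family-aware permutation tests.

Burden metrics per sample: number of merged autosomal segments, mean segment
size, number of distinct genes intersected (a gene counts once per sample no
matter how many CNVs hit it), and deletion/duplication counts.  Group
differences are tested by permuting phenotype labels *within* families, which
preserves every family's affected count and hence respects relatedness
without distributional assumptions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .intervals import is_autosome
from .io import Pedigree, TrackRecord
from .merge import MergedCnv

METRICS = ("n_segments", "mean_segment_size", "n_genes", "n_deletions", "n_duplications")


@dataclass
class BurdenSummary:
    per_sample: pd.DataFrame
    group_means: pd.DataFrame  # metric x {affected, unaffected}
    p_values: dict[str, float]
    n_permutations: int


def per_sample_burden(
    cnvs: Sequence[MergedCnv],
    samples: Sequence[str],
    gene_track: Sequence[TrackRecord] = (),
) -> pd.DataFrame:
    """Per-sample burden metrics over autosomal CNVs.

    Samples without calls appear with zero counts; their ``mean_segment_size``
    is NaN and is excluded from group means of that metric.
    """
    by_sample: dict[str, list[MergedCnv]] = {s: [] for s in samples}
    for cnv in cnvs:
        if not is_autosome(cnv.interval.chrom):
            continue
        if cnv.sample_id in by_sample:
            by_sample[cnv.sample_id].append(cnv)
    rows = []
    for sample in samples:
        calls = by_sample[sample]
        sizes = [c.interval.length for c in calls]
        genes = {
            g.name
            for c in calls
            for g in gene_track
            if g.interval.overlaps(c.interval)
        }
        rows.append(
            {
                "sample_id": sample,
                "n_segments": len(calls),
                "mean_segment_size": float(np.mean(sizes)) if sizes else np.nan,
                "n_genes": len(genes),
                "n_deletions": sum(1 for c in calls if c.state == "loss"),
                "n_duplications": sum(1 for c in calls if c.state == "gain"),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def _within_family_permutation(
    labels: np.ndarray, family_slices: list[np.ndarray], rng: np.random.Generator
) -> np.ndarray:
    permuted = labels.copy()
    for idx in family_slices:
        permuted[idx] = permuted[idx][rng.permutation(len(idx))]
    return permuted


def burden_summary(
    cnvs: Sequence[MergedCnv],
    pedigree: Pedigree,
    gene_track: Sequence[TrackRecord] = (),
    n_permutations: int = 10_000,
    seed: int = 0,
) -> BurdenSummary:
    """Compare burden between affected and unaffected pedigree members.

    Two-sided permutation p-values per metric; the statistic is the difference
    of group means and labels are shuffled only within families.  p-values use
    the add-one estimator ``(1 + #{|T*| >= |T|}) / (n_perm + 1)``.
    """
    phenotyped = [i for i in pedigree.phenotyped()]
    samples = [i.individual_id for i in phenotyped]
    labels = np.array([1 if i.phenotype == "affected" else 0 for i in phenotyped])
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise ValidationError("both phenotype groups must be non-empty")
    families = np.array([i.family_id for i in phenotyped])
    family_slices = [np.flatnonzero(families == f) for f in np.unique(families)]

    per_sample = per_sample_burden(cnvs, samples, gene_track)
    values = {m: per_sample[m].to_numpy(dtype=float) for m in METRICS}

    def diff_of_means(metric_values: np.ndarray, lab: np.ndarray) -> float:
        a = metric_values[lab == 1]
        u = metric_values[lab == 0]
        return float(np.nanmean(a) - np.nanmean(u)) if len(a) and len(u) else 0.0

    rng = np.random.default_rng(seed)
    observed = {m: diff_of_means(values[m], labels) for m in METRICS}
    exceed = {m: 0 for m in METRICS}
    for _ in range(n_permutations):
        permuted = _within_family_permutation(labels, family_slices, rng)
        for m in METRICS:
            if abs(diff_of_means(values[m], permuted)) >= abs(observed[m]) - 1e-12:
                exceed[m] += 1
    p_values = {m: (1 + exceed[m]) / (n_permutations + 1) for m in METRICS}

    group_means = pd.DataFrame(
        {
            "affected": {m: float(np.nanmean(values[m][labels == 1])) for m in METRICS},
            "unaffected": {m: float(np.nanmean(values[m][labels == 0])) for m in METRICS},
        }
    )
    group_means.loc["n", :] = [int(labels.sum()), int((1 - labels).sum())]
    return BurdenSummary(
        per_sample=per_sample,
        group_means=group_means,
        p_values=p_values,
        n_permutations=n_permutations,
    )
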