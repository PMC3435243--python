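"""Sample-level quality control and the cohort phenotype summary.

Two exclusion rules operate at the sample level: an excessive-call rule
(samples with more CNV calls than ``mean + k*sd`` of the cohort distribution
are dropped, k = 3 by default) and an ancestry oval rule that removes samples
falling outside an ellipse in precomputed principal-component space whose
semi-axes are ``factor`` times the reference-cluster standard deviations
(factor = 10 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import Pedigree, round_half_away


@dataclass
class QcReport:
    counts: dict[str, int]
    mean: float
    sd: float
    k: float
    threshold: float
    excluded_samples: list[str] = field(default_factory=list)

    @property
    def retained_samples(self) -> list[str]:
        return [s for s in self.counts if s not in set(self.excluded_samples)]


@dataclass(frozen=True)
class OvalFilterSpec:
    """Ellipse in a 2-D projected PC space."""

    center: tuple[float, float]
    axis_sd: tuple[float, float]
    factor: float = 10.0

    def __post_init__(self) -> None:
        if self.axis_sd[0] <= 0 or self.axis_sd[1] <= 0:
            raise ValidationError("axis_sd must be positive")
        if self.factor <= 0:
            raise ValidationError("factor must be positive")


def exclude_outlier_samples(counts: Mapping[str, int], k: float = 3.0) -> QcReport:
    """Exclude samples with call counts strictly above ``mean + k*sd``.

    The standard deviation uses the n-1 denominator.  The boundary itself is
    retained ("above" is read strictly).
    """
    if len(counts) < 2:
        raise ValidationError("need at least 2 samples to estimate a threshold")
    values = np.asarray(list(counts.values()), dtype=float)
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    threshold = mean + k * sd
    excluded = sorted(s for s, c in counts.items() if c > threshold)
    return QcReport(
        counts=dict(counts), mean=mean, sd=sd, k=k, threshold=threshold,
        excluded_samples=excluded,
    )


def oval_outlier_filter(
    points: Mapping[str, tuple[float, float]], spec: OvalFilterSpec
) -> tuple[list[str], list[str]]:
    """Partition samples into (retained, removed) by the ancestry oval.

    A sample is removed iff
    ``sum_i ((x_i - center_i) / (factor * axis_sd_i))**2 > 1``.
    """
    retained, removed = [], []
    for sample in sorted(points):
        x, y = points[sample]
        d = ((x - spec.center[0]) / (spec.factor * spec.axis_sd[0])) ** 2 + (
            (y - spec.center[1]) / (spec.factor * spec.axis_sd[1])
        ) ** 2
        (removed if d > 1.0 else retained).append(sample)
    return retained, removed


def summarize_phenotypes(
    pedigree: Pedigree,
    lesion_table: Mapping[str, str],
    category_order: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Lesion-category counts with percentages, plus cohort-level fractions.

    Percentages are relative to the number of affected individuals and rounded
    half away from zero to one decimal.  Affected individuals missing from
    ``lesion_table`` are counted as ``uncategorized`` (with a warning entry in
    the returned stats rather than an error).  Cohort fractions are reported
    against all phenotyped individuals.
    """
    affected = pedigree.affected()
    n_affected = len(affected)
    if n_affected == 0:
        raise ValidationError("no affected individuals to summarize")
    counts: dict[str, int] = {}
    n_uncategorized = 0
    for ind in affected:
        cat = lesion_table.get(ind.individual_id)
        if cat is None:
            n_uncategorized += 1
            cat = "uncategorized"
        counts[cat] = counts.get(cat, 0) + 1
    categories = list(category_order) if category_order is not None else sorted(counts)
    for cat in counts:
        if cat not in categories:
            categories.append(cat)
    table = pd.DataFrame(
        {
            "category": categories,
            "count": [counts.get(c, 0) for c in categories],
        }
    )
    table["percent"] = [
        round_half_away(100.0 * c / n_affected, 1) for c in table["count"]
    ]

    phenotyped = pedigree.phenotyped()
    n_total = len(phenotyped)
    n_female = sum(1 for i in phenotyped if i.sex == "female")
    stats = {
        "n_affected": float(n_affected),
        "n_unaffected": float(len(pedigree.unaffected())),
        "n_phenotyped": float(n_total),
        "affected_percent": round_half_away(100.0 * n_affected / n_total, 1),
        "female_percent": round_half_away(100.0 * n_female / n_total, 1),
        "n_uncategorized": float(n_uncategorized),
    }
    return table, stats


def carrier_fraction(n_carriers: int, n_affected: int) -> float:
    """Percent of affected individuals carrying a fully filtered CNV."""
    if n_affected <= 0:
        raise ValidationError("n_affected must be positive")
    return round_half_away(100.0 * n_carriers / n_affected, 1)
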