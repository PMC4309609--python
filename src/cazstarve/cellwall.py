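"""Cell-wall monosaccharide composition analysis.

Acid hydrolysis of isolated cell walls yields four monomers — glucosamine
(from chitin/chitosan), galactose, glucose and mannose — quantified in mole
percent of total carbohydrate.  Strain/time comparisons use a two-sample t
test on replicate mole-percent values; the pooled (Student) variant is the
default because the study's biological n of 2 leaves Welch with unstable
degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .corpus import CompositionSample

__all__ = ["CompositionComparison", "composition_normalize", "compare_composition"]


@dataclass(frozen=True)
class CompositionComparison:
    monomer: str
    mean_a: float
    mean_b: float
    t: float
    df: float
    p: float
    significant: bool


def composition_normalize(raw_amounts: Sequence[float]) -> np.ndarray:
    """Convert raw monomer amounts to mole-percent fractions summing to 100."""
    amounts = np.asarray(raw_amounts, dtype=float)
    if np.any(amounts < 0):
        raise ValueError("monomer amounts must be non-negative")
    total = amounts.sum()
    if total <= 0:
        raise ValueError("at least one monomer amount must be positive")
    return 100.0 * amounts / total


def _extract(samples: Sequence[CompositionSample], monomer: str) -> np.ndarray:
    if monomer not in CompositionSample.MONOMERS:
        raise ValueError(f"unknown monomer {monomer!r}")
    return np.array([s.fractions[monomer] for s in samples], dtype=float)


def compare_composition(
    samples_a: Sequence[CompositionSample],
    samples_b: Sequence[CompositionSample],
    monomer: str,
    test: str = "student",
    alpha: float = 0.05,
) -> CompositionComparison:
    """Two-sample t test on one monomer's mole-percent between two groups.

    ``test='student'`` pools the variances (default); ``test='welch'`` uses
    the Satterthwaite approximation.  Identical zero-variance groups give
    t = 0, p = 1.
    """
    if test not in ("student", "welch"):
        raise ValueError(f"unsupported test {test!r}")
    a = _extract(samples_a, monomer)
    b = _extract(samples_b, monomer)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 replicates per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        t_stat, df, p = 0.0, float(len(a) + len(b) - 2), 1.0
    else:
        res = stats.ttest_ind(a, b, equal_var=(test == "student"))
        df = float(len(a) + len(b) - 2) if test == "student" else float(res.df)
        t_stat, p = float(res.statistic), float(res.pvalue)
    return CompositionComparison(
        monomer=monomer,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        t=t_stat,
        df=df,
        p=p,
        significant=bool(p < alpha),
    )
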