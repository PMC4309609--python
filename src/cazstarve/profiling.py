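"""Expression normalization, fold changes, differential testing and clustering.

All expression values are on the reference-gene scale: percent of the actin
(actA) signal measured during exponential growth of the same strain.  Fold
changes compare a starvation timepoint to the same strain's exponential-phase
baseline, mirroring the "n-fold increase" convention of the source study.

Hierarchical clustering offers the two agglomeration schemes used for the
published heatmaps — McQuitty/WPGMA and Ward minimum-variance — implemented
with the Lance–Williams recurrence and a deterministic lexicographic
tie-break so that merge order is reproducible across platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .corpus import CONDITION_LABELS, STARVATION_TIMEPOINTS, STRAINS, ExpressionMatrix

__all__ = [
    "EXPRESSION_FLOOR",
    "CLUSTER_PSEUDOCOUNT",
    "expressed",
    "normalize_to_reference",
    "fold_change",
    "round_fold",
    "fold_change_table",
    "welch_t_test",
    "bh_fdr",
    "differential_table",
    "Dendrogram",
    "hierarchical_cluster",
    "leaf_order",
    "to_newick",
]

#: Minimum normalized expression treated as "expressed" (% of actA); the
#: comparison is inclusive because the printed table uses this value for
#: minimally expressed genes.
EXPRESSION_FLOOR = 0.2

#: Pseudocount added before the log2 transform used for clustering; half the
#: expression floor, chosen to tame zeros without dominating floor-level cells.
CLUSTER_PSEUDOCOUNT = 0.1


def expressed(value: float, floor: float = EXPRESSION_FLOOR) -> bool:
    """True iff a normalized expression value reaches the floor (inclusive)."""
    if value < 0:
        raise ValueError("expression values are non-negative")
    return value >= floor


def normalize_to_reference(
    raw: pd.DataFrame, reference_gene: str, per_strain: bool = True
) -> ExpressionMatrix:
    """Rescale a raw genes x conditions matrix to % of the reference gene.

    ``value' = 100 * value / ref_exp(strain)`` where ``ref_exp`` is the
    reference gene's exponential-phase value (per strain, or a single global
    value when ``per_strain`` is false).  The reference gene's own
    exponential cell maps to 100.
    """
    if reference_gene not in raw.index:
        raise ValueError(f"reference gene {reference_gene!r} absent from matrix")
    out = raw.copy().astype(float)
    if per_strain:
        for strain in STRAINS:
            ref = float(raw.at[reference_gene, f"{strain}_exp"])
            if ref <= 0:
                raise ValueError(
                    f"reference gene has non-positive exponential value in {strain}"
                )
            cols = [c for c in CONDITION_LABELS if c.startswith(f"{strain}_")]
            out[cols] = 100.0 * raw[cols] / ref
    else:
        ref = float(raw.at[reference_gene, "wt_exp"])
        if ref <= 0:
            raise ValueError("reference gene has non-positive exponential value in wt")
        out = 100.0 * raw / ref
    return ExpressionMatrix(out)


def fold_change(
    matrix: ExpressionMatrix,
    gene: str,
    strain: str,
    timepoint: str,
    baseline: str = "exp",
) -> float:
    """Ratio of a gene's value at ``timepoint`` to its ``baseline`` value.

    Returns ``nan`` (flagged undefined) when the baseline is zero; callers
    exclude such genes from summaries.
    """
    base = matrix.value(gene, strain, baseline)
    if base == 0:
        return float("nan")
    return matrix.value(gene, strain, timepoint) / base


def round_fold(ratio: float) -> int:
    """Round a fold change to the nearest integer, half away from zero."""
    return int(math.floor(abs(ratio) + 0.5) * (1 if ratio >= 0 else -1))


def fold_change_table(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene fold changes vs the same strain's exponential baseline.

    Columns are ``{strain}_{day}`` for the three starvation days; baseline
    zero yields ``nan``.
    """
    rows = {}
    for gene in matrix.genes:
        row = {}
        for strain in STRAINS:
            for day in STARVATION_TIMEPOINTS:
                row[f"{strain}_{day}"] = fold_change(matrix, gene, strain, day)
        rows[gene] = row
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# Differential testing (replicate-level, synthetic data)
# ---------------------------------------------------------------------------

def welch_t_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple[float, float, float]:
    """Welch two-sample t test: (t, Satterthwaite df, two-sided p).

    Degenerate zero-variance inputs: equal means give (0, df, 1); unequal
    means give the smallest representable p.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2 or not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("each sample needs >= 2 finite values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        df = float(len(a) + len(b) - 2)
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        sign = 1.0 if a.mean() > b.mean() else -1.0
        return sign * float("inf"), df, float(np.nextafter(0, 1))
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_table(
    samples_a: pd.DataFrame, samples_b: pd.DataFrame, fdr: float = 0.005
) -> pd.DataFrame:
    """Per-gene Welch tests between two replicate-level matrices + BH FDR.

    Both inputs are genes x replicates; rows are aligned on the index.  The
    significance column uses the configured false-discovery-rate cutoff
    (default 0.005, the cutoff used for the microarray contrasts).
    """
    genes = samples_a.index
    if not genes.equals(samples_b.index):
        raise ValueError("replicate matrices must share their gene index")
    stats_rows = [
        welch_t_test(samples_a.loc[g].values, samples_b.loc[g].values) for g in genes
    ]
    out = pd.DataFrame(stats_rows, index=genes, columns=["t", "df", "p"])
    out["q"] = bh_fdr(out["p"].values)
    out["significant"] = out["q"] <= fdr
    return out


# ---------------------------------------------------------------------------
# Hierarchical clustering
# ---------------------------------------------------------------------------

METRICS = ("euclidean_log", "one_minus_pearson")
LINKAGES = ("wpgma", "ward")


@dataclass
class Dendrogram:
    """Agglomerative merge list over n leaves.

    ``merges`` holds ``(cluster_a, cluster_b, height, size)`` rows; leaves are
    numbered ``0..n-1`` and merge i creates cluster ``n + i`` (the convention
    of scipy linkage matrices).
    """

    n_leaves: int
    merges: list[tuple[int, int, float, int]]
    linkage: str
    metric: str
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.merges) != self.n_leaves - 1:
            raise ValueError("a dendrogram over n leaves has exactly n-1 merges")

    @property
    def heights(self) -> np.ndarray:
        return np.array([m[2] for m in self.merges])


def _pairwise(profiles: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean_log":
        d = np.sqrt(((profiles[:, None, :] - profiles[None, :, :]) ** 2).sum(-1))
    elif metric == "one_minus_pearson":
        r = np.corrcoef(profiles)
        d = 1.0 - r
        np.fill_diagonal(d, 0.0)
        d = np.maximum(d, 0.0)
    else:
        raise ValueError(f"unsupported metric {metric!r}")
    if not np.isfinite(d).all():
        raise ValueError("non-finite distances (constant profile under pearson?)")
    return d


def hierarchical_cluster(
    matrix: ExpressionMatrix | pd.DataFrame | np.ndarray,
    metric: str = "euclidean_log",
    linkage: str = "wpgma",
    log_transform: bool = True,
    pseudocount: float = CLUSTER_PSEUDOCOUNT,
) -> Dendrogram:
    """Agglomerative clustering of expression profiles.

    Profiles are log2(value + pseudocount) when ``log_transform`` is set.
    WPGMA updates ``d(C+D, E) = (d(C,E) + d(D,E)) / 2``; Ward uses the
    Lance–Williams minimum-variance recurrence on squared distances, with
    heights reported on the distance scale (singleton merges at their
    Euclidean distance).  Among equal-distance pairs the lexicographically
    smallest (i, j) cluster-index pair merges first.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unsupported linkage {linkage!r}")
    if isinstance(matrix, ExpressionMatrix):
        labels = matrix.genes
        profiles = matrix.df.values.astype(float)
    elif isinstance(matrix, pd.DataFrame):
        labels = list(matrix.index)
        profiles = matrix.values.astype(float)
    else:
        profiles = np.asarray(matrix, dtype=float)
        labels = [str(i) for i in range(len(profiles))]
    n = len(profiles)
    if n < 2:
        raise ValueError("need >= 2 profiles to cluster")
    if log_transform:
        profiles = np.log2(profiles + pseudocount)

    d = _pairwise(profiles, metric)
    squared = linkage == "ward"
    work = d**2 if squared else d.copy()

    active: dict[int, int] = {i: 1 for i in range(n)}  # cluster id -> size
    pos = {i: i for i in range(n)}  # cluster id -> row in `work`
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    for step in range(n - 1):
        best = None
        ids = sorted(active)
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                i, j = ids[ai], ids[bi]
                dij = work[pos[i], pos[j]]
                if best is None or dij < best[0] - 1e-15:
                    best = (dij, i, j)
        dij, i, j = best
        height = math.sqrt(max(dij, 0.0)) if squared else dij
        size = active[i] + active[j]
        merges.append((i, j, height, size))
        # Lance-Williams update written into row/col of i; j retired.
        pi, pj = pos[i], pos[j]
        for k in ids:
            if k in (i, j):
                continue
            pk = pos[k]
            if linkage == "wpgma":
                new = 0.5 * work[pi, pk] + 0.5 * work[pj, pk]
            else:  # ward on squared distances
                ni, nj, nk = active[i], active[j], active[k]
                new = (
                    (ni + nk) * work[pi, pk]
                    + (nj + nk) * work[pj, pk]
                    - nk * work[pi, pj]
                ) / (ni + nj + nk)
            work[pi, pk] = work[pk, pi] = new
        del active[j]
        del active[i]
        active[next_id] = size
        pos[next_id] = pi
        next_id += 1
    return Dendrogram(n_leaves=n, merges=merges, linkage=linkage, metric=metric, labels=labels)


def leaf_order(dendrogram: Dendrogram) -> list[str]:
    """Left-to-right leaf traversal; input order is the tie-break."""
    children = {}
    n = dendrogram.n_leaves
    for step, (a, b, _, _) in enumerate(dendrogram.merges):
        children[n + step] = (a, b) if a < b else (b, a)
    order: list[int] = []

    def visit(node: int) -> None:
        if node < n:
            order.append(node)
        else:
            left, right = children[node]
            visit(left)
            visit(right)

    root = n + len(dendrogram.merges) - 1 if dendrogram.merges else 0
    visit(root)
    labels = dendrogram.labels or [str(i) for i in range(n)]
    return [labels[i] for i in order]


def to_newick(dendrogram: Dendrogram) -> str:
    """Newick export with merge heights as cumulative node depths.

    Branch lengths are the height difference between a node and its parent,
    so root-to-leaf distance equals the root merge height.
    """
    n = dendrogram.n_leaves
    labels = dendrogram.labels or [str(i) for i in range(n)]
    height = {i: 0.0 for i in range(n)}
    children = {}
    for step, (a, b, h, _) in enumerate(dendrogram.merges):
        node = n + step
        height[node] = h
        children[node] = (a, b) if a < b else (b, a)

    def render(node: int, parent_h: float) -> str:
        blen = max(parent_h - height[node], 0.0)
        if node < n:
            return f"{labels[node]}:{blen:.6g}"
        left, right = children[node]
        inner = f"({render(left, height[node])},{render(right, height[node])})"
        return f"{inner}:{blen:.6g}"

    root = n + len(dendrogram.merges) - 1
    left, right = children[root]
    h = height[root]
    return f"({render(left, h)},{render(right, h)});"
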