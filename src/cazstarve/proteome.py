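"""Transcript–protein concordance over ordinal secretome bins.

The protein table records culture-filtrate abundance on a six-bin ladder
(edges 5 / 50 / 250 / 1000 / 4000 ng/ml; bin 0 = not detected).  Because the
table enumerates *detected* proteins, a gene present in the expression matrix
but absent from the protein table is treated as bin 0 everywhere; a gene
absent from the expression matrix cannot be evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .corpus import (
    STARVATION_TIMEPOINTS,
    TIMEPOINTS,
    ExpressionMatrix,
    GeneRecord,
    ProteinLevelTable,
)
from .profiling import EXPRESSION_FLOOR, expressed

__all__ = [
    "BIN_MASS_PROXY_NG_ML",
    "ConcordanceRecord",
    "concordance",
    "concordance_summary",
    "secretome_fraction",
]

#: Monotone mass proxy per bin: midpoints of the ladder intervals, with the
#: open top bin (> 4000 ng/ml) proxied at 1.5x its lower edge.
BIN_MASS_PROXY_NG_ML: dict[int, float] = {
    0: 0.0, 1: 2.5, 2: 27.5, 3: 150.0, 4: 625.0, 5: 2500.0, 6: 6000.0,
}

#: Strains covered by both data types (the brlA mutant has no proteome data).
SHARED_STRAINS = ("wt", "flbA")


@dataclass(frozen=True)
class ConcordanceRecord:
    gene: str
    strain: str
    timepoint: str
    transcript_value: float | None
    protein_bin: int
    flag: str  # concordant | transcript_no_protein | protein_no_transcript | unevaluated


def concordance(
    expr: ExpressionMatrix,
    protein_table: ProteinLevelTable,
    high_transcript: float = 10.0,
    low_protein_bin: int = 2,
) -> list[ConcordanceRecord]:
    """Flag transcript/protein disagreements per gene and condition.

    ``transcript_no_protein``: transcript at or above ``high_transcript``
    (% actA) while the protein bin is at most ``low_protein_bin``.
    ``protein_no_transcript``: protein detected although the transcript is
    below the expression floor.  Protein bins take the maximum over the
    biological replicates of a strain.
    """
    if not 0 <= low_protein_bin <= 6:
        raise ValueError("low_protein_bin must lie in 0..6")
    genes = set(expr.genes) | set(protein_table.genes)
    records: list[ConcordanceRecord] = []
    for gene in sorted(genes):
        for strain in SHARED_STRAINS:
            for tp in TIMEPOINTS:
                if gene in protein_table.genes:
                    pbin = protein_table.max_bin(gene, strain, tp)
                else:
                    pbin = 0  # not among the detected proteins
                if gene not in expr.genes:
                    records.append(
                        ConcordanceRecord(gene, strain, tp, None, pbin, "unevaluated")
                    )
                    continue
                tval = expr.value(gene, strain, tp)
                if tval >= high_transcript and pbin <= low_protein_bin:
                    flag = "transcript_no_protein"
                elif pbin > 0 and not expressed(tval, EXPRESSION_FLOOR):
                    flag = "protein_no_transcript"
                else:
                    flag = "concordant"
                records.append(ConcordanceRecord(gene, strain, tp, tval, pbin, flag))
    return records


def concordance_summary(records: Sequence[ConcordanceRecord]) -> dict[str, list[str]]:
    """Genes discordant in >= 2 starvation conditions of one strain.

    ``high_transcript_no_protein`` lists genes whose transcript is high while
    protein stays undetected/low; ``protein_without_transcript`` lists the
    reverse pattern.
    """
    def repeated(flag: str) -> list[str]:
        counts: dict[tuple[str, str], int] = {}
        for r in records:
            if r.flag == flag and r.timepoint in STARVATION_TIMEPOINTS:
                counts[(r.gene, r.strain)] = counts.get((r.gene, r.strain), 0) + 1
        return sorted({g for (g, _), n in counts.items() if n >= 2})

    return {
        "high_transcript_no_protein": repeated("transcript_no_protein"),
        "protein_without_transcript": repeated("protein_no_transcript"),
    }


def secretome_fraction(
    protein_table: ProteinLevelTable,
    gene_records: Sequence[GeneRecord],
    strain: str,
    timepoint: str,
    weight: str = "count",
) -> float | None:
    """Fraction of detected secretome attributable to CAZymes.

    ``count`` weighs every detected protein equally; ``bin_mass_proxy``
    weighs by the bin midpoints, so the result approximates a mass fraction.
    Returns ``None`` when nothing is detected.
    """
    if weight not in ("count", "bin_mass_proxy"):
        raise ValueError(f"unsupported weight {weight!r}")
    by_orf = {r.orf_id: r for r in gene_records}
    total = 0.0
    cazy = 0.0
    for gene in protein_table.genes:
        b = protein_table.max_bin(gene, strain, timepoint)
        if b == 0:
            continue
        w = 1.0 if weight == "count" else BIN_MASS_PROXY_NG_ML[b]
        total += w
        rec = by_orf.get(gene)
        if rec is not None and rec.is_cazyme:
            cazy += w
    if total == 0:
        return None
    return cazy / total


def concordance_frame(records: Sequence[ConcordanceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene, "strain": r.strain, "timepoint": r.timepoint,
                "transcript": r.transcript_value, "protein_bin": r.protein_bin,
                "flag": r.flag,
            }
            for r in records
        ]
    )
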