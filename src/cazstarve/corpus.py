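"""Domain types and packaged fixtures for the starvation CAZyme expression study.

The study design is three *Aspergillus niger* strains — the N402 wild type and
the aconidial developmental mutants ``dflbA`` and ``dbrlA`` — sampled during
exponential growth and on days 1, 3 and 6 of carbon starvation (16 h, 60 h and
140 h after maltose depletion).  Transcript levels are expressed as a
percentage of the actin gene (actA, An15g00560) signal measured during the
exponential phase of the same strain; secreted protein abundance is recorded
on an ordinal six-bin ladder; cell-wall composition as mole-percent of four
monosaccharides.

This module holds the static gene annotations, the in-memory containers used
by every downstream step, and readers/writers for the plain-text fixture
formats.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STRAINS",
    "TIMEPOINTS",
    "STARVATION_TIMEPOINTS",
    "CONDITIONS",
    "PROTEIN_BIN_EDGES_NG_ML",
    "SUBSTRATE_CLASSES",
    "Condition",
    "GeneRecord",
    "ExpressionMatrix",
    "ProteinLevelTable",
    "CompositionSample",
    "GrowthCurve",
    "assign_substrate_class",
    "load_expression_fixture",
    "load_proteome_fixture",
    "load_composition_fixture",
]

# Strain-major, time-minor condition order, matching the printed table layout.
STRAINS: tuple[str, ...] = ("wt", "flbA", "brlA")
TIMEPOINTS: tuple[str, ...] = ("exp", "d1", "d3", "d6")
STARVATION_TIMEPOINTS: tuple[str, ...] = ("d1", "d3", "d6")

# Hours of starvation for each sampling point; t = 0 is the end of the
# exponential growth phase (carbon depletion).
TIMEPOINT_HOURS: Mapping[str, float] = {"exp": -1.0, "d1": 16.0, "d3": 60.0, "d6": 140.0}

#: Ordinal secretome ladder: bin k (1-based) means "below the k-th edge",
#: bin 6 means above the last edge, bin 0 means not detected.
PROTEIN_BIN_EDGES_NG_ML: tuple[float, ...] = (5.0, 50.0, 250.0, 1000.0, 4000.0)

SUBSTRATE_CLASSES: tuple[str, ...] = (
    "chitin",
    "mannan",
    "beta_glucan",
    "alpha_glucan",
    "plant_polysaccharide",
    "storage",
    "pectin",
    "other",
    "unknown",
)

GPI_STATES: tuple[str, ...] = ("present", "absent", "ambivalent")
SECTIONS: tuple[str, ...] = ("A", "B", "C", "D", "E", "F", "G", "H", "none")

_ORF_RE = re.compile(r"^An\d{2}g\d{5}$")

_CAZY_PREFIXES = ("GH", "GT", "CBM", "CE", "PL", "AA", "EXPN")


class Condition(NamedTuple):
    """A (strain, timepoint) cell of the 3 x 4 design."""

    strain: str
    timepoint: str

    @property
    def label(self) -> str:
        return f"{self.strain}_{self.timepoint}"


#: The 12 conditions in canonical (strain-major) order.
CONDITIONS: tuple[Condition, ...] = tuple(
    Condition(s, t) for s in STRAINS for t in TIMEPOINTS
)
CONDITION_LABELS: tuple[str, ...] = tuple(c.label for c in CONDITIONS)


@dataclass(frozen=True)
class GeneRecord:
    """Static annotation of one gene from the printed expression table."""

    orf_id: str
    gene_name: str | None = None
    cazy_family: tuple[str, ...] = ()
    signal_peptide: bool = False
    gpi_anchor: str = "absent"
    function_text: str = ""
    substrate_class: str = "unknown"
    table1_section: str = "none"

    def __post_init__(self) -> None:
        if not _ORF_RE.match(self.orf_id):
            raise ValueError(f"malformed ORF id: {self.orf_id!r}")
        for fam in self.cazy_family:
            if not fam.startswith(_CAZY_PREFIXES):
                raise ValueError(f"{self.orf_id}: unknown CAZy family token {fam!r}")
        if self.gpi_anchor not in GPI_STATES:
            raise ValueError(f"{self.orf_id}: bad GPI state {self.gpi_anchor!r}")
        if self.substrate_class not in SUBSTRATE_CLASSES:
            raise ValueError(
                f"{self.orf_id}: bad substrate class {self.substrate_class!r}"
            )
        if self.table1_section not in SECTIONS:
            raise ValueError(f"{self.orf_id}: bad section {self.table1_section!r}")

    @property
    def is_cazyme(self) -> bool:
        return len(self.cazy_family) > 0


@dataclass
class ExpressionMatrix:
    """Genes x conditions, in % of reference-gene exponential-phase expression.

    Wraps a DataFrame whose index is the ORF id and whose columns are the
    condition labels ``wt_exp`` ... ``brlA_d6``.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CONDITION_LABELS if c not in self.df.columns]
        if missing:
            raise ValueError(f"expression matrix lacks condition columns: {missing}")
        self.df = self.df[list(CONDITION_LABELS)].astype(float)
        if self.df.isna().any().any():
            bad = self.df.index[self.df.isna().any(axis=1)].tolist()
            raise ValueError(f"missing expression values for genes: {bad}")
        if (self.df.values < 0).any():
            raise ValueError("negative expression values")

    @property
    def genes(self) -> list[str]:
        return list(self.df.index)

    @property
    def conditions(self) -> tuple[Condition, ...]:
        return CONDITIONS

    def value(self, gene: str, strain: str, timepoint: str) -> float:
        return float(self.df.at[gene, f"{strain}_{timepoint}"])

    def strain_values(self, gene: str, strain: str) -> dict[str, float]:
        return {t: self.value(gene, strain, t) for t in TIMEPOINTS}

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index_label="orf")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col="orf"))


# Protein-table condition blocks: two wild-type biological replicates, one
# flbA-deletion fermentation.
PROTEOME_BLOCKS: tuple[tuple[str, int], ...] = (("wt", 1), ("wt", 2), ("flbA", 1))
PROTEOME_COLUMNS: tuple[str, ...] = tuple(
    f"{s}{r}_{t}" for s, r in PROTEOME_BLOCKS for t in TIMEPOINTS
)


@dataclass
class ProteinLevelTable:
    """Ordinal secretome abundance bins (0 = not detected, 1-6 = ladder).

    ``bins`` and ``high_variance`` share index (ORF) and columns
    (``wt1_exp`` ... ``flbA_d6``); ``annotations`` carries SP/GPI/CAZy/name
    metadata for the secreted proteins.
    """

    bins: pd.DataFrame
    high_variance: pd.DataFrame
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        cols = list(PROTEOME_COLUMNS)
        if len(self.bins) == 0:
            self.bins = pd.DataFrame(columns=cols, dtype=int)
            self.high_variance = pd.DataFrame(columns=cols, dtype=bool)
            return
        self.bins = self.bins[cols].astype(int)
        self.high_variance = self.high_variance[cols].astype(bool)
        if ((self.bins.values < 0) | (self.bins.values > 6)).any():
            raise ValueError("protein bins must lie in 0..6")
        if (self.high_variance.values & (self.bins.values == 0)).any():
            raise ValueError("high_variance flag set on an undetected (bin 0) cell")

    @property
    def genes(self) -> list[str]:
        return list(self.bins.index)

    def bin(self, gene: str, strain: str, replicate: int, timepoint: str) -> int:
        return int(self.bins.at[gene, f"{strain}{replicate}_{timepoint}"])

    def max_bin(self, gene: str, strain: str, timepoint: str) -> int:
        """Highest bin over the biological replicates of a strain/timepoint."""
        cols = [
            f"{s}{r}_{timepoint}" for s, r in PROTEOME_BLOCKS if s == strain
        ]
        return int(self.bins.loc[gene, cols].max())


@dataclass(frozen=True)
class CompositionSample:
    """Cell-wall monosaccharide composition of one sample, in mole-percent."""

    strain: str
    time_h: float
    replicate: int
    fractions: Mapping[str, float]

    MONOMERS = ("glucosamine", "galactose", "glucose", "mannose")

    def __post_init__(self) -> None:
        total = sum(self.fractions[m] for m in self.MONOMERS)
        if abs(total - 100.0) > 0.5:
            raise ValueError(f"fractions sum to {total}, not 100 +/- 0.5")
        for m in self.MONOMERS:
            if not 0.0 <= self.fractions[m] <= 100.0:
                raise ValueError(f"{m} fraction out of [0, 100]")


@dataclass(frozen=True)
class GrowthCurve:
    """Biomass time series of one batch culture, g per kg culture broth."""

    strain: str
    replicate: int
    times_h: tuple[float, ...]
    biomass: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        x = np.asarray(self.biomass, dtype=float)
        if t.shape != x.shape:
            raise ValueError("times and biomass lengths differ")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(x < 0):
            raise ValueError("biomass must be non-negative")


# ---------------------------------------------------------------------------
# Substrate-class keyword mapping
# ---------------------------------------------------------------------------

# Order matters: the first matching rule wins.  Patterns are matched on the
# lowercased function text.  Pectin-backbone activities are split out from the
# general plant-polysaccharide class.
_SUBSTRATE_RULES: tuple[tuple[str, str], ...] = (
    (r"chit(in|o)", "chitin"),
    (r"hexosami(ni)?dase", "chitin"),
    (r"mannosidase|mannanase", "mannan"),
    (r"(beta|β)-1,[36]-glucan", "beta_glucan"),
    (r"(alpha|α)-1,3-glucan|(alpha|α)-glucan synthase", "alpha_glucan"),
    (r"polygalacturon|pectin|rhamnogalacturon", "pectin"),
    (r"xylan|xylosid|arabin|cellul|cellobiohydrolase|galactan|glucosidase", "plant_polysaccharide"),
    (r"(beta|β)-1,4-glucanase|endo-glucanase", "plant_polysaccharide"),
    (r"trehal|glycogen", "storage"),
)


def assign_substrate_class(function_text: str) -> str:
    """Map a free-text enzyme function to a substrate class.

    Deterministic keyword mapping; the curated column packaged with the
    expression fixture is authoritative where expert judgment overrode the
    keywords (e.g. the GH2 beta-mannosidase, which acts on plant
    galacto(gluco)mannan rather than the fungal wall).
    """
    if not function_text:
        raise ValueError("function_text must be non-empty")
    text = function_text.lower()
    for pattern, cls in _SUBSTRATE_RULES:
        if re.search(pattern, text):
            return cls
    return "unknown"


# ---------------------------------------------------------------------------
# Fixture loading
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(resources.files("cazstarve") / "data" / name)


def _parse_gene_row(row: pd.Series) -> GeneRecord:
    fam = row.get("cazy_family")
    families: tuple[str, ...]
    if isinstance(fam, str) and fam.strip():
        families = tuple(tok for part in fam.split("-") for tok in [part.strip()] if tok)
    else:
        families = ()
    gpi_raw = str(row.get("gpi", "0")).strip()
    gpi = {"1": "present", "0": "absent", "A": "ambivalent"}.get(gpi_raw)
    if gpi is None:
        raise ValueError(f"row {row.get('orf')}: bad GPI code {gpi_raw!r}")
    name = row.get("name")
    func = row.get("function")
    return GeneRecord(
        orf_id=str(row["orf"]),
        gene_name=str(name) if isinstance(name, str) and name.strip() else None,
        cazy_family=families,
        signal_peptide=bool(int(row.get("sp", 0))),
        gpi_anchor=gpi,
        function_text=str(func) if isinstance(func, str) else "",
        substrate_class=str(row.get("substrate_class", "unknown")),
        table1_section=str(row.get("section", "none")),
    )


def load_expression_fixture(
    path: str | Path | None = None,
) -> tuple[list[GeneRecord], ExpressionMatrix]:
    """Load the printed normalized-expression table with its annotations.

    Returns the gene records (with section labels A-H preserved) and the
    67 x 12 expression matrix in % actA units.  A malformed row raises a
    ``ValueError`` naming the row.
    """
    path = _data_path("table1_expression.tsv") if path is None else Path(path)
    raw = pd.read_csv(path, sep="\t", dtype={"sp": str, "gpi": str})
    records: list[GeneRecord] = []
    for _, row in raw.iterrows():
        try:
            records.append(_parse_gene_row(row))
        except (ValueError, KeyError, TypeError) as exc:
            raise ValueError(f"malformed fixture row {row.get('orf')!r}: {exc}") from exc
    matrix = ExpressionMatrix(raw.set_index("orf")[list(CONDITION_LABELS)])
    return records, matrix


def load_proteome_fixture(path: str | Path | None = None) -> ProteinLevelTable:
    """Load the printed culture-filtrate protein table (ordinal bins 0-6).

    The two wild-type biological replicates are stored as replicate blocks
    ``wt1``/``wt2`` on the same conditions; asterisked cells (relative SD
    > 50% between technical replicates) set the high-variance flag.
    """
    path = _data_path("table2_proteome.tsv") if path is None else Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if len(raw) == 0:
        return ProteinLevelTable(pd.DataFrame(), pd.DataFrame())
    raw = raw.set_index("orf")
    bins = raw[list(PROTEOME_COLUMNS)].astype(int)
    hv = raw[[f"{c}_hv" for c in PROTEOME_COLUMNS]].astype(int).astype(bool)
    hv.columns = list(PROTEOME_COLUMNS)
    annot = raw[["sp", "gpi", "cazy_family", "name", "function"]].copy()
    return ProteinLevelTable(bins=bins, high_variance=hv, annotations=annot)


def load_composition_fixture(path: str | Path | None = None) -> list[CompositionSample]:
    """Load the cell-wall composition table (partly synthetic completion).

    Only a handful of mole-percent values are printed in the source study;
    the packaged CSV fills the remaining cells under the stated constraint
    that galactose and mannose stay roughly constant, and is named
    accordingly.
    """
    path = _data_path("cellwall_composition_synthetic.csv") if path is None else Path(path)
    raw = pd.read_csv(path)
    samples = []
    for _, row in raw.iterrows():
        samples.append(
            CompositionSample(
                strain=str(row["strain"]),
                time_h=float(row["time_h"]),
                replicate=int(row["replicate"]),
                fractions={m: float(row[m]) for m in CompositionSample.MONOMERS},
            )
        )
    return samples


def write_composition_csv(samples: Iterable[CompositionSample], path: str | Path) -> None:
    rows = [
        {"strain": s.strain, "time_h": s.time_h, "replicate": s.replicate,
         **{m: s.fractions[m] for m in CompositionSample.MONOMERS}}
        for s in samples
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def records_by_orf(records: Sequence[GeneRecord]) -> dict[str, GeneRecord]:
    return {r.orf_id: r for r in records}
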