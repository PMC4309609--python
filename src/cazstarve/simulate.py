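"""Synthetic data with the statistical structure the analysis assumes.

Each generator emulates one data type of the starvation study at its study
conditions: duplicate cultivations over the 3 strains x 4 timepoints design,
log-normal (multiplicative) noise on expression as is typical of microarray
intensities, ordinal secretome bins derived from a secreted-mass proxy,
Dirichlet-distributed cell-wall compositions around the published means, and
exponential-growth-then-decay biomass curves at the published rates.  Truth
labels always travel with the simulated data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import (
    CONDITION_LABELS,
    PROTEIN_BIN_EDGES_NG_ML,
    PROTEOME_BLOCKS,
    STRAINS,
    TIMEPOINTS,
    CompositionSample,
    ExpressionMatrix,
    GeneRecord,
    GrowthCurve,
    ProteinLevelTable,
)

__all__ = [
    "SimulationConfig",
    "ProteomeConfig",
    "CompositionConfig",
    "GrowthConfig",
    "default_group_templates",
    "simulate_expression",
    "simulate_proteome",
    "simulate_composition",
    "simulate_growth",
    "protein_bin",
]


def _linear_templates() -> dict[str, dict[str, tuple[float, ...]]]:
    """Per-group mean profiles on the % actA scale, by strain.

    Each template satisfies its group's classification rule exactly at zero
    noise, with every binding constraint at least ~0.6 log2 units from its
    threshold so the planted label survives replicate noise.
    """
    return {
        "A": {"wt": (1, 16, 16, 16), "flbA": (1, 16, 16, 16), "brlA": (1, 16, 16, 16)},
        "B": {"wt": (0.4, 0.4, 8, 16), "flbA": (0.4, 0.4, 0.4, 0.4), "brlA": (0.4, 0.4, 0.4, 0.4)},
        "C": {"wt": (10, 30, 50, 50), "flbA": (10, 10, 3, 2), "brlA": (10, 12, 5, 3)},
        "D": {"wt": (1, 1, 1.2, 1.2), "flbA": (1, 1, 1.2, 1.2), "brlA": (1, 1.5, 8, 12)},
        "E": {"wt": (2, 2, 2, 2), "flbA": (10, 6, 6, 6), "brlA": (2, 2, 2, 2)},
        "F": {"wt": (16, 16, 16, 16), "flbA": (2, 2, 2, 2), "brlA": (16, 16, 16, 16)},
        "G": {"wt": (1, 12, 12, 12), "flbA": (1, 2, 2, 2), "brlA": (1, 10, 10, 10)},
        "H": {"wt": (1, 1, 1, 1), "flbA": (1, 8, 8, 8), "brlA": (1, 1, 1, 1)},
        "unclassified": {"wt": (1, 1, 1, 1), "flbA": (1, 1, 1, 1), "brlA": (1, 1, 1, 1)},
    }


def default_group_templates() -> dict[str, np.ndarray]:
    """Mean log2 expression (12-vector in condition order) per profile group."""
    out = {}
    for group, by_strain in _linear_templates().items():
        vec = [by_strain[s][i] for s in STRAINS for i in range(len(TIMEPOINTS))]
        out[group] = np.log2(np.asarray(vec, dtype=float))
    return out


@dataclass(frozen=True)
class ProteomeConfig:
    secretion_probability: float = 0.7  # chance a gene carries a signal peptide
    gain_ng_ml_per_pct: float = 30.0  # secreted mass per % actA of transcript
    detection_floor_ng_ml: float = 2.0
    noise_sigma_log2: float = 0.2


@dataclass(frozen=True)
class CompositionConfig:
    #: Mean mole-percent (glucosamine, galactose, glucose, mannose) per
    #: (strain, time_h); the published wild-type exponential wall and the
    #: elevated-chitin flbA wall are the anchor conditions.
    means: Mapping[tuple[str, float], tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            ("wt", 0.0): (13, 8, 73, 6),
            ("wt", 140.0): (24, 8, 63, 5),
            ("flbA", 0.0): (24, 9, 61, 6),
            ("brlA", 0.0): (22, 8, 64, 6),
        }
    )
    concentration: float = 200.0  # Dirichlet precision (higher = tighter)
    replicates: int = 2


@dataclass(frozen=True)
class GrowthConfig:
    #: Published maximum specific growth rates (1/h) and end-of-exponential
    #: biomass (g per kg broth) per strain.
    mu: Mapping[str, float] = field(
        default_factory=lambda: {"wt": 0.242, "flbA": 0.162, "brlA": 0.218}
    )
    x_end: Mapping[str, float] = field(
        default_factory=lambda: {"wt": 4.9, "flbA": 3.4, "brlA": 4.8}
    )
    #: Starvation decay: (fast rate 0-20 h, slow rate thereafter), 1/h.  The
    #: flbA mutant loses biomass quickly during the first day, then barely.
    decay: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "wt": (0.004, 0.004),
            "brlA": (0.004, 0.004),
            "flbA": (0.02, 0.0005),
        }
    )
    decay_breakpoint_h: float = 20.0
    growth_times_h: tuple[float, ...] = tuple(np.arange(-24.0, 0.1, 2.0))
    starvation_times_h: tuple[float, ...] = tuple(np.arange(4.0, 141.0, 4.0))
    noise_sigma: float = 0.02  # multiplicative (log-normal) noise
    replicates: int = 2


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_genes_per_group: Mapping[str, int] = field(
        default_factory=lambda: {g: 8 for g in
                                 ("A", "B", "C", "D", "E", "F", "G", "H", "unclassified")}
    )
    replicates: int = 2
    noise_sigma_log2: float = 0.1
    cazyme_fraction: float = 0.8
    proteome: ProteomeConfig = field(default_factory=ProteomeConfig)
    composition: CompositionConfig = field(default_factory=CompositionConfig)
    growth: GrowthConfig = field(default_factory=GrowthConfig)

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng((int(config.seed) % (2**31), stream))


def simulate_expression(
    config: SimulationConfig | None = None,
) -> tuple[list[GeneRecord], list[pd.DataFrame], ExpressionMatrix, dict[str, str]]:
    """Replicate-level expression matrices with planted profile groups.

    Returns gene records, one genes x 12-conditions DataFrame per biological
    replicate (``value = 2**(template + N(0, sigma))``), the replicate-mean
    matrix in % actA convention, and the planted truth labels.
    """
    cfg = config or SimulationConfig()
    if any(n <= 0 for n in cfg.n_genes_per_group.values()):
        raise ValueError("gene counts per group must be positive")
    rng = _rng(cfg, 0)
    templates = default_group_templates()
    orfs: list[str] = []
    records: list[GeneRecord] = []
    truth: dict[str, str] = {}
    rows: list[np.ndarray] = []
    idx = 1
    for group, count in cfg.n_genes_per_group.items():
        if group not in templates:
            raise ValueError(f"no template for group {group!r}")
        for _ in range(count):
            orf = f"An99g{idx:05d}"
            idx += 1
            secreted = bool(rng.random() < cfg.proteome.secretion_probability)
            is_cazy = bool(rng.random() < cfg.cazyme_fraction)
            records.append(
                GeneRecord(
                    orf_id=orf,
                    cazy_family=("GH18",) if is_cazy else (),
                    signal_peptide=secreted,
                    function_text="synthetic planted profile",
                    substrate_class="unknown",
                    table1_section="none",
                )
            )
            orfs.append(orf)
            truth[orf] = group
            rows.append(templates[group])
    template_matrix = np.vstack(rows)
    reps: list[pd.DataFrame] = []
    for _ in range(cfg.replicates):
        noise = rng.normal(0.0, cfg.noise_sigma_log2, size=template_matrix.shape)
        values = np.exp2(template_matrix + noise)
        reps.append(pd.DataFrame(values, index=orfs, columns=list(CONDITION_LABELS)))
    mean = ExpressionMatrix(sum(reps) / len(reps))
    return records, reps, mean, truth


def protein_bin(mass_ng_ml: float, detection_floor: float = 0.0) -> int:
    """Ordinal bin for a secreted mass; ladder boundaries are upper-exclusive
    (mass < 5 -> bin 1, mass = 5 -> bin 2); below the floor -> bin 0."""
    if mass_ng_ml < detection_floor or mass_ng_ml <= 0:
        return 0
    return 1 + int(sum(mass_ng_ml >= e for e in PROTEIN_BIN_EDGES_NG_ML))


def simulate_proteome(
    records: Sequence[GeneRecord],
    expression: ExpressionMatrix,
    config: SimulationConfig | None = None,
) -> ProteinLevelTable:
    """Ordinal protein bins from a secreted-mass proxy of the transcript.

    Secreted mass = gain x transcript for genes with a signal peptide (zero
    otherwise), log-normally noised per biological replicate, then binned by
    the ladder; mass below the detection floor gives bin 0.  Only wild type
    and the flbA mutant are covered, matching the measured secretomes.
    """
    cfg = config or SimulationConfig()
    rng = _rng(cfg, 1)
    pconf = cfg.proteome
    by_orf = {r.orf_id: r for r in records}
    cols = [f"{s}{r}_{t}" for s, r in PROTEOME_BLOCKS for t in TIMEPOINTS]
    bins = pd.DataFrame(0, index=expression.genes, columns=cols, dtype=int)
    for gene in expression.genes:
        rec = by_orf.get(gene)
        secreted = rec is not None and rec.signal_peptide
        for strain, rep in PROTEOME_BLOCKS:
            for tp in TIMEPOINTS:
                if not secreted:
                    continue
                transcript = expression.value(gene, strain, tp)
                noise = 2.0 ** rng.normal(0.0, pconf.noise_sigma_log2)
                mass = pconf.gain_ng_ml_per_pct * transcript * noise
                bins.at[gene, f"{strain}{rep}_{tp}"] = protein_bin(
                    mass, pconf.detection_floor_ng_ml
                )
    hv = pd.DataFrame(False, index=bins.index, columns=cols)
    return ProteinLevelTable(bins=bins, high_variance=hv)


def simulate_composition(
    config: SimulationConfig | None = None,
) -> list[CompositionSample]:
    """Dirichlet-noised cell-wall compositions around the configured means."""
    cfg = config or SimulationConfig()
    ccfg = cfg.composition
    if ccfg.concentration <= 0:
        raise ValueError("Dirichlet concentration must be positive")
    rng = _rng(cfg, 2)
    samples: list[CompositionSample] = []
    for (strain, time_h), means in ccfg.means.items():
        alpha = ccfg.concentration * np.asarray(means, dtype=float) / 100.0
        for rep in range(1, ccfg.replicates + 1):
            draw = 100.0 * rng.dirichlet(alpha)
            samples.append(
                CompositionSample(
                    strain=strain,
                    time_h=time_h,
                    replicate=rep,
                    fractions=dict(zip(CompositionSample.MONOMERS, draw)),
                )
            )
    return samples


def _biomass(t: float, strain: str, gcfg: GrowthConfig) -> float:
    x_end = gcfg.x_end[strain]
    if t <= 0:
        return x_end * float(np.exp(gcfg.mu[strain] * t))
    fast, slow = gcfg.decay[strain]
    bp = gcfg.decay_breakpoint_h
    if t <= bp:
        return x_end * float(np.exp(-fast * t))
    return x_end * float(np.exp(-fast * bp - slow * (t - bp)))


def simulate_growth(config: SimulationConfig | None = None) -> list[GrowthCurve]:
    """Exponential-growth-then-decay biomass curves with multiplicative noise.

    Curves are synchronized at t = 0, the end of the exponential phase; the
    flbA mutant decays fast during the first 20 h of starvation and slowly
    afterwards, the other strains at a single moderate rate.
    """
    cfg = config or SimulationConfig()
    gcfg = cfg.growth
    rng = _rng(cfg, 3)
    times = tuple(gcfg.growth_times_h) + tuple(gcfg.starvation_times_h)
    curves: list[GrowthCurve] = []
    for strain in STRAINS:
        for rep in range(1, gcfg.replicates + 1):
            clean = np.array([_biomass(t, strain, gcfg) for t in times])
            noise = np.exp(rng.normal(0.0, gcfg.noise_sigma, size=clean.shape))
            curves.append(
                GrowthCurve(
                    strain=strain,
                    replicate=rep,
                    times_h=tuple(float(t) for t in times),
                    biomass=tuple(float(b) for b in clean * noise),
                )
            )
    return curves
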