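"""Reproduction report: recompute the study's headline numbers end to end.

Everything here is computed at run time from the packaged fixtures or from
seeded simulations at the study conditions — nothing is hard-coded.  The
report is the programmatic core behind ``analysis/07_reproduce.py`` and
``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np

from . import cellwall, classify, physiology, profiling, simulate
from .corpus import load_expression_fixture

__all__ = ["reproduce"]

# (name, gene, kind, args) for the fold-change claims made in the study's
# narrative.  "fold" = starvation day vs the same strain's exponential phase;
# "cross_exp" = flbA exponential value vs wild-type exponential value.
_FOLD_CLAIMS = (
    ("abaA_wt_day3_fold", "An01g03750", "fold", ("wt", "d3"), True),
    ("cfcI_wt_day3_fold", "An02g13580", "fold", ("wt", "d3"), False),
    ("ctcB_wt_day6_fold", "An09g05920", "fold", ("wt", "d6"), False),
    ("fwnA_wt_day3_fold", "An09g05730", "fold", ("wt", "d3"), True),
    ("an15g02350_wt_day3_fold", "An15g02350", "fold", ("wt", "d3"), True),
    ("nagA_wt_max_starvation_fold", "An09g02240", "max_fold", ("wt",), False),
    ("an08g08370_wt_max_starvation_fold", "An08g08370", "max_fold", ("wt",), False),
    ("tpsC_brlA_day3_fold", "An14g02180", "fold", ("brlA", "d3"), True),
    ("crhC_flbA_vs_wt_exp_fold", "An07g01160", "cross_exp", (), True),
    ("agsA_flbA_vs_wt_exp_fold", "An04g09890", "cross_exp", (), True),
)


def _entry(value: float, n: int) -> dict:
    return {"value": float(value), "n": int(n)}


def fixture_quantities() -> dict[str, dict]:
    """Headline counts, fold-change claims and classifier agreement from the
    printed expression table."""
    records, matrix = load_expression_fixture()
    n_genes = len(matrix.genes)
    out: dict[str, dict] = {}

    sections = {r.orf_id: r.table1_section for r in records if r.table1_section != "none"}
    counts = classify.headline_counts(sections, records)
    for key, val in counts.items():
        out[f"{key}_count"] = _entry(val, n_genes)

    for name, gene, kind, args, rounded in _FOLD_CLAIMS:
        if kind == "fold":
            ratio = profiling.fold_change(matrix, gene, *args)
        elif kind == "max_fold":
            (strain,) = args
            ratio = max(
                profiling.fold_change(matrix, gene, strain, d) for d in ("d1", "d3", "d6")
            )
        else:  # cross_exp: flbA exponential level relative to wild type
            ratio = matrix.value(gene, "flbA", "exp") / matrix.value(gene, "wt", "exp")
        out[name] = _entry(profiling.round_fold(ratio) if rounded else ratio, n_genes)

    assignment = classify.classify_all(matrix, records)
    out["classifier_section_agreement_pct"] = _entry(100.0 * assignment.agreement, n_genes)
    return out


def growth_quantities(seed: int, n_replicates: int = 200) -> dict[str, dict]:
    """Specific growth rates recovered from seeded synthetic biomass curves."""
    fits: dict[str, list[float]] = {"wt": [], "flbA": [], "brlA": []}
    base = simulate.SimulationConfig(seed=seed)
    n_calls = -(-n_replicates // base.growth.replicates)
    for k in range(n_calls):
        cfg = base.with_seed((seed + 1009 * (k + 1)) % (2**31))
        for curve in simulate.simulate_growth(cfg):
            fits[curve.strain].append(physiology.fit_mu_max(curve).mu_max)
    wt = np.array(fits["wt"][:n_replicates])
    true_mu = base.growth.mu["wt"]
    return {
        "wt_mu_max_per_h": _entry(wt.mean(), len(wt)),
        "wt_mu_max_max_abs_error": _entry(np.abs(wt - true_mu).max(), len(wt)),
        "wt_mu_max_mean_abs_error": _entry(np.abs(wt - true_mu).mean(), len(wt)),
        "flbA_mu_max_per_h": _entry(np.mean(fits["flbA"][:n_replicates]), len(wt)),
        "brlA_mu_max_per_h": _entry(np.mean(fits["brlA"][:n_replicates]), len(wt)),
    }


def classifier_recovery(seed: int, sigma: float = 0.1) -> dict[str, dict]:
    """Planted-group recovery on synthetic expression at the stated noise."""
    cfg = simulate.SimulationConfig(seed=seed, noise_sigma_log2=sigma)
    records, _, mean, truth = simulate.simulate_expression(cfg)
    assignment = classify.classify_all(mean, records)
    hits = sum(assignment.group_of(g) == grp for g, grp in truth.items())
    return {
        "planted_group_recovery_pct": _entry(100.0 * hits / len(truth), len(truth))
    }


def welch_type1_error(seed: int, n_sims: int = 10_000, n: int = 5, alpha: float = 0.05) -> dict[str, dict]:
    """Empirical size of the Welch test on null normal samples."""
    rng = np.random.default_rng((seed % (2**31), 17))
    a = rng.normal(size=(n_sims, n))
    b = rng.normal(size=(n_sims, n))
    rejections = sum(
        profiling.welch_t_test(a[i], b[i])[2] < alpha for i in range(n_sims)
    )
    return {"welch_type1_error_rate": _entry(rejections / n_sims, n_sims)}


def bh_realized_fdr(
    seed: int, n_sims: int = 400, m: int = 200, m_alt: int = 50, alpha: float = 0.05
) -> dict[str, dict]:
    """Realized false-discovery proportion of BH on mixed p-values."""
    rng = np.random.default_rng((seed % (2**31), 23))
    fdps = []
    for _ in range(n_sims):
        p_null = rng.uniform(size=m - m_alt)
        # alternative p-values from one-sided normal shift tests (effect 3 sd)
        p_alt = 1.0 - _normal_cdf(rng.normal(3.0, 1.0, size=m_alt))
        p = np.concatenate([p_null, p_alt])
        q = profiling.bh_fdr(p)
        rejected = q <= alpha
        n_rej = rejected.sum()
        false_rej = rejected[: m - m_alt].sum()
        fdps.append(false_rej / n_rej if n_rej else 0.0)
    return {"bh_realized_fdr": _entry(float(np.mean(fdps)), n_sims)}


def _normal_cdf(x: np.ndarray) -> np.ndarray:
    from scipy.stats import norm

    return norm.cdf(x)


def composition_quantities(seed: int, n_sims: int = 200, n_reps: int = 4) -> dict[str, dict]:
    """Glucosamine-shift detection power and mean recovered composition."""
    base = simulate.SimulationConfig(seed=seed)
    ccfg = simulate.CompositionConfig(replicates=n_reps)
    hits = 0
    glcn_wt = []
    for k in range(n_sims):
        cfg = simulate.SimulationConfig(
            seed=(seed + 2003 * (k + 1)) % (2**31), composition=ccfg
        )
        samples = simulate.simulate_composition(cfg)
        wt_exp = [s for s in samples if s.strain == "wt" and s.time_h == 0.0]
        flbA_exp = [s for s in samples if s.strain == "flbA" and s.time_h == 0.0]
        cmp = cellwall.compare_composition(wt_exp, flbA_exp, "glucosamine")
        hits += cmp.significant
        glcn_wt.extend(s.fractions["glucosamine"] for s in wt_exp)
    return {
        "glucosamine_shift_power": _entry(hits / n_sims, n_sims),
        "wt_exp_glucosamine_pct": _entry(float(np.mean(glcn_wt)), len(glcn_wt)),
    }


def reproduce(seed: int = 1) -> dict[str, dict]:
    """Compute every reported quantity from scratch; see module docstring."""
    out: dict[str, dict] = {}
    out.update(fixture_quantities())
    out.update(growth_quantities(seed))
    out.update(classifier_recovery(seed))
    out.update(welch_type1_error(seed))
    out.update(bh_realized_fdr(seed))
    out.update(composition_quantities(seed))
    return out
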