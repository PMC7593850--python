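"""Statistical calibration and power diagnostics for the differential test.

Two properties stand in for headline site counts that only the full deposited
data could reproduce: (1) under a pure null the per-site t-test's rejection
rate at a nominal alpha must match that alpha, and (2) recovery of planted
effects must improve with coverage and effect size.  Both run the same
compare() machinery as the real analysis.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .calling import SampleProfile
from .differential import ComparisonSpec, compare
from .genome import enumerate_sites
from .simulate import (
    EffectSpec,
    SimulationConfig,
    apply_effects,
    sample_id,
    simulate_counts_frame,
    simulate_genome,
    simulate_truth,
)


def null_type1_rate(
    n_sites: int = 10_000,
    n_reps: int = 3,
    alpha: float = 0.01,
    sigma: float = 0.05,
    seed: int = 0,
) -> tuple[float, int]:
    """Rejection rate of the per-site t-test under a Gaussian null.

    Every site has identical group means; replicate ratios are
    Normal(mu_i, sigma).  Under normality the equal-variance t at nominal
    alpha rejects with probability exactly alpha, so the observed rate
    should sit inside the binomial confidence band around alpha.  Returns
    (rate, rejection count) before any effect-size filtering.
    """
    rng = np.random.default_rng([seed, 91])
    mu = rng.uniform(0.2, 0.8, size=n_sites)
    from .differential import _pooled_t

    A = rng.normal(mu[:, None], sigma, size=(n_sites, n_reps))
    B = rng.normal(mu[:, None], sigma, size=(n_sites, n_reps))
    _t, p, _deg = _pooled_t(A, B)
    n_reject = int((p <= alpha).sum())
    return n_reject / n_sites, n_reject


def _profiles_for_conditions(
    truth: pd.DataFrame,
    per_condition: dict[tuple[int, str], np.ndarray],
    cfg: SimulationConfig,
    conditions: list[tuple[int, str]],
    min_coverage: int,
    coverage_mean: float | None = None,
) -> dict[str, SampleProfile]:
    """Simulate counts for the requested conditions and package them as
    already-validated profiles (simulated sites are catalog sites by
    construction, so validation reduces to the coverage filter)."""
    profiles = {}
    for day, trt in conditions:
        for rep in range(1, cfg.replicates + 1):
            counts = simulate_counts_frame(
                truth, per_condition[(day, trt)], cfg, day, trt, rep,
                coverage_mean=coverage_mean,
            )
            kept = counts[counts["coverage"] >= min_coverage].reset_index(drop=True)
            sid = sample_id(day, trt, rep)
            profiles[sid] = SampleProfile(
                sample_id=sid, day=day, treatment=trt, replicate=rep, calls=kept
            )
    return profiles


def planted_recall_grid(
    coverages: tuple[float, ...] = (20.0, 50.0, 100.0),
    deltas: tuple[float, ...] = (0.1, 0.2, 0.3),
    n_planted: int = 400,
    seed: int = 0,
    cfg: SimulationConfig | None = None,
    p_threshold: float = 0.01,
) -> pd.DataFrame:
    """Recall of planted hypomethylation vs coverage and effect size.

    One default-scale genome and baseline methylome are drawn once; for each
    |delta| a fixed-magnitude hypomethylation effect is planted on
    ``n_planted`` heavily methylated CpG sites at Day 10, and for each mean
    coverage the Day4-vs-Day10 comparison is run through the standard filter
    chain.  Recall = retained planted sites / planted sites; precision over
    retained sites is reported alongside.
    """
    base_cfg = cfg or SimulationConfig(seed=seed)
    rows = []
    for delta in deltas:
        eff_cfg = dataclasses.replace(
            base_cfg,
            seed=base_cfg.seed,
            days=(4, 10),
            treatments=("control",),
            effects=[
                EffectSpec(
                    name="planted_hypo",
                    n_sites=n_planted,
                    delta_range=(delta, delta),
                    direction="hypo",
                    days=[10],
                    treatments=["control"],
                    truth_range=(0.5, 0.95),
                )
            ],
        )
        genome, _genes = simulate_genome(eff_cfg)
        catalog = enumerate_sites(genome)
        truth = simulate_truth(catalog, eff_cfg)
        per_condition, registry = apply_effects(truth, eff_cfg)
        planted = set(
            map(tuple, registry[["contig", "pos", "strand"]].itertuples(index=False))
        )
        for cov in coverages:
            profiles = _profiles_for_conditions(
                truth, per_condition, eff_cfg,
                [(4, "control"), (10, "control")],
                min_coverage=20, coverage_mean=cov,
            )
            spec = ComparisonSpec(
                label=f"cov{cov}_delta{delta}",
                group_a=[sample_id(4, "control", r) for r in (1, 2, 3)],
                group_b=[sample_id(10, "control", r) for r in (1, 2, 3)],
                p_threshold=p_threshold,
            )
            res = compare(profiles, spec)
            retained = set(map(tuple, res[["contig", "pos", "strand"]].itertuples(index=False)))
            tp = len(retained & planted)
            rows.append(
                {
                    "coverage": cov,
                    "delta": delta,
                    "n_planted": len(planted),
                    "n_retained": len(retained),
                    "true_positives": tp,
                    "recall": tp / len(planted),
                    "precision": tp / len(retained) if retained else np.nan,
                }
            )
    return pd.DataFrame(rows)
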