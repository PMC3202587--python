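"""Replicated simulation studies over the preset scenarios.

Each replicate runs the *full* analysis path on freshly simulated data:
per-gene dilution series are simulated and regressed to estimate
amplification efficiencies (the true E is never handed to the
analysis), CP duplicates are aggregated, Ca values normalized, and the
design's model fitted. These studies drive parameter-recovery and
error-control checks: with ground truth known, the distribution of
estimates across replicates measures bias and false-discovery control
of the whole pipeline, not of a single stage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diffexpr import InferenceConfig, design_for, screen_genes
from .quantify import aggregate_duplicates, estimate_efficiency, normalize_ca
from .simulate import (
    DEFAULT_NORMALIZATION_CONTROLS,
    null_scenario,
    preset_scenario,
    simulate_dilution_series,
    simulate_experiment,
)
from .stress_index import compare_psi, compute_psi

#: Default measurement noise of a simulated standard curve, in CP cycles.
DILUTION_NOISE_SD = 0.15


def _simulated_efficiencies(config, rng, noise_sd):
    eff = {}
    for gene in config.genes:
        series = simulate_dilution_series(
            gene.true_efficiency, cp_at_max=18.0, n_points=7, fold_step=2.0,
            noise_sd=noise_sd, seed=int(rng.integers(0, 2**31 - 1)),
            gene_id=gene.gene_id,
        )
        eff[gene.gene_id] = estimate_efficiency(series)
    return eff


def _one_replicate(preset, rep_seed, rng, null, estimate_efficiencies,
                   dilution_noise_sd, include_controls):
    config = preset_scenario(preset, seed=rep_seed)
    if null:
        config = null_scenario(config)
    cp, truth = simulate_experiment(config)
    if estimate_efficiencies:
        eff = _simulated_efficiencies(config, rng, dilution_noise_sd)
    else:
        eff = config.efficiency_map()
    ca = aggregate_duplicates(cp, eff)
    controls = [g for g in DEFAULT_NORMALIZATION_CONTROLS
                if g in ca.values.columns]
    norm = None
    if controls:
        norm = normalize_ca(ca, controls, include_controls=include_controls)
    return config, truth, ca, norm


def replicate_screen_study(
    preset: str,
    n_replicates: int,
    seed: int,
    genes: list[str] | None = None,
    null: bool = False,
    include_controls: bool = False,
    estimate_efficiencies: bool = True,
    dilution_noise_sd: float = DILUTION_NOISE_SD,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run the gene-wise screen on ``n_replicates`` simulated experiments.

    Returns a tidy frame with one row per (replicate, gene, term):
    replicate, gene_id, term, B, fold, p, p_adj.
    """
    rng = np.random.default_rng(seed)
    design = design_for(preset)
    frames = []
    for rep in range(n_replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        _, truth, _, norm = _one_replicate(
            preset, rep_seed, rng, null, estimate_efficiencies,
            dilution_noise_sd, include_controls,
        )
        res = screen_genes(norm, truth.metadata, design,
                           InferenceConfig(alpha=alpha), genes=genes)
        res.insert(0, "replicate", rep)
        frames.append(res)
    return pd.concat(frames, ignore_index=True)


def replicate_psi_study(
    preset: str,
    n_replicates: int,
    seed: int,
    estimate_efficiencies: bool = True,
    dilution_noise_sd: float = DILUTION_NOISE_SD,
) -> pd.DataFrame:
    """Stress-index group comparison on ``n_replicates`` simulated
    experiments; one row per replicate with the fitted contrast."""
    rng = np.random.default_rng(seed)
    design = design_for(preset)
    rows = []
    for rep in range(n_replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        _, truth, ca, _ = _one_replicate(
            preset, rep_seed, rng, False, estimate_efficiencies,
            dilution_noise_sd, False,
        )
        psi = compute_psi(ca)
        est = compare_psi(psi, truth.metadata, design)
        rows.append({"replicate": rep, "term": est.term, "B": est.B,
                     "p": est.p, "method": est.method})
    return pd.DataFrame(rows)


def geometric_mean_fold(b_values) -> float:
    """Summarize per-replicate log2 effects as a fold: 2**mean(B).

    The geometric mean is the natural average for ratio-scale fold
    changes and is unbiased when the estimator is unbiased on the log2
    scale (the arithmetic mean of 2**B is inflated by Jensen's
    inequality).
    """
    return float(2.0 ** np.mean(np.asarray(b_values, dtype=float)))


def mc_standard_error(values) -> float:
    v = np.asarray(values, dtype=float)
    return float(np.std(v, ddof=1) / np.sqrt(len(v)))
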