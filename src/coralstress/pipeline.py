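"""End-to-end pipeline: efficiencies -> Ca -> stability -> models -> index.

A RunConfig names the input tables and analysis choices; run_pipeline
executes the stages in assay order, writes every result as CSV and
records a run log (seed, version, QC flags) so a run is reproducible
from config + seed alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .datatypes import CaMatrix
from .diffexpr import DESIGNS, InferenceConfig, design_for, screen_genes
from .errors import ConfigurationError
from .io import (
    read_cp_table,
    read_dilution_table,
    read_metadata,
    write_ca_matrix,
    write_effects_table,
    write_efficiencies,
    write_psi,
)
from .quantify import (
    DEFAULT_DISCORDANCE_LIMIT,
    DEFAULT_QC_RANGE,
    aggregate_duplicates,
    estimate_efficiency,
    normalize_ca,
)
from .stability import control_variation, genorm_rank
from .stress_index import compare_psi, compute_psi, pca_markers

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    cp_table: str
    dilution_table: str
    metadata: str
    out_dir: str
    control_genes: list[str]
    psi_numerator: str = "Hsp16"
    psi_denominator: str = "Actin"
    design: str = "exp1"
    condition_column: str = "treatment"
    alpha: float = 0.05
    seed: int = 0
    efficiency_range: tuple[float, float] = DEFAULT_QC_RANGE
    discordance_limit: float = DEFAULT_DISCORDANCE_LIMIT
    stability_candidates: list[str] | None = None
    run_pca: bool = False

    def validate(self) -> None:
        for p in (self.cp_table, self.dilution_table, self.metadata):
            if not Path(p).exists():
                raise ConfigurationError(f"input file not found: {p}")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")
        lo, hi = self.efficiency_range
        if not lo < hi:
            raise ConfigurationError("efficiency range low must be < high")
        if self.design not in DESIGNS:
            raise ConfigurationError(
                f"unknown design {self.design!r}; known: {sorted(DESIGNS)}"
            )
        if not self.control_genes:
            raise ConfigurationError("at least one control gene required")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "efficiency_range" in raw:
            raw["efficiency_range"] = tuple(raw["efficiency_range"])
        return cls(**raw)


@dataclass
class PipelineResult:
    efficiencies: dict
    ca_raw: CaMatrix
    ca_normalized: CaMatrix
    stability: object
    effects: object
    psi: object
    psi_effect: object
    control_report: object = None
    pca: object = None


def run_pipeline(config: RunConfig) -> PipelineResult:
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"coralstress {__version__}", f"seed={config.seed}",
                 f"design={config.design}", f"alpha={config.alpha}"]

    def stage(name):
        logger.info("stage: %s", name)
        log_lines.append(f"stage {name}: ok")

    # --- read inputs and validate gene-role assignments up front ---------
    cp = read_cp_table(config.cp_table)
    series = read_dilution_table(config.dilution_table)
    meta = read_metadata(config.metadata)
    genes = set(cp.genes)
    undefined = [g for g in config.control_genes if g not in genes]
    if undefined:
        raise ConfigurationError(f"control gene(s) not in CP table: {undefined}")
    for g in (config.psi_numerator, config.psi_denominator):
        if g not in genes:
            raise ConfigurationError(f"index gene {g!r} not in CP table")
    missing_series = [g for g in cp.genes if g not in series]
    if missing_series:
        raise ConfigurationError(
            f"no dilution series for gene(s): {missing_series}"
        )
    stage("read")

    # --- efficiency calibration ------------------------------------------
    efficiencies = {
        g: estimate_efficiency(series[g], qc_range=config.efficiency_range)
        for g in cp.genes
    }
    n_fail = sum(1 for e in efficiencies.values() if not e.qc_pass)
    log_lines.append(f"efficiency QC failures: {n_fail}")
    write_efficiencies(efficiencies, out / "efficiencies.csv")
    stage("efficiency")

    # --- quantification ----------------------------------------------------
    ca_raw = aggregate_duplicates(
        cp, efficiencies, discordance_limit=config.discordance_limit
    )
    n_disc = int(ca_raw.discordant.to_numpy().sum())
    log_lines.append(f"discordant duplicate cells: {n_disc}")
    write_ca_matrix(ca_raw, out / "ca_raw.csv")
    stage("quantify")

    # --- reference-gene stability -----------------------------------------
    candidates = config.stability_candidates or config.control_genes
    stability = None
    if len(candidates) >= 3:
        stability = genorm_rank(ca_raw, list(candidates))
        pd.DataFrame({
            "gene_id": list(stability.m_at_removal),
            "M_at_removal": [stability.m_at_removal[g]
                             for g in stability.m_at_removal],
        }).to_csv(out / "stability_ranking.csv", index=False)
    stage("stability")

    # --- normalization ------------------------------------------------------
    ca_norm = normalize_ca(ca_raw, config.control_genes)
    write_ca_matrix(ca_norm, out / "ca_normalized.csv")
    control_report = None
    if len(candidates) >= 3 and config.condition_column in meta.columns:
        ca_ctrl = normalize_ca(ca_raw.restrict(list(candidates)),
                               list(candidates), include_controls=True)
        control_report = control_variation(
            ca_ctrl, meta[config.condition_column]
        )
        control_report.to_csv(out / "control_variation.csv")
    stage("normalize")

    # --- differential expression --------------------------------------------
    design = design_for(config.design)
    inference = InferenceConfig(alpha=config.alpha, seed=config.seed)
    effects = screen_genes(ca_norm, meta, design, inference)
    write_effects_table(effects, out / "effects.csv")
    stage("diffexpr")

    # --- two-gene index -------------------------------------------------------
    psi = compute_psi(ca_raw, config.psi_numerator, config.psi_denominator)
    write_psi(psi.values, out / "psi.csv")
    psi_effect = compare_psi(psi, meta, design, inference)
    pd.DataFrame([{
        "term": psi_effect.term, "B": psi_effect.B, "fold": psi_effect.fold,
        "ci_low": psi_effect.ci_low, "ci_high": psi_effect.ci_high,
        "p": psi_effect.p, "method": psi_effect.method,
    }]).to_csv(out / "psi_effect.csv", index=False)
    stage("psi")

    pca = None
    if config.run_pca and config.condition_column in meta.columns:
        pca = pca_markers(ca_norm, meta[config.condition_column])
        pca.loadings.to_csv(out / "pca_loadings.csv")
        stage("pca")

    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return PipelineResult(
        efficiencies=efficiencies, ca_raw=ca_raw, ca_normalized=ca_norm,
        stability=stability, effects=effects, psi=psi, psi_effect=psi_effect,
        control_report=control_report, pca=pca,
    )
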