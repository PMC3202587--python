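"""Efficiency-calibrated quantification of qPCR data.

The instrument reports a crossing point CP: the cycle at which product
fluorescence crosses the detection threshold. With per-cycle
amplification factor E (estimated per primer pair from a standard
curve), the amount of starting template is proportional to E**(-CP);
on the log2 scale this is

    Ca = -CP * log2(E)

so differences of Ca values are log2 fold changes. Normalizing each
sample by the arithmetic mean of its control genes' Ca values removes
the template-loading factor shared by all genes of that sample; on the
linear scale this is identical to dividing by the geometric mean of the
control genes' relative amounts.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .datatypes import CaMatrix, CpTable, DilutionSeries, EfficiencyEstimate
from .errors import (
    ConfigurationError,
    InsufficientDataError,
    InvalidArgumentError,
    NonAmplifyingSeriesError,
)

logger = logging.getLogger(__name__)

#: Accepted amplification-factor range; primer pairs outside it should be
#: redesigned, but the pipeline only flags them (qc_pass=False).
DEFAULT_QC_RANGE = (1.85, 2.15)

#: Technical duplicates further apart than this (in cycles) are flagged.
DEFAULT_DISCORDANCE_LIMIT = 1.5


def estimate_efficiency(
    series: DilutionSeries,
    qc_range: tuple[float, float] = DEFAULT_QC_RANGE,
) -> EfficiencyEstimate:
    """Estimate the amplification factor E from a dilution series.

    Ordinary least squares of CP on log2(input amount); E = 2**(-1/slope).
    A perfect doubling assay loses one cycle per 2-fold dilution
    (slope -1, E = 2).

    Raises
    ------
    NonAmplifyingSeriesError
        If the fitted slope is >= 0 (CP not decreasing with template).
    InvalidArgumentError
        If fewer than 3 distinct input amounts are available.
    """
    amounts = series.amounts
    if np.unique(amounts).size < 3:
        raise InvalidArgumentError(
            f"{series.gene_id!r}: need >= 3 distinct input amounts for the "
            f"standard-curve regression, got {np.unique(amounts).size}"
        )
    x = np.log2(amounts)
    fit = stats.linregress(x, series.cps)
    slope = float(fit.slope)
    if slope >= 0:
        raise NonAmplifyingSeriesError(
            f"{series.gene_id!r}: CP does not decrease with input "
            f"(slope={slope:.4g}); series is non-amplifying"
        )
    efficiency = float(2.0 ** (-1.0 / slope))
    qc_pass = bool(qc_range[0] <= efficiency <= qc_range[1])
    if not qc_pass:
        logger.warning(
            "gene %s: efficiency %.4f outside QC range [%.2f, %.2f]",
            series.gene_id, efficiency, qc_range[0], qc_range[1],
        )
    return EfficiencyEstimate(
        gene_id=series.gene_id,
        slope=slope,
        efficiency=efficiency,
        r_squared=float(fit.rvalue) ** 2,
        qc_pass=qc_pass,
    )


def cp_to_ca(cp, efficiency):
    """Convert CP cycles to Ca (log2 relative abundance): -cp * log2(E).

    Accepts scalars or arrays for ``cp``. E must exceed 1 (an
    amplification factor of 1 would mean no amplification at all).
    """
    eff = float(efficiency)
    if not np.isfinite(eff) or eff <= 1.0:
        raise InvalidArgumentError(f"efficiency must be > 1, got {efficiency!r}")
    cp_arr = np.asarray(cp, dtype=float)
    if not np.all(np.isfinite(cp_arr)):
        raise InvalidArgumentError("cp must be finite")
    out = -cp_arr * np.log2(eff)
    return float(out) if np.isscalar(cp) or cp_arr.ndim == 0 else out


def _efficiency_value(e) -> float:
    return e.efficiency if isinstance(e, EfficiencyEstimate) else float(e)


def aggregate_duplicates(
    table: CpTable,
    efficiencies: Mapping[str, float | EfficiencyEstimate],
    discordance_limit: float = DEFAULT_DISCORDANCE_LIMIT,
) -> CaMatrix:
    """Collapse technical runs into one Ca value per (sample, gene).

    Each run's CP is converted to Ca with the gene-specific efficiency
    and runs are averaged on the Ca scale (downstream models are linear
    in Ca). Runs spanning more than ``discordance_limit`` cycles are
    flagged in the result's ``discordant`` matrix but kept.
    """
    genes = table.genes
    missing = [g for g in genes if g not in efficiencies]
    if missing:
        raise ConfigurationError(
            f"no amplification efficiency provided for gene(s): {missing}"
        )
    eff = {g: _efficiency_value(efficiencies[g]) for g in genes}

    df = table.data.copy()
    df["ca"] = [
        -cp * np.log2(eff[g]) for cp, g in zip(df["cp"], df["gene_id"])
    ]
    grouped = df.groupby(["sample_id", "gene_id"], sort=True)
    ca_mean = grouped["ca"].mean()
    cp_span = grouped["cp"].agg(lambda v: v.max() - v.min())
    flags = cp_span > discordance_limit
    n_flagged = int(flags.sum())
    if n_flagged:
        logger.warning(
            "%d (sample, gene) cell(s) with duplicate CPs more than %.2f "
            "cycles apart (kept, flagged)", n_flagged, discordance_limit,
        )

    values = ca_mean.unstack("gene_id")
    discordant = flags.unstack("gene_id").reindex_like(values)
    discordant = discordant.where(discordant.notna(), False).astype(bool)
    values.index.name = "sample_id"
    values.columns.name = "gene_id"
    return CaMatrix(values=values, normalized=False, discordant=discordant)


def normalize_ca(
    raw: CaMatrix,
    control_genes: Sequence[str],
    include_controls: bool = False,
) -> CaMatrix:
    """Subtract each sample's mean control-gene Ca from its other genes.

    This removes the per-sample template-loading factor. With
    ``include_controls=True`` the control genes themselves are also
    normalized against the control mean and kept in the output (useful
    for stability diagnostics); otherwise the output holds target genes
    only, with the controls recorded in ``control_genes``.

    Samples missing some (not all) control genes are normalized against
    the mean of the available ones, with a warning; a sample missing
    every control gene is an error.
    """
    controls = list(control_genes)
    if not controls:
        raise InvalidArgumentError("need at least one control gene")
    absent = [g for g in controls if g not in raw.values.columns]
    if absent:
        raise ConfigurationError(f"control gene(s) not in matrix: {absent}")

    ctrl = raw.values.loc[:, controls]
    n_avail = ctrl.notna().sum(axis=1)
    dead = list(ctrl.index[n_avail == 0])
    if dead:
        raise InsufficientDataError(
            f"sample(s) missing all control genes: {dead}"
        )
    partial = list(ctrl.index[(n_avail > 0) & (n_avail < len(controls))])
    if partial:
        logger.warning(
            "%d sample(s) missing some control genes; normalized against "
            "the mean of the available ones: %s", len(partial), partial,
        )
    ctrl_mean = ctrl.mean(axis=1, skipna=True)

    if include_controls:
        out_genes = list(raw.values.columns)
    else:
        out_genes = [g for g in raw.values.columns if g not in controls]
    values = raw.values.loc[:, out_genes].sub(ctrl_mean, axis=0)
    return CaMatrix(
        values=values,
        normalized=True,
        control_genes=tuple(controls),
        discordant=None if raw.discordant is None
        else raw.discordant.loc[:, out_genes],
    )
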