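"""Core data containers shared across the pipeline.

The pipeline moves through three representations:

* raw quantification cycles (``CpTable``): one row per (sample, gene,
  technical run), the atomic observable of a qPCR instrument;
* log2-scale relative abundances (``CaMatrix``): samples x genes, either
  raw (efficiency-calibrated only) or normalized against control genes;
* per-gene effect estimates (``EffectEstimate``): log2 effect sizes with
  uncertainty and multiplicity-adjusted significance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, SchemaError

CP_COLUMNS = ("sample_id", "gene_id", "run_id", "cp")


@dataclass(frozen=True)
class DilutionSeries:
    """A standard curve: (input amount, CP) pairs for one primer pair.

    Amounts are in arbitrary mass units (the assay used ng of
    RNA-equivalent template); only their ratios matter for the
    efficiency regression.
    """

    gene_id: str
    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.points) < 3:
            raise InvalidArgumentError(
                f"dilution series for {self.gene_id!r} needs >= 3 points, "
                f"got {len(self.points)}"
            )
        amounts = np.array([p[0] for p in self.points], dtype=float)
        if np.any(amounts <= 0) or not np.all(np.isfinite(amounts)):
            raise InvalidArgumentError("input amounts must be positive and finite")
        if np.unique(amounts).size < 2:
            raise InvalidArgumentError("need at least two distinct input amounts")

    @property
    def amounts(self) -> np.ndarray:
        return np.array([p[0] for p in self.points], dtype=float)

    @property
    def cps(self) -> np.ndarray:
        return np.array([p[1] for p in self.points], dtype=float)


@dataclass(frozen=True)
class EfficiencyEstimate:
    """Per-gene amplification factor E derived from a dilution series.

    ``slope`` is the OLS slope of CP on log2(input amount); a perfect
    assay doubles the template every cycle, giving slope -1 and E = 2.
    ``qc_pass`` records whether E falls in the accepted range; failing
    genes are flagged, never silently dropped.
    """

    gene_id: str
    slope: float
    efficiency: float
    r_squared: float
    qc_pass: bool

    @property
    def E(self) -> float:  # noqa: N802 - field notation of the assay
        return self.efficiency


class CpTable:
    """Raw quantification-cycle observations.

    One row per (sample_id, gene_id, run_id); duplicate keys are
    rejected because a run is the unit of technical replication.
    """

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in CP_COLUMNS if c not in data.columns]
        if missing:
            raise SchemaError(f"CpTable missing column(s): {', '.join(missing)}")
        df = data.loc[:, list(CP_COLUMNS)].copy()
        cp = pd.to_numeric(df["cp"], errors="coerce")
        if cp.isna().any() or not np.all(np.isfinite(cp.to_numpy(dtype=float))):
            raise InvalidArgumentError("cp values must be finite numbers")
        if (cp <= 0).any():
            raise InvalidArgumentError("cp values must be > 0")
        df["cp"] = cp.astype(float)
        key = df[["sample_id", "gene_id", "run_id"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0].tolist()
            raise SchemaError(f"duplicate (sample, gene, run) key: {dup}")
        self.data = df.reset_index(drop=True)

    @property
    def samples(self) -> list[str]:
        return sorted(self.data["sample_id"].unique())

    @property
    def genes(self) -> list[str]:
        return sorted(self.data["gene_id"].unique())

    def __len__(self) -> int:
        return len(self.data)

    def __repr__(self) -> str:
        return (
            f"CpTable({len(self.data)} observations, "
            f"{len(self.samples)} samples, {len(self.genes)} genes)"
        )


@dataclass
class CaMatrix:
    """Samples x genes grid of Ca values (log2 relative abundance).

    ``values`` holds NaN for explicitly missing cells — a cell that was
    never measured stays visible rather than being dropped.
    ``discordant`` (optional, same shape) flags cells whose technical
    duplicates disagreed by more than the discordance limit.
    """

    values: pd.DataFrame
    normalized: bool = False
    control_genes: tuple[str, ...] | None = None
    discordant: pd.DataFrame | None = None

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    def restrict(self, genes: Sequence[str]) -> "CaMatrix":
        """Return a view restricted to the given genes (order preserved)."""
        missing = [g for g in genes if g not in self.values.columns]
        if missing:
            raise InvalidArgumentError(f"genes not in matrix: {missing}")
        return CaMatrix(
            values=self.values.loc[:, list(genes)].copy(),
            normalized=self.normalized,
            control_genes=self.control_genes,
            discordant=None if self.discordant is None
            else self.discordant.loc[:, list(genes)].copy(),
        )


@dataclass
class FoldChange:
    """A log2 effect expressed on the fold scale with its direction."""

    fold: float        # 2**B, signed-on-log-scale convention
    magnitude: float   # 2**|B|, the "x-fold" number reported in prose
    direction: str     # 'up', 'down' or 'none'


@dataclass
class EffectEstimate:
    """One fixed-effect estimate from a gene-wise model.

    ``B`` is the log2 effect size (a difference of Ca values); ``fold``
    is exactly 2**B. ``p_adj`` stays None until a multiple-testing
    correction is applied across the gene panel.
    """

    gene_id: str
    term: str
    B: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    p_adj: float | None = None
    method: str = ""
    n_obs: int = 0
    boundary: bool = False
    extra: dict = field(default_factory=dict)

    @property
    def fold(self) -> float:
        return float(2.0 ** self.B)

    @property
    def fold_change(self) -> FoldChange:
        from .diffexpr import fold_change

        return fold_change(self.B)
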