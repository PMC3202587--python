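"""Reference-gene stability ranking (geNorm) and control-variation report.

A good reference gene keeps a constant expression *ratio* with every
other reference candidate across samples. For genes a and b the pairwise
variation V(a, b) is the standard deviation over samples of the log2
expression ratio, which on the Ca scale is simply sd(Ca_a - Ca_b). A
gene's stability value M is the mean of its pairwise variations with all
other candidates; the least stable gene (highest M) is excluded and M is
recomputed until two genes remain. Because V is computed on within-sample
differences, per-sample template-loading factors cancel exactly and
cannot create apparent instability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import CaMatrix
from .errors import DegenerateDesignError, InsufficientDataError, InvalidArgumentError


@dataclass
class StabilityRanking:
    """geNorm iterative-exclusion result.

    ``exclusion_order`` lists genes from least to most stable (the two
    survivors come last, ordered lexicographically — pairwise variation
    cannot distinguish them). ``m_at_removal`` holds each gene's M at the
    step it was removed; the two survivors share the final two-gene M.
    ``steps`` records the full M table of every iteration.
    """

    exclusion_order: list[str]
    m_at_removal: dict[str, float]
    steps: list[dict[str, float]]

    @property
    def most_stable(self) -> tuple[str, str]:
        return tuple(self.exclusion_order[-2:])  # type: ignore[return-value]


def pairwise_variation(ca: CaMatrix, gene_a: str, gene_b: str) -> float:
    """sd (n-1 denominator) over samples of Ca_a - Ca_b.

    Uses samples where both genes were measured; fewer than 3 common
    samples cannot support a standard deviation worth reporting.
    """
    for g in (gene_a, gene_b):
        if g not in ca.values.columns:
            raise InvalidArgumentError(f"gene {g!r} not in matrix")
    diff = (ca.values[gene_a] - ca.values[gene_b]).dropna()
    if len(diff) < 3:
        raise InsufficientDataError(
            f"genes {gene_a!r}, {gene_b!r}: only {len(diff)} common samples (< 3)"
        )
    return float(np.std(diff.to_numpy(), ddof=1))


def genorm_m(ca: CaMatrix, candidates: list[str]) -> pd.Series:
    """Stability value M per candidate: mean pairwise V with all others."""
    if len(candidates) < 3:
        raise InvalidArgumentError(
            f"geNorm needs >= 3 candidate genes, got {len(candidates)}"
        )
    m = {}
    for g in candidates:
        vs = [pairwise_variation(ca, g, k) for k in candidates if k != g]
        m[g] = float(np.mean(vs))
    return pd.Series(m, name="M").loc[candidates]


def genorm_rank(ca: CaMatrix, candidates: list[str]) -> StabilityRanking:
    """Iteratively exclude the least stable gene until two remain.

    Ties in the maximal M are broken deterministically by gene_id order
    (the lexicographically first tied gene is removed).
    """
    current = list(candidates)
    exclusion: list[str] = []
    m_at_removal: dict[str, float] = {}
    steps: list[dict[str, float]] = []
    while len(current) > 2:
        m = genorm_m(ca, current)
        steps.append(m.to_dict())
        worst_m = m.max()
        tied = sorted(g for g in current if m[g] == worst_m)
        worst = tied[0]
        exclusion.append(worst)
        m_at_removal[worst] = float(m[worst])
        current.remove(worst)
    # the two survivors share the final pairwise variation
    final_v = pairwise_variation(ca, current[0], current[1])
    survivors = sorted(current)
    steps.append({g: final_v for g in survivors})
    for g in survivors:
        m_at_removal[g] = final_v
    exclusion.extend(survivors)
    return StabilityRanking(
        exclusion_order=exclusion, m_at_removal=m_at_removal, steps=steps
    )


def control_variation(
    ca_normalized: CaMatrix,
    conditions: pd.Series,
    sd_multiplier: float = 1.0,
) -> pd.DataFrame:
    """Residual variation of control genes normalized against all candidates.

    For each gene, a condition-means model on its normalized Ca gives

    * ``between_condition_fold`` = 2**(max condition mean - min condition
      mean): how much the gene is regulated across experimental
      conditions, as a fold;
    * ``within_condition_fold`` = 2**(sd_multiplier * pooled residual sd):
      how much it fluctuates within a condition.

    ``conditions`` maps sample_id -> condition label and must contain at
    least two conditions with two samples each.
    """
    cond = conditions.reindex(ca_normalized.values.index)
    if cond.isna().any():
        missing = list(cond.index[cond.isna()])
        raise InvalidArgumentError(f"samples without condition label: {missing}")
    counts = cond.value_counts()
    if len(counts) < 2:
        raise DegenerateDesignError("need >= 2 conditions for control_variation")
    if (counts < 2).any():
        small = list(counts.index[counts < 2])
        raise DegenerateDesignError(f"condition(s) with < 2 samples: {small}")

    rows = {}
    for g in ca_normalized.values.columns:
        y = ca_normalized.values[g]
        ok = y.notna()
        means = y[ok].groupby(cond[ok]).mean()
        n = int(ok.sum())
        k = means.size
        ss_within = float(
            ((y[ok] - cond[ok].map(means)) ** 2).sum()
        )
        resid_sd = np.sqrt(ss_within / (n - k)) if n > k else 0.0
        rows[g] = {
            "between_condition_fold": float(2.0 ** (means.max() - means.min())),
            "within_condition_fold": float(2.0 ** (sd_multiplier * resid_sd)),
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("gene_id")
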