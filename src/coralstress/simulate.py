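"""Synthetic qPCR experiment generator.

Emulates the data-generating process the downstream analysis assumes:
multiplicative biology on the log2 (Ca) scale, additive cycle error on
the CP scale. For sample s and gene g the true log2 abundance is

    a(s, g) = baseline_g + colony(s, g) + tank(s, g)
              + effect(g, cell(s)) + residual(s, g)

and every gene of a sample shares that sample's template-loading factor
L(s), so the emitted crossing point per technical run is

    CP(s, g, run) = -(a(s, g) + L(s)) / log2(E_g) + technical noise.

Ground truth (all random draws, the expected Ca surface, and the sample
metadata) is returned alongside the CP table so parameter-recovery tests
can compare pipeline estimates with what was actually simulated.

Presets mirror the study designs this pipeline was written for: a paired
heat-light stress exposure (exp1), a stress/recovery factorial (exp2),
an unbalanced tank experiment on a congener (exp4) and a two-site field
comparison (field).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import CpTable, DilutionSeries
from .errors import InvalidArgumentError

Cell = tuple[str, ...]


@dataclass(frozen=True)
class GeneSpec:
    """One gene of the panel.

    role: 'target', 'control', 'psi_numerator' or 'psi_denominator'
    true_efficiency: per-cycle amplification factor (~1.85-2.15)
    baseline_level: mean log2 abundance (Ca units) in the control cell
    """

    gene_id: str
    role: str
    true_efficiency: float
    baseline_level: float

    def __post_init__(self) -> None:
        if self.true_efficiency <= 1.0:
            raise InvalidArgumentError(
                f"{self.gene_id}: true_efficiency must be > 1"
            )
        if self.role not in {"target", "control", "psi_numerator", "psi_denominator"}:
            raise InvalidArgumentError(f"{self.gene_id}: unknown role {self.role!r}")


@dataclass
class ScenarioConfig:
    """Generative parameters of one synthetic experiment.

    Effects are log2 shifts keyed by (gene_id, cell), where a cell is the
    tuple of factor levels — ``("heat",)`` for a single-factor design or
    ``("heat", "stress")`` for the treatment x time factorial. Cells
    without an entry default to 0. All standard deviations are in log2
    (Ca) units except ``technical_sd`` which is in CP cycles.
    """

    genes: list[GeneSpec]
    n_colonies: int
    treatments: list[str]
    timepoints: list[str] | None = None
    tanks_per_treatment: int | None = None
    replicates_per_colony_per_cell: int | tuple[int, int] = 1
    effects: dict[tuple[str, Cell], float] = field(default_factory=dict)
    colony_sd: float = 0.5
    tank_sd: float = 0.0
    residual_sd: float = 0.5
    loading_sd: float = 1.0
    technical_sd: float = 0.2
    n_runs: int = 2
    shared_colony_effects: bool = False
    factor_name: str = "treatment"
    control_level: str | None = None
    group_sizes: dict[Cell, int] | None = None
    replicate_overrides: dict[tuple[str, Cell], int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("colony_sd", "tank_sd", "residual_sd", "loading_sd",
                     "technical_sd"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be >= 0")
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise InvalidArgumentError("gene_id must be unique within a scenario")
        known = set(ids)
        self.effects = {
            (g, tuple(c) if isinstance(c, (tuple, list)) else (c,)): v
            for (g, c), v in self.effects.items()
        }
        for (g, _), _v in self.effects.items():
            if g not in known:
                raise InvalidArgumentError(f"effect refers to unknown gene {g!r}")
        if self.n_colonies < 1 and self.group_sizes is None:
            raise InvalidArgumentError("n_colonies must be >= 1")

    @property
    def cells(self) -> list[Cell]:
        if self.timepoints:
            return [(t, tp) for t in self.treatments for tp in self.timepoints]
        return [(t,) for t in self.treatments]

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    @property
    def control_genes(self) -> list[str]:
        return [g.gene_id for g in self.genes if g.role == "control"]

    @property
    def psi_pair(self) -> tuple[str, str] | None:
        num = [g.gene_id for g in self.genes if g.role == "psi_numerator"]
        den = [g.gene_id for g in self.genes if g.role == "psi_denominator"]
        if num and den:
            return num[0], den[0]
        return None

    def effect_for(self, gene_id: str, cell: Cell) -> float:
        return self.effects.get((gene_id, tuple(cell)), 0.0)

    def efficiency_map(self) -> dict[str, float]:
        return {g.gene_id: g.true_efficiency for g in self.genes}


@dataclass
class Truth:
    """Everything simulate_experiment drew, stored exactly as drawn."""

    config: ScenarioConfig
    metadata: pd.DataFrame                 # sample_id-indexed design table
    loading: pd.Series                     # per-sample loading factor L(s)
    colony_effects: pd.DataFrame           # colony x gene
    tank_effects: pd.DataFrame | None      # tank x gene (None if no tanks)
    residuals: pd.DataFrame                # sample x gene
    expected_ca: pd.DataFrame              # sample x gene, a(s,g) + L(s)

    def true_effect(self, gene_id: str, cell: Cell | str) -> float:
        cell_t = (cell,) if isinstance(cell, str) else tuple(cell)
        return self.config.effect_for(gene_id, cell_t)


def simulate_dilution_series(
    true_E: float,
    cp_at_max: float,
    n_points: int,
    fold_step: float,
    noise_sd: float,
    seed: int,
    gene_id: str = "gene",
    max_amount: float = 5.0,
) -> DilutionSeries:
    """Simulate a standard curve of ``n_points`` serial dilutions.

    Starting from ``max_amount`` (in arbitrary mass units; the assay's
    curves ran 5 ng down to 0.078 ng in 2-fold steps), each
    ``fold_step``-fold dilution raises the expected CP by
    log(fold_step)/log(true_E) cycles; Gaussian noise of ``noise_sd``
    cycles is added per point.
    """
    if true_E <= 1.0:
        raise InvalidArgumentError("true_E must be > 1")
    if n_points < 3:
        raise InvalidArgumentError("n_points must be >= 3")
    if fold_step <= 1.0:
        raise InvalidArgumentError("fold_step must be > 1")
    if max_amount <= 0:
        raise InvalidArgumentError("max_amount must be positive")
    if noise_sd < 0:
        raise InvalidArgumentError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    step_cycles = math.log(fold_step) / math.log(true_E)
    pts = []
    for i in range(n_points):
        amount = max_amount / fold_step**i
        cp = cp_at_max + i * step_cycles + rng.normal(0.0, noise_sd)
        pts.append((amount, float(cp)))
    return DilutionSeries(gene_id=gene_id, points=tuple(pts))


def _replicate_count(config: ScenarioConfig, rng: np.random.Generator,
                     colony: str, cell: Cell) -> int:
    if config.replicate_overrides is not None:
        key = (colony, tuple(cell))
        if key in config.replicate_overrides:
            return config.replicate_overrides[key]
    reps = config.replicates_per_colony_per_cell
    if isinstance(reps, tuple):
        return int(rng.integers(reps[0], reps[1] + 1))
    return int(reps)


def _cell_label(cell: Cell) -> str:
    return "_".join(cell)


def _build_samples(config: ScenarioConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Lay out the sample sheet (metadata) before drawing any noise."""
    rows = []
    if config.group_sizes is not None:
        # Unpaired design (field survey): every sample is its own colony.
        sizes = {tuple(c) if isinstance(c, (tuple, list)) else (c,): n
                 for c, n in config.group_sizes.items()}
        counter = 0
        for cell in config.cells:
            for i in range(sizes.get(cell, 0)):
                counter += 1
                rows.append(_sample_row(config, f"col{counter:02d}", cell, 1))
    else:
        for ci in range(1, config.n_colonies + 1):
            colony = f"col{ci:02d}"
            for cell in config.cells:
                n_rep = _replicate_count(config, rng, colony, cell)
                for rep in range(1, n_rep + 1):
                    rows.append(_sample_row(config, colony, cell, rep, ci))
    meta = pd.DataFrame(rows).set_index("sample_id")
    return meta


def _sample_row(config: ScenarioConfig, colony: str, cell: Cell,
                rep: int, colony_idx: int | None = None) -> dict:
    row: dict = {"colony": colony}
    row[config.factor_name] = cell[0]
    if config.timepoints:
        row["timepoint"] = cell[1]
    if config.tanks_per_treatment:
        # spread a colony's replicate fragments across its treatment's tanks
        k = ((colony_idx or 0) + rep - 1) % config.tanks_per_treatment + 1
        row["tank"] = f"{cell[0]}_tank{k}"
    sid = f"{colony}_{_cell_label(cell)}_r{rep}"
    row["sample_id"] = sid
    return row


def simulate_experiment(config: ScenarioConfig) -> tuple[CpTable, Truth]:
    """Draw one experiment from the generative model.

    Returns the emitted CP table (``n_runs`` technical runs per sample x
    gene) and a Truth object that round-trips with it: with all noise
    terms at zero, ``-cp * log2(E_g)`` equals ``expected_ca`` exactly.
    """
    rng = np.random.default_rng(config.seed)
    meta = _build_samples(config, rng)
    genes = config.gene_ids
    samples = list(meta.index)

    colonies = sorted(meta["colony"].unique())
    if config.shared_colony_effects:
        shared = rng.normal(0.0, config.colony_sd, size=len(colonies))
        colony_eff = pd.DataFrame(
            np.tile(shared[:, None], (1, len(genes))),
            index=colonies, columns=genes,
        )
    else:
        colony_eff = pd.DataFrame(
            rng.normal(0.0, config.colony_sd, size=(len(colonies), len(genes))),
            index=colonies, columns=genes,
        )

    tank_eff = None
    if "tank" in meta.columns:
        tanks = sorted(meta["tank"].unique())
        if config.shared_colony_effects:
            shared = rng.normal(0.0, config.tank_sd, size=len(tanks))
            tank_eff = pd.DataFrame(
                np.tile(shared[:, None], (1, len(genes))),
                index=tanks, columns=genes,
            )
        else:
            tank_eff = pd.DataFrame(
                rng.normal(0.0, config.tank_sd, size=(len(tanks), len(genes))),
                index=tanks, columns=genes,
            )

    loading = pd.Series(
        rng.normal(0.0, config.loading_sd, size=len(samples)),
        index=samples, name="loading",
    )
    residuals = pd.DataFrame(
        rng.normal(0.0, config.residual_sd, size=(len(samples), len(genes))),
        index=samples, columns=genes,
    )

    baseline = {g.gene_id: g.baseline_level for g in config.genes}
    eff_map = config.efficiency_map()

    expected = pd.DataFrame(0.0, index=samples, columns=genes)
    for sid in samples:
        row = meta.loc[sid]
        cell: Cell = (row[config.factor_name],)
        if config.timepoints:
            cell = (row[config.factor_name], row["timepoint"])
        for g in genes:
            a = (
                baseline[g]
                + colony_eff.loc[row["colony"], g]
                + (tank_eff.loc[row["tank"], g] if tank_eff is not None else 0.0)
                + config.effect_for(g, cell)
                + residuals.loc[sid, g]
            )
            expected.loc[sid, g] = a + loading[sid]

    records = []
    for sid in samples:
        for g in genes:
            base_cp = -expected.loc[sid, g] / math.log2(eff_map[g])
            noise = rng.normal(0.0, config.technical_sd, size=config.n_runs)
            for run in range(1, config.n_runs + 1):
                records.append(
                    (sid, g, f"run{run}", float(base_cp + noise[run - 1]))
                )
    cp_df = pd.DataFrame(records, columns=["sample_id", "gene_id", "run_id", "cp"])
    truth = Truth(
        config=config, metadata=meta, loading=loading,
        colony_effects=colony_eff, tank_effects=tank_eff,
        residuals=residuals, expected_ca=expected,
    )
    return CpTable(cp_df), truth


# ---------------------------------------------------------------------------
# Preset scenarios
# ---------------------------------------------------------------------------

_CONTROL_GENES = [
    GeneSpec("RPL11", "control", 1.98, -16.0),
    GeneSpec("EIF3H", "control", 1.93, -19.0),
    GeneSpec("ND5", "control", 2.02, -15.0),
    GeneSpec("G3PDH", "control", 1.90, -18.0),
    GeneSpec("GSP2", "control", 2.05, -20.0),
]

#: Control genes the pipeline normalizes against by default (the three
#: most stable of the five-candidate panel).
DEFAULT_NORMALIZATION_CONTROLS = ("RPL11", "EIF3H", "ND5")

_EXP1_TARGETS = [
    GeneSpec("Hsp16", "psi_numerator", 2.00, -24.0),
    GeneSpec("Actin", "psi_denominator", 2.00, -18.0),
    GeneSpec("ADK", "target", 1.95, -20.0),
    GeneSpec("C3", "target", 2.05, -19.0),
    GeneSpec("Clect", "target", 1.90, -21.0),
    GeneSpec("Chrom", "target", 2.10, -17.0),
    GeneSpec("Spon2", "target", 1.92, -20.0),
    GeneSpec("Ubl3", "target", 1.97, -21.0),
]

_EXP2_TARGETS = [
    GeneSpec("Hsp16", "psi_numerator", 2.00, -24.0),
    GeneSpec("Actin", "psi_denominator", 2.00, -18.0),
    GeneSpec("ADK", "target", 1.95, -20.0),
    GeneSpec("C3", "target", 2.05, -19.0),
    GeneSpec("Chrom", "target", 2.10, -17.0),
    GeneSpec("Ubl3", "target", 1.97, -21.0),
    GeneSpec("Hsp60", "target", 1.94, -19.0),
    GeneSpec("Hsp90", "target", 2.00, -17.0),
]

#: Default log2 effect sizes encode the stress-scenario fold changes the
#: pipeline is expected to recover: Hsp16 ~800x up, chromoprotein ~2x up,
#: actin ~4x down, C3 ~6x down in the acute-stress exposure; Hsp16 ~700x /
#: actin ~4x down / Hsp60 ~4x / Hsp90 ~6x at the factorial's stress time
#: point, with only Hsp16 (~8x) persisting at recovery.
EXP1_EFFECTS: dict[tuple[str, Cell], float] = {
    ("Hsp16", ("heat",)): math.log2(800.0),
    ("Chrom", ("heat",)): 1.0,
    ("Actin", ("heat",)): -2.0,
    ("C3", ("heat",)): -math.log2(6.0),
}

EXP2_EFFECTS: dict[tuple[str, Cell], float] = {
    ("Hsp16", ("heat", "stress")): math.log2(700.0),
    ("Hsp16", ("heat", "recovery")): 3.0,
    ("Actin", ("heat", "stress")): -2.0,
    ("Hsp60", ("heat", "stress")): 2.0,
    ("Hsp90", ("heat", "stress")): math.log2(6.0),
}

EXP4_EFFECTS: dict[tuple[str, Cell], float] = {
    ("Hsp16", ("heat",)): 2.0,
    ("Actin", ("heat",)): -1.0,
}

FIELD_EFFECTS: dict[tuple[str, Cell], float] = {
    ("Hsp16", ("inshore",)): 1.5,
    ("Actin", ("inshore",)): -0.5,
}

_PSI_GENES = [
    GeneSpec("Hsp16", "psi_numerator", 2.00, -24.0),
    GeneSpec("Actin", "psi_denominator", 2.00, -18.0),
]


def preset_scenario(name: str, seed: int = 0, n_colonies: int | None = None) -> ScenarioConfig:
    """Return a fully populated config for one of the study designs.

    exp1   5 colonies halved into paired control / heat-light stress.
    exp2   paired colonies x {control, heat} x {stress, recovery}
           (n_colonies parameterized, default 8).
    exp4   5 colonies, 3 tanks per treatment, 1-3 replicate fragments per
           colony per treatment, with the fifth colony represented by two
           control replicates only (unbalanced).
    field  two sites (9 inshore vs 7 offshore samples, distinct
           colonies) with a 2-log2-unit shift of the two-gene index.
    """
    if name == "exp1":
        return ScenarioConfig(
            genes=_EXP1_TARGETS + _CONTROL_GENES,
            n_colonies=n_colonies or 5,
            treatments=["control", "heat"],
            effects=dict(EXP1_EFFECTS),
            control_level="control",
            seed=seed,
        )
    if name == "exp2":
        return ScenarioConfig(
            genes=_EXP2_TARGETS + _CONTROL_GENES,
            n_colonies=n_colonies or 8,
            treatments=["control", "heat"],
            timepoints=["stress", "recovery"],
            effects=dict(EXP2_EFFECTS),
            control_level="control",
            seed=seed,
        )
    if name == "exp4":
        return ScenarioConfig(
            genes=list(_PSI_GENES),
            n_colonies=n_colonies or 5,
            treatments=["control", "heat"],
            tanks_per_treatment=3,
            replicates_per_colony_per_cell=(1, 3),
            replicate_overrides={
                ("col05", ("control",)): 2,
                ("col05", ("heat",)): 0,
            },
            effects=dict(EXP4_EFFECTS),
            tank_sd=0.25,
            control_level="control",
            seed=seed,
        )
    if name == "field":
        return ScenarioConfig(
            genes=list(_PSI_GENES),
            n_colonies=16,
            treatments=["offshore", "inshore"],
            factor_name="site",
            group_sizes={("inshore",): 9, ("offshore",): 7},
            effects=dict(FIELD_EFFECTS),
            colony_sd=0.0,
            residual_sd=math.sqrt(0.5**2 + 0.5**2),
            control_level="offshore",
            seed=seed,
        )
    raise KeyError(f"unknown preset scenario {name!r}")


def null_scenario(base: ScenarioConfig) -> ScenarioConfig:
    """Copy of a scenario with every fixed effect set to zero."""
    return replace(base, effects={})


def with_seed(config: ScenarioConfig, seed: int) -> ScenarioConfig:
    return replace(config, seed=seed)
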