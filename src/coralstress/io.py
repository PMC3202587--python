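"""CSV interchange formats.

All tables are plain CSV (comma separated, header row, UTF-8, '.'
decimal). Column contracts:

* CP table:        sample_id, gene_id, run_id, cp
* dilution series: gene_id, amount, cp
* metadata:        sample_id plus design columns (colony, treatment,
                   timepoint, tank, site — whichever apply)
* efficiencies:    gene_id, slope, efficiency, r_squared, qc_pass
* Ca matrix:       samples as rows, genes as columns; the first line is
                   a comment recording the normalized flag and controls
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .datatypes import CaMatrix, CpTable, DilutionSeries, EfficiencyEstimate
from .errors import SchemaError
from .simulate import Truth

logger = logging.getLogger(__name__)


def read_cp_table(path) -> CpTable:
    """Read and validate a CP table CSV.

    Rows with an empty / NA cp are skipped with a logged warning (failed
    wells are a fact of qPCR life); any other non-numeric cp is an error
    naming the offending line.
    """
    df = pd.read_csv(path, dtype={"cp": object})
    missing = [c for c in ("sample_id", "gene_id", "run_id", "cp")
               if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s): {', '.join(missing)}")
    raw = df["cp"]
    na_like = raw.isna() | raw.astype(str).str.strip().str.upper().isin(
        {"", "NA", "NAN", "N/A"}
    )
    numeric = pd.to_numeric(raw, errors="coerce")
    bad = numeric.isna() & ~na_like
    if bad.any():
        line = int(bad.idxmax()) + 2  # header is line 1
        raise SchemaError(
            f"{path}: non-numeric cp value {raw[bad.idxmax()]!r} on line {line}"
        )
    if na_like.any():
        logger.warning(
            "%s: skipped %d row(s) with missing cp", path, int(na_like.sum())
        )
    df = df.loc[~na_like].copy()
    df["cp"] = numeric[~na_like].astype(float)
    return CpTable(df)


def write_cp_table(table: CpTable, path) -> None:
    table.data.to_csv(path, index=False)


def read_dilution_table(path) -> dict[str, DilutionSeries]:
    """Read a dilution-series CSV (gene_id, amount, cp) into per-gene series."""
    df = pd.read_csv(path)
    missing = [c for c in ("gene_id", "amount", "cp") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s): {', '.join(missing)}")
    out = {}
    for gene, sub in df.groupby("gene_id"):
        pts = tuple(zip(sub["amount"].astype(float), sub["cp"].astype(float)))
        out[str(gene)] = DilutionSeries(gene_id=str(gene), points=pts)
    return out


def write_dilution_table(series_map: dict[str, DilutionSeries], path) -> None:
    rows = [
        {"gene_id": s.gene_id, "amount": a, "cp": c}
        for s in series_map.values() for a, c in s.points
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise SchemaError(f"{path}: missing column(s): sample_id")
    if df["sample_id"].duplicated().any():
        raise SchemaError(f"{path}: duplicate sample_id values")
    return df.set_index("sample_id")


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.rename_axis("sample_id").to_csv(path)


def write_efficiencies(estimates: dict[str, EfficiencyEstimate], path) -> None:
    rows = [
        {"gene_id": e.gene_id, "slope": e.slope, "efficiency": e.efficiency,
         "r_squared": e.r_squared, "qc_pass": e.qc_pass}
        for e in estimates.values()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_efficiencies(path) -> dict[str, float]:
    df = pd.read_csv(path)
    missing = [c for c in ("gene_id", "efficiency") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s): {', '.join(missing)}")
    return dict(zip(df["gene_id"].astype(str), df["efficiency"].astype(float)))


def write_ca_matrix(ca: CaMatrix, path) -> None:
    """Write a Ca matrix with its normalized flag in a header comment."""
    controls = ",".join(ca.control_genes) if ca.control_genes else ""
    header = f"# normalized={str(ca.normalized).lower()} controls={controls}\n"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        ca.values.rename_axis("sample_id").to_csv(fh, float_format="%.10g")


def read_ca_matrix(path) -> CaMatrix:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        normalized = False
        controls: tuple[str, ...] | None = None
        if first.startswith("#"):
            fields = dict(
                tok.split("=", 1) for tok in first[1:].strip().split() if "=" in tok
            )
            normalized = fields.get("normalized", "false") == "true"
            ctrl = fields.get("controls", "")
            controls = tuple(ctrl.split(",")) if ctrl else None
            values = pd.read_csv(fh, index_col="sample_id")
        else:
            fh.seek(0)
            values = pd.read_csv(fh, index_col="sample_id")
    values.columns.name = "gene_id"
    return CaMatrix(values=values, normalized=normalized, control_genes=controls)


def write_truth(truth: Truth, path) -> None:
    """Structured JSON sidecar with everything the generator drew."""
    payload = {
        "effects": [
            {"gene_id": g, "cell": list(c), "effect": v}
            for (g, c), v in truth.config.effects.items()
        ],
        "loading": truth.loading.to_dict(),
        "colony_effects": truth.colony_effects.to_dict(),
        "tank_effects": (
            None if truth.tank_effects is None else truth.tank_effects.to_dict()
        ),
        "expected_ca": truth.expected_ca.to_dict(),
        "seed": truth.config.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def write_effects_table(effects: pd.DataFrame, path) -> None:
    effects.to_csv(path, index=False, float_format="%.10g")


def write_psi(psi_values: pd.Series, path) -> None:
    psi_values.rename("psi").rename_axis("sample_id").to_csv(path)
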