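"""Table schemas, validating readers, and provenance-stamped writers.

Every table crossing a stage boundary is a tidy CSV with unit-suffixed
column names (conc_M, h_nm, time_h, ...) so units cannot silently drift.
Validation is strict: a schema violation produces a row-indexed error
report naming the file, row, and column; values are never silently
coerced.  JSON reports carry a provenance block (package version, seed,
and a hash of the generating configuration) so any stage can be rerun
bit-for-bit from its on-disk inputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "TITRATION_SCHEMA",
    "AFM_SCHEMA",
    "PLATE_SCHEMA",
    "GROWTH_SCHEMA",
    "validate_table",
    "read_titration_csv",
    "read_afm_csv",
    "read_plate_csv",
    "read_growth_csv",
    "write_report",
    "provenance",
]


class SchemaError(ValueError):
    """Raised on table-validation failure; ``errors`` is row-indexed."""

    def __init__(self, path, errors: list[str]):
        self.path = str(path)
        self.errors = errors
        super().__init__(f"{path}: {len(errors)} schema violation(s):\n" + "\n".join(errors))


@dataclass(frozen=True)
class ColumnSpec:
    name: str
    kind: str            # "number" | "bool" | "str"
    required: bool = True
    positive: bool = False
    nonnegative: bool = False
    allow_na: bool = False


TITRATION_SCHEMA = (
    ColumnSpec("curve_id", "str"),
    ColumnSpec("conc_M", "number", nonnegative=True),
    ColumnSpec("signal", "number"),
    ColumnSpec("signal_sd", "number", required=False, positive=True, allow_na=True),
    ColumnSpec("DT_hint_M", "number", required=False, positive=True, allow_na=True),
)

AFM_SCHEMA = (
    ColumnSpec("peak_id", "str"),
    ColumnSpec("h_nm", "number", positive=True),
    ColumnSpec("w_long_nm", "number", positive=True),
    ColumnSpec("w_orth_nm", "number", positive=True),
    ColumnSpec("dna_bound", "bool"),
    ColumnSpec("h_dna_nm", "number", required=False, positive=True, allow_na=True),
    ColumnSpec("w_dna_nm", "number", required=False, positive=True, allow_na=True),
)

PLATE_SCHEMA = (
    ColumnSpec("substrate_mM", "number", positive=True, allow_na=True),
    ColumnSpec("replicate", "number"),
    ColumnSpec("luminescence", "number", positive=True),
    ColumnSpec("is_control", "bool"),
)

GROWTH_SCHEMA = (
    ColumnSpec("strain", "str"),
    ColumnSpec("time_h", "number", nonnegative=True),
    ColumnSpec("od600", "number", nonnegative=True),
    ColumnSpec("replicate", "number", required=False),
)


def validate_table(path, schema, df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Validate a CSV (or an in-memory frame) against a column schema.

    Returns the validated frame; raises :class:`SchemaError` listing every
    violation as ``row <i>, column <name>: <problem>``.
    """
    if df is None:
        df = pd.read_csv(path)
    errors: list[str] = []
    for col in schema:
        if col.name not in df.columns:
            if col.required:
                errors.append(f"missing required column {col.name!r}")
            continue
        s = df[col.name]
        if col.kind == "number":
            coerced = pd.to_numeric(s, errors="coerce")
            bad = coerced.isna() & s.notna()
            for i in df.index[bad]:
                errors.append(f"row {i}, column {col.name}: not numeric ({s[i]!r})")
            if not col.allow_na:
                for i in df.index[s.isna()]:
                    errors.append(f"row {i}, column {col.name}: missing value")
            if col.positive:
                for i in df.index[(coerced <= 0) & coerced.notna()]:
                    errors.append(f"row {i}, column {col.name}: must be > 0 (got {s[i]})")
            if col.nonnegative:
                for i in df.index[(coerced < 0) & coerced.notna()]:
                    errors.append(f"row {i}, column {col.name}: must be >= 0 (got {s[i]})")
        elif col.kind == "bool":
            ok = s.isin([True, False, 0, 1, "True", "False", "true", "false"])
            for i in df.index[~ok]:
                errors.append(f"row {i}, column {col.name}: not boolean ({s[i]!r})")
    if errors:
        raise SchemaError(path, errors)
    return df


def read_titration_csv(path) -> pd.DataFrame:
    return validate_table(path, TITRATION_SCHEMA)


def read_afm_csv(path) -> pd.DataFrame:
    """Read and validate an AFM measurement sheet.

    Beyond column checks, enforces the invariant that DNA-bound peaks
    carry positive adjacent-DNA measurements.
    """
    df = validate_table(path, AFM_SCHEMA)
    bound = df["dna_bound"].astype(bool)
    errors = []
    for c in ("h_dna_nm", "w_dna_nm"):
        if c not in df.columns:
            if bound.any():
                errors.append(f"missing column {c!r} required for DNA-bound peaks")
            continue
        bad = bound & df[c].isna()
        for i in df.index[bad]:
            errors.append(
                f"row {i}, column {c}: DNA-bound peak requires a positive adjacent-DNA measurement"
            )
    if errors:
        raise SchemaError(path, errors)
    return df


def read_plate_csv(path) -> pd.DataFrame:
    return validate_table(path, PLATE_SCHEMA)


def read_growth_csv(path) -> pd.DataFrame:
    df = validate_table(path, GROWTH_SCHEMA)
    errors = []
    group_cols = ["strain"] + (["replicate"] if "replicate" in df.columns else [])
    for key, grp in df.groupby(group_cols):
        t = grp["time_h"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            errors.append(f"series {key}: time_h must be strictly increasing")
    if errors:
        raise SchemaError(path, errors)
    return df


def provenance(config: dict, seed: int | None = None) -> dict:
    """Provenance block: config hash, seed, package version."""
    from . import __version__

    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "config_sha256": hashlib.sha256(payload).hexdigest(),
        "seed": seed,
        "version": __version__,
    }


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(path, payload: dict, config: dict | None = None, seed: int | None = None):
    """Write a JSON report with an attached provenance block."""
    out = dict(_jsonable(payload))
    out["provenance"] = provenance(config or {}, seed)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(out, fh, indent=2, sort_keys=True)
        fh.write("\n")
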