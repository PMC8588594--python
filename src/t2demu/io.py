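"""CSV serialization of training tables and binary model persistence."""

from __future__ import annotations

import json
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from .emulator import EmulatorResults, INPUT_COLUMNS
from .surrogate import OUTPUT_COLUMNS, TABLE_COLUMNS

__all__ = [
    "SchemaError",
    "read_training_table",
    "write_training_table",
    "save_model",
    "load_model",
]


class SchemaError(ValueError):
    """A serialized table does not match the expected schema."""


def write_training_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a long-format table as UTF-8 CSV ('.' decimal, header required).

    Floats are written at full repr precision so a write/read round trip is
    lossless to at least 15 significant digits.
    """
    table.to_csv(path, index=False)


def read_training_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format trajectory table."""
    df = pd.read_csv(path)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    for col in TABLE_COLUMNS:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            raise SchemaError(
                f"{path}: non-numeric value in column {col!r} at row "
                f"{int(bad.idxmax())}"
            )
        if numeric.isna().any():
            raise SchemaError(
                f"{path}: missing value in column {col!r} at row "
                f"{int(numeric.isna().idxmax())}"
            )
        df[col] = numeric
    return df


def save_model(results: EmulatorResults, path: str | Path) -> None:
    """Persist a fitted emulator (joblib) with a JSON metadata sidecar."""
    path = Path(path)
    joblib.dump(results, path)
    sidecar = {
        "format_version": 1,
        "feature_schema": INPUT_COLUMNS,
        "outputs": OUTPUT_COLUMNS,
        "n_trees": results.n_trees,
        "seed": results.seed,
        "oob_error": results.oob_error,
        "residual_cov": np.asarray(results.residual_cov).tolist(),
        "n_rows": len(results.model.table),
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2)
    )


def load_model(path: str | Path) -> EmulatorResults:
    return joblib.load(path)
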