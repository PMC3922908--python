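"""File formats: study CSV, covariance text files, and JSON artifacts.

CSV tables are comma-separated with a mandatory header, UTF-8, LF line
endings, and empty fields for missing item scores.  Covariance matrices
travel as plain text with an ``n=<sample size>`` header line.  JSON
artifacts are pretty-printed with sorted keys so that reruns are
byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cfa import CFAFit, FitIndices
from .model import DEFAULT_SPEC, ITEM_COLUMNS, METADATA_COLUMNS, HBMModelSpec
from . import __version__ as _pkg_version


class SchemaError(ValueError):
    """Raised when an input table does not match the expected layout."""


def write_table(table: pd.DataFrame, path) -> None:
    """Write a study table as CSV (missing scores become empty fields)."""
    table.to_csv(path, index=False, lineterminator="\n", encoding="utf-8")


def read_table(path, spec: HBMModelSpec = DEFAULT_SPEC) -> pd.DataFrame:
    """Read and validate a study CSV.

    Item columns are coerced to nullable integers when every observed value
    is integral (ordinal data), otherwise kept as floats (continuous mode).
    """
    df = pd.read_csv(path, encoding="utf-8")
    items = list(ITEM_COLUMNS[: spec.n_items])
    missing_cols = [c for c in METADATA_COLUMNS + tuple(items) if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"input table lacks required columns: {missing_cols}")
    block = df[items]
    vals = block.to_numpy(dtype=float)
    observed = vals[~np.isnan(vals)]
    if observed.size and np.all(observed == np.round(observed)):
        df[items] = block.astype("Int64")
        bad = (observed < 1) | (observed > 5)
        if bad.any():
            raise SchemaError("ordinal item scores must lie in 1..5")
    return df


def write_covariance(S: np.ndarray, n: int, path) -> None:
    """Write a symmetric covariance with its sample size to plain text."""
    S = np.asarray(S, dtype=float)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"n={int(n)}\n")
        for row in S:
            fh.write(" ".join(f"{v:.12g}" for v in row) + "\n")


def read_covariance(path) -> tuple[np.ndarray, int]:
    """Read a covariance text file; returns (S, n)."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
        if not header.startswith("n="):
            raise SchemaError("covariance file must start with an 'n=' header line")
        n = int(header[2:])
        S = np.loadtxt(fh)
    S = np.atleast_2d(S)
    if S.shape[0] != S.shape[1] or not np.allclose(S, S.T, atol=1e-8):
        raise SchemaError("covariance matrix must be square and symmetric")
    return (S + S.T) / 2.0, n


def write_json(obj: dict, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def write_fit_artifact(fit: CFAFit, path, seed: int | None = None) -> None:
    """Persist a fitted CFA as JSON, with seed and version provenance."""
    payload = fit.to_dict()
    payload["software_version"] = _pkg_version
    payload["seed"] = seed
    write_json(payload, path)


def read_weights(path) -> np.ndarray:
    """Load the total-effect weight vector W from a fit artifact."""
    payload = read_json(path)
    w = np.asarray(payload["total_effects"], dtype=float)
    if not np.all(np.isfinite(w)):
        raise SchemaError("fit artifact holds non-finite weights")
    return w


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
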