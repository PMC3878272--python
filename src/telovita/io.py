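"""Schema-checked delimited-table I/O and run manifests.

All writes are atomic (temp file + rename).  Unknown columns warn;
missing required columns or malformed numeric cells fail fast naming the
offending row and column.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
import warnings

import numpy as np
import pandas as pd

from .errors import SchemaError

#: required columns and dtypes per table kind
SCHEMAS = {
    "cohort": {
        "id": int, "sex": str, "entry_age_months": float,
        "exit_age_months": float, "event": int,
    },
    "panel": {
        "age": float, "sex": str, "organ": str, "replicate": int, "trf_bp": float,
    },
    "assay_panel": {
        "age": float, "sex": str, "organ": str, "replicate": int,
        "e2": float, "t": float, "kt11": float, "ta_rel": float, "trf_bp": float,
    },
    "lane": {"position_mm": float, "od": float},
    "ladder": {"size_bp": float, "position_mm": float},
    "amplification": {
        "sample": str, "replicate": int, "cycle": int, "fluorescence": float,
    },
    "survival_curve": {
        "time": float, "s": float, "lo": float, "hi": float,
        "at_risk": int, "events": int,
    },
    "pairing": {
        "age": float, "survival": float, "mean_trf": float, "sex": str,
    },
}


def read_table(path, schema):
    spec = SCHEMAS[schema]
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = set(spec) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required columns {sorted(missing)}")
    extra = set(df.columns) - set(spec)
    if extra:
        warnings.warn(f"{path}: ignoring unknown columns {sorted(extra)}",
                      stacklevel=2)
    for col, typ in spec.items():
        if typ in (float, int):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = int(np.nonzero(bad.to_numpy())[0][0])
                raise SchemaError(
                    f"{path}: malformed numeric value {df[col].iloc[row]!r} "
                    f"in column '{col}', row {row}")
            df[col] = coerced.astype(typ) if not coerced.isna().any() else coerced
        else:
            df[col] = df[col].astype(str)
    return df


def write_table(df, path, schema=None):
    if schema is not None:
        missing = set(SCHEMAS[schema]) - set(df.columns)
        if missing:
            raise SchemaError(f"refusing to write {path}: missing {sorted(missing)}")
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    _atomic_write(path, df.to_csv(index=False, sep=sep))


def write_json(obj, path):
    _atomic_write(path, json.dumps(obj, indent=2, sort_keys=True, default=_jsonify))


def _jsonify(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, tuple):
        return list(v)
    raise TypeError(f"not JSON serialisable: {type(v)}")


def _atomic_write(path, text):
    d = os.path.dirname(os.path.abspath(path))
    os.makedirs(d, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def sha256_file(path):
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
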