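"""Reflection-table input/output.

The canonical interchange format is a plain text table (whitespace- or
comma-delimited, auto-detected) with a header row naming the columns
H K L, D or S2, IOBS, SIGIOBS, CENTRIC, EPSILON and optionally
SIGMA_EXPECTED plus any derived columns.  MTZ reading is an optional
convenience behind a gemmi import; centricity and epsilon then come from the
file's space group.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import REQUIRED_COLUMNS

__all__ = ["read_reflections", "write_reflections", "read_mtz"]

log = logging.getLogger("diffinfo")

_OPTIONAL_COLUMNS = ["SIGMA_EXPECTED", "ZOBS", "SIGZ", "INFO_BITS", "KEEP"]


def _validate(df: pd.DataFrame, path) -> pd.DataFrame:
    if "S2" in df.columns and "D" not in df.columns:
        df["D"] = 1.0 / np.sqrt(df["S2"].astype(float))
    if "EPSILON" not in df.columns:
        df["EPSILON"] = 1
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    n_raw = len(df)
    df = df[df["IOBS"].notna()].reset_index(drop=True)
    if len(df) < n_raw:
        log.info("%s: skipped %d rows with missing IOBS", path, n_raw - len(df))
    bad = df.index[df["SIGIOBS"].astype(float) <= 0.0].tolist()
    if bad:
        raise ValueError(f"{path}: non-positive SIGIOBS on rows {bad[:10]}")
    dup = df.duplicated(subset=["H", "K", "L"])
    if dup.any():
        raise ValueError(
            f"{path}: duplicate Miller indices at rows {df.index[dup].tolist()[:10]}"
        )
    for col in ("H", "K", "L", "EPSILON"):
        df[col] = df[col].astype(int)
    df["CENTRIC"] = df["CENTRIC"].astype(int)
    return df


def read_reflections(path, fmt: str = "auto") -> pd.DataFrame:
    """Read a reflection table (text dialect, or MTZ when requested/detected)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "mtz" or (fmt == "auto" and path.suffix.lower() == ".mtz"):
        return read_mtz(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "," if "," in header else r"\s+"
    df = pd.read_csv(path, sep=sep, comment="#", float_precision="round_trip")
    return _validate(df, path)


def write_reflections(df: pd.DataFrame, path) -> None:
    """Write the canonical text table at full float precision.

    Derived columns (SIGMA_EXPECTED, ZOBS, SIGZ, INFO_BITS, KEEP) are
    emitted when present; simulation ground-truth columns are dropped.
    """
    from .simulate import TRUTH_COLUMNS

    cols = [c for c in REQUIRED_COLUMNS if c in df.columns]
    cols += [c for c in _OPTIONAL_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols and c not in TRUTH_COLUMNS]
    out = df[cols]
    with open(path, "w") as fh:
        fh.write(" ".join(cols) + "\n")
        for row in out.itertuples(index=False):
            fields = []
            for col, val in zip(cols, row):
                if col in ("H", "K", "L", "CENTRIC", "EPSILON", "KEEP"):
                    fields.append(str(int(val)))
                else:
                    fields.append(format(float(val), ".17g"))
            fh.write(" ".join(fields) + "\n")


def read_mtz(path) -> pd.DataFrame:
    """Read reflections from an MTZ file via gemmi (optional dependency).

    Centricity and epsilon are derived from the file's space group.  Looks
    for intensity/sigma columns of MTZ types J/Q (first match wins).
    """
    try:
        import gemmi
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError("MTZ reading requires the optional gemmi dependency") from exc

    mtz = gemmi.read_mtz_file(str(path))
    i_col = next((c for c in mtz.columns if c.type == "J"), None)
    sig_col = next((c for c in mtz.columns if c.type == "Q"), None)
    if i_col is None or sig_col is None:
        raise ValueError(f"{path}: no intensity (J) / sigma (Q) column pair found")
    hkl = np.array(mtz.make_miller_array(), dtype=int)
    gops = mtz.spacegroup.operations()
    centric = np.array([gops.is_reflection_centric(m) for m in hkl], dtype=int)
    epsilon = np.array([gops.epsilon_factor(m) for m in hkl], dtype=int)
    d = mtz.make_d_array()
    df = pd.DataFrame({
        "H": hkl[:, 0], "K": hkl[:, 1], "L": hkl[:, 2],
        "D": d,
        "IOBS": np.array(i_col), "SIGIOBS": np.array(sig_col),
        "CENTRIC": centric, "EPSILON": epsilon,
    })
    return _validate(df, path)
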