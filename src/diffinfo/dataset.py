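"""Dataset-level information analysis: normalization, totals, shells, pruning.

A dataset is a pandas DataFrame with the canonical reflection columns
(H, K, L, D, IOBS, SIGIOBS, CENTRIC, EPSILON and optionally SIGMA_EXPECTED).
The pipeline is: ``normalize`` fills the normalized intensity Z_O and its
standard deviation sigma_Z; ``analyze`` fills per-reflection information in
bits and aggregates totals and resolution-shell statistics; ``prune``
separates reflections below an information threshold.  Input frames are
never mutated — every step returns a copy, so the original data are left
unaltered.

Normalization divides by ``epsilon * Sigma`` where Sigma is the expected
intensity.  If a SIGMA_EXPECTED column is present (from an upstream
anisotropy/tNCS analysis) it is used exactly; otherwise Sigma is estimated
isotropically as a smoothed binned mean of I/epsilon against 1/d^2.  The
isotropic estimate ignores anisotropy and tNCS, which inflates the apparent
information of systematically strengthened reflections — supply a corrected
SIGMA_EXPECTED whenever those effects are present.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .infogain import (
    expected_info_gain,
    info_gain_acentric_nats,
    info_gain_centric_nats,
    LN2,
)

__all__ = ["ShellStats", "PruneReport", "normalize", "analyze", "prune", "shell_table"]

REQUIRED_COLUMNS = ["H", "K", "L", "D", "IOBS", "SIGIOBS", "CENTRIC", "EPSILON"]

_MIN_RECORDS_FOR_ESTIMATE = 50


@dataclass(frozen=True)
class ShellStats:
    """Aggregates for one resolution shell (equal-population, 1/d^3 order)."""

    shell: int
    d_max: float
    d_min: float
    n_reflections: int
    mean_bits: float
    total_bits: float
    mean_i_over_sigma: float


@dataclass(frozen=True)
class PruneReport:
    """Outcome of information-threshold pruning."""

    threshold_bits: float
    mode: str
    n_total: int
    n_kept: int
    n_excluded: int
    total_bits_kept: float
    shells: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "threshold_bits": self.threshold_bits,
            "mode": self.mode,
            "n_total": self.n_total,
            "n_kept": self.n_kept,
            "n_excluded": self.n_excluded,
            "total_bits_kept": self.total_bits_kept,
            "shells": [vars(s) for s in self.shells],
        }


def _require(df: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"reflection table is missing columns: {missing}")


def _estimate_sigma_expected(df: pd.DataFrame, n_bins: int) -> np.ndarray:
    """Isotropic expected intensity from binned means of I/epsilon vs 1/d^2."""
    s2 = 1.0 / df["D"].to_numpy() ** 2
    i_over_eps = df["IOBS"].to_numpy() / df["EPSILON"].to_numpy()
    order = np.argsort(s2)
    bins = np.array_split(order, n_bins)
    if any(len(b) == 0 for b in bins):
        raise ValueError(f"cannot form {n_bins} non-empty resolution bins from {len(df)} rows")
    centers = np.array([s2[b].mean() for b in bins])
    means = np.array([i_over_eps[b].mean() for b in bins])
    if np.any(means <= 0.0):
        # noise-dominated bins can average below zero; clamp to the smallest
        # positive bin mean so normalization stays defined
        floor = means[means > 0.0].min() if np.any(means > 0.0) else 1.0
        means = np.clip(means, floor, None)
    # interpolate the log of the binned mean linearly in s^2 (Wilson falloff
    # is log-linear in s^2, so this is the natural smoothing)
    return np.exp(np.interp(s2, centers, np.log(means)))


def normalize(df: pd.DataFrame, n_bins: int = 20) -> pd.DataFrame:
    """Fill Z_O (ZOBS) and sigma_Z (SIGZ) columns.

    Uses SIGMA_EXPECTED exactly when present on every row; otherwise
    estimates an isotropic expected-intensity curve (requires at least 50
    reflections).
    """
    _require(df, REQUIRED_COLUMNS)
    if (df["SIGIOBS"] <= 0.0).any():
        bad = df.index[df["SIGIOBS"] <= 0.0].tolist()
        raise ValueError(f"SIGIOBS must be positive; offending rows: {bad[:10]}")
    out = df.copy()
    if "SIGMA_EXPECTED" in df.columns and df["SIGMA_EXPECTED"].notna().all():
        sigma_big = df["SIGMA_EXPECTED"].to_numpy(dtype=float)
        if (sigma_big <= 0.0).any():
            raise ValueError("SIGMA_EXPECTED must be positive")
    elif "SIGMA_EXPECTED" in df.columns and df["SIGMA_EXPECTED"].notna().any():
        raise ValueError("SIGMA_EXPECTED must be supplied for all rows or none")
    else:
        if len(df) < _MIN_RECORDS_FOR_ESTIMATE:
            raise ValueError(
                f"isotropic Sigma estimation needs at least {_MIN_RECORDS_FOR_ESTIMATE} "
                f"reflections (got {len(df)}); supply SIGMA_EXPECTED instead"
            )
        sigma_big = _estimate_sigma_expected(df, n_bins)
        out["SIGMA_EXPECTED"] = sigma_big
    denom = df["EPSILON"].to_numpy(dtype=float) * sigma_big
    out["ZOBS"] = df["IOBS"].to_numpy(dtype=float) / denom
    out["SIGZ"] = df["SIGIOBS"].to_numpy(dtype=float) / denom
    return out


def _info_bits(z_obs: np.ndarray, sigma_z: np.ndarray, centric: np.ndarray) -> np.ndarray:
    bits = np.empty(z_obs.size)
    acent = ~centric
    if acent.any():
        bits[acent] = info_gain_acentric_nats(z_obs[acent], sigma_z[acent]) / LN2
    for i in np.flatnonzero(centric):
        bits[i] = info_gain_centric_nats(z_obs[i], sigma_z[i]) / LN2
    return bits


def _expected_bits(sigma_z: np.ndarray, centric: np.ndarray) -> np.ndarray:
    # expected info depends only on (sigma_z, centricity); cache rounded keys
    bits = np.empty(sigma_z.size)
    cache: dict = {}
    for i in range(sigma_z.size):
        key = (round(float(sigma_z[i]), 6), bool(centric[i]))
        if key not in cache:
            cache[key] = expected_info_gain(max(key[0], 1e-6), key[1]).bits
        bits[i] = cache[key]
    return bits


def analyze(df: pd.DataFrame, mode: str = "actual", n_shells: int = 20):
    """Fill per-reflection INFO_BITS and aggregate totals and shells.

    ``mode="actual"`` evaluates the measurement-specific KL divergence of
    each reflection; ``mode="expected"`` evaluates the observation-averaged
    expected information at each reflection's sigma_Z (the earlier,
    threshold-table criterion).  Returns ``(frame, shells, total_bits)``.
    """
    if mode not in ("actual", "expected"):
        raise ValueError(f"unknown mode {mode!r}")
    if "ZOBS" not in df.columns or "SIGZ" not in df.columns:
        raise ValueError("records are not normalized; call normalize() first")
    out = df.copy()
    z = df["ZOBS"].to_numpy(dtype=float)
    s = df["SIGZ"].to_numpy(dtype=float)
    cen = df["CENTRIC"].to_numpy().astype(bool)
    if mode == "actual":
        out["INFO_BITS"] = _info_bits(z, s, cen)
    else:
        out["INFO_BITS"] = _expected_bits(s, cen)
    shells = shell_table(out, n_shells=min(n_shells, len(out)))
    return out, shells, float(out["INFO_BITS"].sum())


def shell_table(df: pd.DataFrame, n_shells: int = 20) -> list[ShellStats]:
    """Equal-population resolution shells in 1/d^3 order with mean bits."""
    if n_shells < 1:
        raise ValueError("n_shells must be at least 1")
    if n_shells > len(df):
        raise ValueError(f"cannot form {n_shells} shells from {len(df)} reflections")
    if "INFO_BITS" not in df.columns:
        raise ValueError("records are not analyzed; call analyze() first")
    d = df["D"].to_numpy(dtype=float)
    order = np.argsort(1.0 / d**3, kind="stable")
    stats = []
    for idx, members in enumerate(np.array_split(order, n_shells)):
        sub = df.iloc[members]
        i_over_sig = (sub["IOBS"] / sub["SIGIOBS"]).mean()
        stats.append(ShellStats(
            shell=idx,
            d_max=float(sub["D"].max()),
            d_min=float(sub["D"].min()),
            n_reflections=int(len(sub)),
            mean_bits=float(sub["INFO_BITS"].mean()),
            total_bits=float(sub["INFO_BITS"].sum()),
            mean_i_over_sigma=float(i_over_sig),
        ))
    return stats


def prune(df: pd.DataFrame, threshold_bits: float = 0.01, mode: str = "actual",
          n_shells: int = 20):
    """Split analyzed records at an information threshold.

    Reflections conveying strictly less than ``threshold_bits`` are excluded;
    a reflection at exactly the threshold is kept.  Returns
    ``(kept_frame, report)``; the input frame is not modified.
    """
    if threshold_bits < 0.0:
        raise ValueError("threshold_bits must be non-negative")
    if "INFO_BITS" not in df.columns:
        raise ValueError("records are not analyzed; call analyze() first")
    keep = df["INFO_BITS"].to_numpy(dtype=float) >= threshold_bits
    out = df.copy()
    out["KEEP"] = keep.astype(int)
    kept = out.loc[keep].copy()
    shells = shell_table(out, n_shells=min(n_shells, len(out)))
    report = PruneReport(
        threshold_bits=float(threshold_bits),
        mode=mode,
        n_total=int(len(df)),
        n_kept=int(keep.sum()),
        n_excluded=int((~keep).sum()),
        total_bits_kept=float(df["INFO_BITS"].to_numpy()[keep].sum()),
        shells=shells,
    )
    return kept, report
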