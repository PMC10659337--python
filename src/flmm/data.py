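"""Core containers for trial-structured functional data.

A functional dataset couples a trial-by-time signal matrix (e.g. ΔF/F
sampled at a fixed rate around an alignment event) with a trial-level
covariate table and the common time grid. All model fitting downstream
operates on these three pieces.
"""

from __future__ import annotations

import dataclasses
import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TimeGrid",
    "FunctionalDataset",
    "ValidationError",
    "load_wide_csv",
    "load_long_csv",
    "write_result_tables",
    "read_result_table",
]

RESERVED_ID_COLUMNS = ("subject", "session", "trial")


class ValidationError(ValueError):
    """Raised when an input table or signal matrix violates the data contract."""


@dataclasses.dataclass(frozen=True)
class TimeGrid:
    """Equally spaced time points, in seconds relative to the alignment event.

    Parameters
    ----------
    points : ndarray
        Strictly increasing, equally spaced time offsets. ``points[0]`` is
        the earliest time; the alignment event sits at t = 0 by convention.
    rate : float
        Sampling rate in samples per second; must equal ``1 / spacing``.
    """

    points: np.ndarray
    rate: float

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 1 or pts.size < 1:
            raise ValidationError("time grid needs at least 1 point")
        if pts.size == 1:
            # degenerate single-point grid: scalar-outcome collapse
            return
        diffs = np.diff(pts)
        if np.any(diffs <= 0):
            raise ValidationError("time grid must be strictly increasing")
        spacing = diffs[0]
        if not np.allclose(diffs, spacing, rtol=1e-8, atol=1e-12):
            raise ValidationError("time grid must be equally spaced")
        if not np.isclose(self.rate * spacing, 1.0, rtol=1e-6):
            raise ValidationError(
                f"rate ({self.rate}) inconsistent with grid spacing ({spacing})"
            )

    @classmethod
    def regular(cls, time_start: float, n_points: int, rate: float) -> "TimeGrid":
        pts = time_start + np.arange(n_points) / rate
        return cls(points=pts, rate=float(rate))

    @property
    def n_points(self) -> int:
        return self.points.size

    def window_indices(self, a: float, b: float) -> np.ndarray:
        """Indices of grid points inside the closed interval [a, b]."""
        eps = 1e-9
        return np.where((self.points >= a - eps) & (self.points <= b + eps))[0]

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.points.size


def _validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    for col in RESERVED_ID_COLUMNS:
        if col not in trials.columns:
            raise ValidationError(f"trial table missing required column '{col}'")
    if trials["subject"].isna().any():
        bad = trials.index[trials["subject"].isna()].tolist()
        raise ValidationError(f"missing subject id in rows {bad}")
    for col in ("session", "trial"):
        vals = pd.to_numeric(trials[col], errors="coerce")
        if vals.isna().any() or (vals < 1).any() or (vals != vals.round()).any():
            raise ValidationError(f"column '{col}' must contain integers >= 1")
    keys = trials[list(RESERVED_ID_COLUMNS)]
    dup = keys.duplicated(keep=False)
    if dup.any():
        rows = keys[dup].drop_duplicates().to_records(index=False).tolist()
        raise ValidationError(f"duplicate (subject, session, trial) keys: {rows}")
    out = trials.reset_index(drop=True).copy()
    out["session"] = out["session"].astype(int)
    out["trial"] = out["trial"].astype(int)
    return out


@dataclasses.dataclass
class FunctionalDataset:
    """Trial × time signal matrix bound to a trial table and a time grid.

    Invariants: ``Y.shape == (len(trials), grid.n_points)``; values are
    finite except in rows flagged missing (missing samples are handled by
    per-column case deletion in the pointwise engine, never imputed).
    Trial row order is arbitrary and carries no meaning.
    """

    Y: np.ndarray
    grid: TimeGrid
    trials: pd.DataFrame

    def __post_init__(self):
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.ndim != 2:
            raise ValidationError("Y must be a 2-D trial x time matrix")
        self.trials = _validate_trials(self.trials)
        if self.Y.shape[0] != len(self.trials):
            raise ValidationError(
                f"Y has {self.Y.shape[0]} rows but trial table has {len(self.trials)}"
            )
        if self.Y.shape[1] != self.grid.n_points:
            raise ValidationError(
                f"Y has {self.Y.shape[1]} columns but grid has {self.grid.n_points} points"
            )

    @property
    def n_trials(self) -> int:
        return self.Y.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.Y.shape[1]

    @property
    def covariate_columns(self) -> list[str]:
        return [c for c in self.trials.columns if c not in RESERVED_ID_COLUMNS]

    def subset_rows(self, idx: np.ndarray) -> "FunctionalDataset":
        return FunctionalDataset(
            Y=self.Y[idx],
            grid=self.grid,
            trials=self.trials.iloc[idx].reset_index(drop=True),
        )

    def to_wide_frame(self, signal_prefix: str = "sig") -> pd.DataFrame:
        sig = pd.DataFrame(
            self.Y, columns=[f"{signal_prefix}{k}" for k in range(self.n_timepoints)]
        )
        return pd.concat([self.trials.reset_index(drop=True), sig], axis=1)


def load_wide_csv(
    path, signal_prefix: str = "sig", time_start: float = 0.0, rate: float = 15.0
) -> FunctionalDataset:
    """Read the wide CSV dialect: id/covariate columns plus ``<prefix>0..<prefix>{S-1}``.

    The grid is reconstructed as ``time_start + k / rate``. A row with any
    non-finite signal sample is rejected with a message naming its
    (subject, session, trial) key.
    """
    df = pd.read_csv(path)
    pat = re.compile(re.escape(signal_prefix) + r"(\d+)$")
    sig_cols = {}
    for c in df.columns:
        m = pat.fullmatch(str(c))
        if m:
            sig_cols[int(m.group(1))] = c
    if not sig_cols:
        raise ValidationError(f"no signal columns with prefix '{signal_prefix}' found")
    S = max(sig_cols) + 1
    missing = sorted(set(range(S)) - set(sig_cols))
    if missing:
        raise ValidationError(
            f"signal columns not consecutively numbered; missing indices {missing[:10]}"
        )
    ordered = [sig_cols[k] for k in range(S)]
    Y = df[ordered].to_numpy(dtype=float)
    trials = df.drop(columns=ordered)
    trials_valid = _validate_trials(trials)
    bad = ~np.isfinite(Y).all(axis=1)
    if bad.any():
        keys = trials_valid.loc[bad, list(RESERVED_ID_COLUMNS)]
        raise ValidationError(
            "non-finite signal values in rows (subject, session, trial): "
            f"{keys.to_records(index=False).tolist()}"
        )
    grid = TimeGrid.regular(time_start, S, rate)
    return FunctionalDataset(Y=Y, grid=grid, trials=trials_valid)


def load_long_csv(path, value_column: str = "value", time_column: str = "time") -> FunctionalDataset:
    """Read long-format CSV (subject, session, trial, time, value, covariates) and pivot to wide."""
    df = pd.read_csv(path)
    needed = set(RESERVED_ID_COLUMNS) | {value_column, time_column}
    miss = needed - set(df.columns)
    if miss:
        raise ValidationError(f"long CSV missing columns {sorted(miss)}")
    times = np.sort(df[time_column].unique())
    if times.size < 2:
        raise ValidationError("long CSV must contain at least 2 distinct time points")
    spacing = np.diff(times)
    rate = 1.0 / spacing[0]
    grid = TimeGrid(points=times.astype(float), rate=rate)
    wide = df.pivot_table(
        index=list(RESERVED_ID_COLUMNS), columns=time_column, values=value_column
    )
    wide = wide.reindex(columns=times)
    cov_cols = [c for c in df.columns if c not in needed]
    meta = df.drop_duplicates(list(RESERVED_ID_COLUMNS)).set_index(
        list(RESERVED_ID_COLUMNS)
    )[cov_cols]
    meta = meta.loc[wide.index]
    trials = meta.reset_index()
    Y = wide.to_numpy(dtype=float)
    if not np.isfinite(Y).all():
        bad = ~np.isfinite(Y).all(axis=1)
        keys = trials.loc[bad, list(RESERVED_ID_COLUMNS)]
        raise ValidationError(
            "incomplete trials in long CSV (subject, session, trial): "
            f"{keys.to_records(index=False).tolist()}"
        )
    return FunctionalDataset(Y=Y, grid=grid, trials=trials)


def write_result_tables(result, out_dir) -> list[Path]:
    """Write one CSV per coefficient plus a JSON sidecar describing the fit.

    Each CSV has columns time, estimate, se, pw_lower, pw_upper,
    joint_lower, joint_upper (full float precision so a round trip is exact).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for band in result.bands:
        df = pd.DataFrame(
            {
                "time": band.time,
                "estimate": band.estimate,
                "se": band.se,
                "pw_lower": band.pw_bounds[:, 0],
                "pw_upper": band.pw_bounds[:, 1],
                "joint_lower": band.joint_bounds[:, 0],
                "joint_upper": band.joint_bounds[:, 1],
            }
        )
        safe = re.sub(r"[^A-Za-z0-9_.-]", "_", band.name)
        p = out / f"coef_{safe}.csv"
        df.to_csv(p, index=False)  # pandas writes shortest round-trip repr
        written.append(p)
    sidecar = out / "fit_info.json"
    info = dict(result.info)
    info["multipliers"] = {b.name: b.q_joint for b in result.bands}
    with open(sidecar, "w") as fh:
        json.dump(info, fh, indent=2, default=_json_default)
    written.append(sidecar)
    return written


def read_result_table(path) -> pd.DataFrame:
    # round_trip parsing: the default C parser can be off by one ULP
    return pd.read_csv(path, float_precision="round_trip")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
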