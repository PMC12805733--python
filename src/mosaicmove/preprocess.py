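"""Telemetry ingestion and step-table construction with data-cleaning rules.

Fixed-interval GPS collars (nominally one fix every 20 minutes) produce a
time-ordered sequence of fixes per individual.  The segment between two
consecutive fixes is a *step* — the basic unit of every downstream
analysis.  Three cleaning rules are applied:

1. speed outliers — steps whose length exceeds the individual's empirical
   99th percentile are removed (implausible displacement for the interval);
2. long gaps — steps spanning more than 60 minutes (three or more missed
   fixes) are removed;
3. zero flooring — for the traversal-time regression only, zero-length
   steps are floored to 1 m because the model works on log step length.

Filters flag rows rather than dropping them, so every rule is idempotent
and removal counts are exactly recoverable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .landscape import ConfigurationError

#: Default local-time offset from UTC for diel binning (study region uses
#: UTC-4 standard time).
DEFAULT_TZ_OFFSET_HOURS = -4

#: Default Movebank-dialect column names.
MOVEBANK_COLUMNS: dict[str, str] = {
    "individual_id": "individual-local-identifier",
    "timestamp": "timestamp",
    "x": "x",
    "y": "y",
    "lon": "location-long",
    "lat": "location-lat",
    "sex": "sex",
}


class FormatError(ValueError):
    """Raised when an input file does not match the expected dialect."""


@dataclass
class Trajectory:
    """One individual's time-ordered GPS fixes plus metadata.

    ``fixes`` has columns ``timestamp`` (tz-aware UTC), ``x`` and ``y``
    (planar metres).  ``truth`` optionally carries simulator ground truth
    (latent states, traversal times, injected-artifact labels) and is never
    consulted by the analysis itself.
    """

    individual_id: str
    sex: str = "unknown"
    fixes: pd.DataFrame = field(default_factory=pd.DataFrame)
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.fixes):
            ts = self.fixes["timestamp"]
            if not ts.is_monotonic_increasing or ts.duplicated().any():
                raise ValueError(
                    f"{self.individual_id}: timestamps must be strictly increasing"
                )

    @property
    def n_fixes(self) -> int:
        return len(self.fixes)


# ---------------------------------------------------------------------------
# Geographic -> planar projection (transverse Mercator / UTM, WGS84)
# ---------------------------------------------------------------------------

_WGS84_A = 6378137.0
_WGS84_F = 1.0 / 298.257223563
_UTM_K0 = 0.9996


def utm_forward(
    lon: np.ndarray, lat: np.ndarray, lon0_deg: float
) -> tuple[np.ndarray, np.ndarray]:
    """Forward transverse-Mercator projection (metres) about ``lon0_deg``.

    Classic series expansion on the WGS84 ellipsoid; accurate to well under
    a metre anywhere inside a UTM zone, which is ample for 20-minute animal
    steps.  The standard 500 km false easting is applied.
    """
    e2 = _WGS84_F * (2 - _WGS84_F)
    ep2 = e2 / (1 - e2)
    phi = np.radians(np.asarray(lat, dtype=float))
    lam = np.radians(np.asarray(lon, dtype=float) - lon0_deg)

    sin_p, cos_p, tan_p = np.sin(phi), np.cos(phi), np.tan(phi)
    n_rad = _WGS84_A / np.sqrt(1 - e2 * sin_p**2)
    t = tan_p**2
    c = ep2 * cos_p**2
    a_term = lam * cos_p
    m = _WGS84_A * (
        (1 - e2 / 4 - 3 * e2**2 / 64 - 5 * e2**3 / 256) * phi
        - (3 * e2 / 8 + 3 * e2**2 / 32 + 45 * e2**3 / 1024) * np.sin(2 * phi)
        + (15 * e2**2 / 256 + 45 * e2**3 / 1024) * np.sin(4 * phi)
        - (35 * e2**3 / 3072) * np.sin(6 * phi)
    )
    x = (
        _UTM_K0
        * n_rad
        * (
            a_term
            + (1 - t + c) * a_term**3 / 6
            + (5 - 18 * t + t**2 + 72 * c - 58 * ep2) * a_term**5 / 120
        )
        + 500_000.0
    )
    y = _UTM_K0 * (
        m
        + n_rad
        * tan_p
        * (
            a_term**2 / 2
            + (5 - t + 9 * c + 4 * c**2) * a_term**4 / 24
            + (61 - 58 * t + t**2 + 600 * c - 330 * ep2) * a_term**6 / 720
        )
    )
    return x, y


def _project_lonlat(df: pd.DataFrame) -> pd.DataFrame:
    """Project lon/lat columns to the UTM zone of the track centroid."""
    lon0 = math.floor(df["lon"].mean() / 6.0) * 6.0 + 3.0
    x, y = utm_forward(df["lon"].to_numpy(), df["lat"].to_numpy(), lon0)
    out = df.copy()
    out["x"], out["y"] = x, y
    return out


# ---------------------------------------------------------------------------
# Movebank-style CSV I/O
# ---------------------------------------------------------------------------

def write_movebank_csv(
    trajectories: Iterable[Trajectory],
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> None:
    """Write trajectories to a Movebank-style CSV with planar coordinates."""
    cols = dict(MOVEBANK_COLUMNS, **(column_map or {}))
    frames = []
    for traj in trajectories:
        df = pd.DataFrame(
            {
                cols["individual_id"]: traj.individual_id,
                cols["sex"]: traj.sex,
                cols["timestamp"]: traj.fixes["timestamp"].dt.strftime(
                    "%Y-%m-%dT%H:%M:%SZ"
                ),
                cols["x"]: traj.fixes["x"],
                cols["y"]: traj.fixes["y"],
            }
        )
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.8f")


def read_tracks(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> list[Trajectory]:
    """Read a Movebank-style CSV into one ``Trajectory`` per individual.

    Fixes are sorted by timestamp within individual; duplicate timestamps
    are rejected.  If only geographic coordinates are present they are
    projected to the UTM zone of each individual's centroid so that all
    downstream distances are metre-true.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cols = dict(MOVEBANK_COLUMNS, **(column_map or {}))
    df = pd.read_csv(path)

    for key in ("individual_id", "timestamp"):
        if cols[key] not in df.columns:
            raise FormatError(f"missing required column {cols[key]!r}")
    planar = cols["x"] in df.columns and cols["y"] in df.columns
    geographic = cols["lon"] in df.columns and cols["lat"] in df.columns
    if not planar and not geographic:
        raise FormatError(
            f"need either planar columns ({cols['x']!r}, {cols['y']!r}) or "
            f"geographic columns ({cols['lon']!r}, {cols['lat']!r})"
        )

    ts = pd.to_datetime(df[cols["timestamp"]], utc=True, errors="coerce")
    bad = ts.isna() & df[cols["timestamp"]].notna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 zero-based
        raise FormatError(
            f"unparseable timestamp {df.loc[bad.idxmax(), cols['timestamp']]!r} "
            f"at line {line}"
        )

    work = pd.DataFrame({"individual_id": df[cols["individual_id"]].astype(str), "timestamp": ts})
    work["sex"] = (
        df[cols["sex"]].astype(str).str.lower() if cols["sex"] in df.columns else "unknown"
    )
    if planar:
        work["x"] = df[cols["x"]].astype(float)
        work["y"] = df[cols["y"]].astype(float)
    else:
        work["lon"] = df[cols["lon"]].astype(float)
        work["lat"] = df[cols["lat"]].astype(float)

    trajectories = []
    for ind, grp in work.groupby("individual_id", sort=True):
        grp = grp.sort_values("timestamp").reset_index(drop=True)
        if grp["timestamp"].duplicated().any():
            raise FormatError(f"duplicate timestamps for individual {ind!r}")
        if not planar:
            grp = _project_lonlat(grp)
        sex = grp["sex"].iloc[0]
        if sex not in ("female", "male"):
            sex = "unknown"
        trajectories.append(
            Trajectory(
                individual_id=str(ind),
                sex=sex,
                fixes=grp[["timestamp", "x", "y"]].reset_index(drop=True),
            )
        )
    return trajectories


# ---------------------------------------------------------------------------
# Step table
# ---------------------------------------------------------------------------

STEP_COLUMNS = [
    "individual_id",
    "sex",
    "step_id",
    "fix_index",
    "t_start",
    "x0",
    "y0",
    "x1",
    "y1",
    "d",
    "t_min",
    "theta",
    "hour",
    "removed_speed",
    "removed_gap",
    "floored_zero",
]


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap angles to [-pi, pi] (with +pi mapped to -pi... then fixed to +pi
    boundary-inclusive so the interval is [-pi, pi])."""
    out = np.mod(a + np.pi, 2 * np.pi) - np.pi
    return out


def build_steps(
    traj: Trajectory, tz_offset_hours: float = DEFAULT_TZ_OFFSET_HOURS
) -> pd.DataFrame:
    """Derive the per-step table from a trajectory.

    N fixes yield N-1 steps with Euclidean length ``d`` (m), duration
    ``t_min`` (minutes), signed turning angle ``theta`` in [-pi, pi]
    (positive = left turn; missing for the first step and wherever either
    adjacent segment has zero length) and local clock ``hour`` of the start
    fix.
    """
    n = traj.n_fixes
    if n < 2:
        import warnings

        warnings.warn(f"{traj.individual_id}: fewer than 2 fixes, empty step table")
        return pd.DataFrame(columns=STEP_COLUMNS)
    f = traj.fixes
    x = f["x"].to_numpy(dtype=float)
    y = f["y"].to_numpy(dtype=float)
    t = f["timestamp"]
    dx, dy = np.diff(x), np.diff(y)
    d = np.hypot(dx, dy)
    t_min = t.diff().dt.total_seconds().to_numpy()[1:] / 60.0
    heading = np.arctan2(dy, dx)
    theta = np.full(n - 1, np.nan)
    if n > 2:
        raw = _wrap_angle(heading[1:] - heading[:-1])
        ok = (d[1:] > 0) & (d[:-1] > 0)
        theta[1:] = np.where(ok, raw, np.nan)
    local = t + pd.to_timedelta(tz_offset_hours, unit="h")
    hour = local.dt.hour.to_numpy()[:-1]
    return pd.DataFrame(
        {
            "individual_id": traj.individual_id,
            "sex": traj.sex,
            "step_id": [f"{traj.individual_id}:{i}" for i in range(n - 1)],
            "fix_index": np.arange(n - 1),
            "t_start": t.iloc[:-1].to_numpy(),
            "x0": x[:-1],
            "y0": y[:-1],
            "x1": x[1:],
            "y1": y[1:],
            "d": d,
            "t_min": t_min,
            "theta": theta,
            "hour": hour,
            "removed_speed": False,
            "removed_gap": False,
            "floored_zero": False,
        }
    )


def build_step_table(
    trajectories: Iterable[Trajectory],
    tz_offset_hours: float = DEFAULT_TZ_OFFSET_HOURS,
) -> pd.DataFrame:
    """Concatenate per-individual step tables."""
    frames = [build_steps(t, tz_offset_hours) for t in trajectories]
    frames = [f for f in frames if len(f)]
    if not frames:
        return pd.DataFrame(columns=STEP_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def retained_mask(steps: pd.DataFrame) -> pd.Series:
    """Steps surviving both cleaning rules."""
    return ~(steps["removed_speed"] | steps["removed_gap"])


def _refresh_theta(steps: pd.DataFrame) -> pd.DataFrame:
    """Recompute turning-angle validity after filtering.

    The heading chain breaks wherever the immediately preceding step of the
    same individual was removed (or floored): the following step's turning
    angle becomes missing.
    """
    out = steps.copy()
    for _, idx in out.groupby("individual_id", sort=False).groups.items():
        sub = out.loc[idx].sort_values("fix_index")
        kept = retained_mask(sub).to_numpy() & ~sub["floored_zero"].to_numpy()
        fix_idx = sub["fix_index"].to_numpy()
        dx = sub["x1"].to_numpy() - sub["x0"].to_numpy()
        dy = sub["y1"].to_numpy() - sub["y0"].to_numpy()
        d = np.hypot(dx, dy)
        heading = np.arctan2(dy, dx)
        theta = np.full(len(sub), np.nan)
        for i in range(1, len(sub)):
            contiguous = fix_idx[i] == fix_idx[i - 1] + 1
            if (
                contiguous
                and kept[i]
                and kept[i - 1]
                and d[i] > 0
                and d[i - 1] > 0
            ):
                theta[i] = _wrap_angle(np.array([heading[i] - heading[i - 1]]))[0]
        out.loc[sub.index, "theta"] = theta
    return out


def filter_speed_outliers(steps: pd.DataFrame, quantile: float = 0.99) -> pd.DataFrame:
    """Flag implausibly long steps: ``d`` strictly above the individual's
    empirical ``quantile`` of step length (linear-interpolation quantile).

    The threshold is computed per individual over *all* of that
    individual's steps (including previously flagged rows), which makes the
    filter idempotent.
    """
    out = steps.copy()
    if out.empty:
        return out
    thresh = out.groupby("individual_id")["d"].transform(
        lambda s: np.quantile(s.to_numpy(), quantile)
    )
    out["removed_speed"] = out["d"].to_numpy() > thresh.to_numpy()
    return _refresh_theta(out)


def filter_long_gaps(steps: pd.DataFrame, max_minutes: float = 60.0) -> pd.DataFrame:
    """Flag steps spanning strictly more than ``max_minutes``."""
    out = steps.copy()
    if out.empty:
        return out
    out["removed_gap"] = out["t_min"].to_numpy() > max_minutes
    return _refresh_theta(out)


def floor_zero_steps(steps: pd.DataFrame, floor_m: float = 1.0) -> pd.DataFrame:
    """Floor zero-length steps to ``floor_m`` (traversal-time branch only).

    The time regression works on log step length, so exact zeros are
    replaced by the shortest observable step; floored steps keep no turning
    angle.
    """
    if floor_m <= 0:
        raise ConfigurationError("floor_m must be positive")
    out = steps.copy()
    zero = out["d"].to_numpy() == 0.0
    out.loc[zero, "d"] = floor_m
    out["floored_zero"] = out["floored_zero"].to_numpy() | zero
    return _refresh_theta(out)


def preprocess_steps(
    steps: pd.DataFrame,
    quantile: float = 0.99,
    max_gap_minutes: float = 60.0,
) -> pd.DataFrame:
    """Apply the cleaning rules in their fixed order: speed, then gaps."""
    return filter_long_gaps(filter_speed_outliers(steps, quantile), max_gap_minutes)


def filter_summary(steps: pd.DataFrame) -> pd.DataFrame:
    """Per-individual counts removed by each rule and retained."""
    def _agg(g: pd.DataFrame) -> pd.Series:
        return pd.Series(
            {
                "n_steps": len(g),
                "removed_speed": int(g["removed_speed"].sum()),
                "removed_gap": int(g["removed_gap"].sum()),
                "floored_zero": int(g["floored_zero"].sum()),
                "retained": int(retained_mask(g).sum()),
            }
        )

    return steps.groupby("individual_id").apply(_agg, include_groups=False).reset_index()
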