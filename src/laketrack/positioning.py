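"""From raw position estimates to quality-filtered 15-min q-positions.

A *q-position* is the mean of all raw fixes of one fish within one
clock-aligned 15-minute interval (left-closed, right-open on the UTC
grid).  Depth is averaged over every detection carrying a sensor
reading, so an interval can have a depth without planar coordinates.
Short positioning gaps are filled by linear interpolation when the
bracketing q-positions are close in time (< 2 h), space (< 100 m) and
depth (< 2 m); tags that go motionless until the end of their series
are flagged as dead or tag-expelling.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import shapely

from .lake import LakeGrid

__all__ = [
    "filter_positions",
    "regularize",
    "interpolate_gaps",
    "distance_to_bottom",
    "flag_mortality",
    "INTERVAL_S",
]

log = logging.getLogger(__name__)

INTERVAL_S = 900  # q-position interval length, seconds


def _ensure_sorted(fixes: pd.DataFrame) -> pd.DataFrame:
    return fixes.sort_values(["tag_id", "timestamp"], kind="mergesort").reset_index(drop=True)


def filter_positions(
    fixes: pd.DataFrame,
    lake: LakeGrid | None = None,
    max_speed: float = 2.0,
    boundary_buffer: float = 50.0,
) -> pd.DataFrame:
    """Remove duplicate, out-of-lake and speed-implausible fixes.

    Three rules, applied in order per tag:

    1. exact duplicates (same tag and timestamp) collapse to the first row;
    2. fixes outside the shoreline polygon buffered outward by
       ``boundary_buffer`` metres are dropped;
    3. fixes implying a speed above ``max_speed`` m/s to *both* temporal
       neighbours are dropped, iterating until stable.

    Per-rule removal counts are logged and stored in
    ``result.attrs["filter_counts"]``.  Empty input returns empty output.
    """
    counts = {"duplicate": 0, "boundary": 0, "speed": 0}
    if fixes.empty:
        out = fixes.copy()
        out.attrs["filter_counts"] = counts
        return out
    df = _ensure_sorted(fixes)

    dup = df.duplicated(subset=["tag_id", "timestamp"], keep="first")
    counts["duplicate"] = int(dup.sum())
    df = df.loc[~dup]

    if lake is None:
        warnings.warn("no lake supplied; boundary rule skipped", stacklevel=2)
    else:
        boundary = lake.shoreline.buffer(boundary_buffer)
        has_xy = df["x"].notna() & df["y"].notna()
        inside = np.ones(len(df), dtype=bool)
        if has_xy.any():
            inside[has_xy.to_numpy()] = shapely.contains_xy(
                boundary, df.loc[has_xy, "x"].to_numpy(), df.loc[has_xy, "y"].to_numpy()
            )
        counts["boundary"] = int((~inside).sum())
        df = df.loc[inside]

    kept = []
    for _, g in df.groupby("tag_id", sort=False):
        xy = g["x"].notna() & g["y"].notna()
        pos = g.loc[xy]
        rest = g.loc[~xy]
        t = pos["timestamp"].to_numpy(dtype="datetime64[ns]").astype("int64") / 1e9
        x = pos["x"].to_numpy(dtype=float)
        y = pos["y"].to_numpy(dtype=float)
        keep = np.ones(len(pos), dtype=bool)
        while True:
            idx = np.flatnonzero(keep)
            if idx.size < 3:
                break
            ti, xi, yi = t[idx], x[idx], y[idx]
            seg = np.hypot(np.diff(xi), np.diff(yi)) / np.maximum(np.diff(ti), 1e-9)
            bad_mid = (seg[:-1] > max_speed) & (seg[1:] > max_speed)
            if not bad_mid.any():
                break
            keep[idx[1:-1][bad_mid]] = False
        counts["speed"] += int((~keep).sum())
        kept.append(pd.concat([pos.loc[keep], rest]))
    out = _ensure_sorted(pd.concat(kept)) if kept else df
    out = out.reset_index(drop=True)
    out.attrs["filter_counts"] = counts
    log.info("position filter removals: %s", counts)
    return out


def regularize(fixes: pd.DataFrame) -> pd.DataFrame:
    """Collapse raw fixes to 15-min q-positions.

    Coordinates average over positioned fixes; depth averages over every
    fix with a sensor reading (depth-only detections included), so at
    most 96 q-positions exist per tag per day.  Intervals with neither a
    position nor a depth are absent from the output.
    """
    cols = [
        "tag_id", "interval_start", "x", "y", "depth",
        "n_fixes", "n_depth_fixes", "interpolated",
    ]
    if fixes.empty:
        return pd.DataFrame(columns=cols)
    df = fixes.copy()
    df["interval_start"] = pd.to_datetime(df["timestamp"]).dt.floor(f"{INTERVAL_S}s")
    has_xy = df["x"].notna() & df["y"].notna()
    df["_x"] = df["x"].where(has_xy)
    df["_y"] = df["y"].where(has_xy)
    g = df.groupby(["tag_id", "interval_start"], sort=True)
    out = g.agg(
        x=("_x", "mean"),
        y=("_y", "mean"),
        depth=("depth", "mean"),
        n_fixes=("_x", "count"),
        n_depth_fixes=("depth", "count"),
    ).reset_index()
    out = out.loc[(out["n_fixes"] > 0) | (out["n_depth_fixes"] > 0)].reset_index(drop=True)
    out["interpolated"] = False
    return out[cols]


def interpolate_gaps(
    qpos: pd.DataFrame,
    max_gap: float = 7200.0,
    max_dist: float = 100.0,
    max_ddepth: float = 2.0,
) -> pd.DataFrame:
    """Fill runs of missing intervals by linear interpolation.

    A gap between consecutive q-positions P and Q is filled only when
    all three conditions hold strictly: the time difference is shorter
    than ``max_gap`` seconds, their planar distance is less than
    ``max_dist`` metres, and their depth difference is less than
    ``max_ddepth`` metres.  If P or Q lacks coordinates or depth, the
    gap is left open.  Filled records are flagged ``interpolated`` with
    zero fix counts.  Idempotent.
    """
    if qpos.empty:
        return qpos.copy()
    parts = [qpos]
    step = pd.Timedelta(seconds=INTERVAL_S)
    for tag, g in qpos.groupby("tag_id", sort=False):
        g = g.sort_values("interval_start")
        t = g["interval_start"].to_numpy()
        x = g["x"].to_numpy(dtype=float)
        y = g["y"].to_numpy(dtype=float)
        z = g["depth"].to_numpy(dtype=float)
        dt_s = np.diff(t) / np.timedelta64(1, "s")
        for i in np.flatnonzero(dt_s > INTERVAL_S):
            if not (dt_s[i] < max_gap):
                continue
            if np.isnan(x[i]) or np.isnan(x[i + 1]) or np.isnan(y[i]) or np.isnan(y[i + 1]):
                continue
            if np.isnan(z[i]) or np.isnan(z[i + 1]):
                continue
            if np.hypot(x[i + 1] - x[i], y[i + 1] - y[i]) >= max_dist:
                continue
            if abs(z[i + 1] - z[i]) >= max_ddepth:
                continue
            n_missing = int(round(dt_s[i] / INTERVAL_S)) - 1
            fracs = np.arange(1, n_missing + 1) / (n_missing + 1)
            parts.append(
                pd.DataFrame(
                    {
                        "tag_id": tag,
                        "interval_start": t[i] + np.arange(1, n_missing + 1) * step,
                        "x": x[i] + fracs * (x[i + 1] - x[i]),
                        "y": y[i] + fracs * (y[i + 1] - y[i]),
                        "depth": z[i] + fracs * (z[i + 1] - z[i]),
                        "n_fixes": 0,
                        "n_depth_fixes": 0,
                        "interpolated": True,
                    }
                )
            )
    out = pd.concat(parts, ignore_index=True)
    return out.sort_values(["tag_id", "interval_start"]).reset_index(drop=True)[
        list(qpos.columns) + [c for c in out.columns if c not in qpos.columns]
    ]


def distance_to_bottom(
    qpos: pd.DataFrame,
    lake: LakeGrid,
    fixes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Attach ``dist_to_bottom`` = bottom depth at the position minus sensor depth.

    When the raw ``fixes`` are supplied, raw intervals use the mean of
    the per-fix distances within the interval; interpolated records (and
    intervals without usable fixes) fall back to the q-position itself.
    Positions off the raster keep the record but get NaN with a warning.
    """
    out = qpos.copy()
    d2b = pd.Series(np.nan, index=out.index)

    ok = out["x"].notna() & out["y"].notna() & out["depth"].notna()
    if ok.any():
        bottom = lake.bottom_depth(out.loc[ok, "x"].to_numpy(), out.loc[ok, "y"].to_numpy())
        d2b.loc[ok] = bottom - out.loc[ok, "depth"].to_numpy()

    if fixes is not None and not fixes.empty:
        f = fixes.loc[fixes["x"].notna() & fixes["y"].notna() & fixes["depth"].notna()].copy()
        if not f.empty:
            f["interval_start"] = pd.to_datetime(f["timestamp"]).dt.floor(f"{INTERVAL_S}s")
            f["_d2b"] = lake.bottom_depth(f["x"].to_numpy(), f["y"].to_numpy()) - f["depth"].to_numpy()
            per = f.groupby(["tag_id", "interval_start"])["_d2b"].mean()
            key = pd.MultiIndex.from_frame(out[["tag_id", "interval_start"]])
            mapped = pd.Series(per.reindex(key).to_numpy(), index=out.index)
            raw = ~out["interpolated"].astype(bool)
            d2b.loc[raw & mapped.notna()] = mapped.loc[raw & mapped.notna()]

    n_off = int((out["x"].notna() & out["y"].notna() & out["depth"].notna() & d2b.isna()).sum())
    if n_off:
        warnings.warn(f"{n_off} q-positions fall off the bathymetry raster", stacklevel=2)
    out["dist_to_bottom"] = d2b
    return out


def flag_mortality(
    qpos: pd.DataFrame,
    window_h: float = 48.0,
    xy_sd_max: float = 5.0,
    depth_sd_max: float = 0.3,
) -> pd.DataFrame:
    """Flag tags whose track becomes constant until the end of the series.

    A tag is flagged dead / tag-expelled when there is a terminal run of
    at least ``window_h`` hours over which the SDs of x, y and depth all
    stay below the thresholds (constancy followed by later movement does
    not flag).  Returns one row per tag: ``tag_id, flagged, onset``; data
    at or after ``onset`` should be excluded from trait computation.
    """
    rows = []
    for tag, g in qpos.groupby("tag_id", sort=False):
        g = g.sort_values("interval_start")
        n = len(g)
        rec = {"tag_id": tag, "flagged": False, "onset": pd.NaT}
        if n >= 2:
            rx = g["x"][::-1].expanding(min_periods=2).std()
            ry = g["y"][::-1].expanding(min_periods=2).std()
            rz = g["depth"][::-1].expanding(min_periods=2).std()
            quiet = (
                (rx.fillna(0.0) < xy_sd_max)
                & (ry.fillna(0.0) < xy_sd_max)
                & (rz.fillna(0.0) < depth_sd_max)
            ).to_numpy()  # quiet[k]: suffix of length k+1 is motionless
            run = 0
            while run < n and quiet[run]:
                run += 1
            if run >= 2:
                onset = g["interval_start"].iloc[n - run]
                duration_h = (
                    g["interval_start"].iloc[-1] - onset
                ) / pd.Timedelta(hours=1) + INTERVAL_S / 3600.0
                if duration_h >= window_h:
                    rec = {"tag_id": tag, "flagged": True, "onset": onset}
        rows.append(rec)
    return pd.DataFrame(rows)
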