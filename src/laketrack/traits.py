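"""Daily behavioural traits per individual.

For every fish and calendar day the pipeline computes:

* **dH-KUD** (ha) — area of the 95% highest-density region of a
  bivariate Gaussian kernel density (fixed bandwidth h = 50 m) over the
  day's q-positions, evaluated on the lake's 10 m raster, truncated at
  the shoreline and renormalized; only reported for days with more than
  12 daytime and 12 night-time q-positions.
* **dV-KS** (m) — total length of the 95% highest-density set of a 1-D
  Gaussian kernel density (bandwidth 0.4 m) over the day's depths.
* **mean depth** (m), **horizontal activity** (body lengths / s) and
  **vertical activity** (m/s) between consecutive q-positions, and
  **TOW**, the fraction of q-positions at least 5 m above the bottom.

Day and night are delimited one hour inside the civil twilight times.
Traits are reported on their natural scales; variance-component
transforms (log, sqrt) belong to the statistics layer.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .lake import LakeGrid
from .positioning import INTERVAL_S

__all__ = [
    "split_diel",
    "kud_area",
    "daily_hkud",
    "daily_vks",
    "daily_activity",
    "daily_tow",
    "daily_mean_depth",
    "daily_temperature",
    "day_length",
    "daily_traits",
]

OPEN_WATER_DIST = 5.0  # m above bottom separating benthic from open water


def split_diel(qpos: pd.DataFrame, twilight: pd.DataFrame) -> pd.DataFrame:
    """Label each q-position day or night and attach its calendar date.

    A record is *day* iff its interval midpoint falls within
    [civil dawn + 1 h, civil dusk - 1 h] of its date.  Every date present
    in the data must appear in the twilight table.
    """
    out = qpos.copy()
    mid = pd.to_datetime(out["interval_start"]) + pd.Timedelta(seconds=INTERVAL_S / 2)
    out["date"] = mid.dt.date.astype(str)
    tw = twilight.set_index(twilight["date"].astype(str))
    missing = sorted(set(out["date"]) - set(tw.index))
    if missing:
        raise ValueError(f"twilight table lacks dates: {', '.join(missing)}")
    dawn = pd.to_datetime(out["date"] + " " + out["date"].map(tw["dawn"]))
    dusk = pd.to_datetime(out["date"] + " " + out["date"].map(tw["dusk"]))
    day0 = dawn + pd.Timedelta(hours=1)
    day1 = dusk - pd.Timedelta(hours=1)
    out["diel"] = np.where((mid >= day0) & (mid <= day1), "day", "night")
    return out


def kud_area(
    x,
    y,
    lake: LakeGrid,
    h: float = 50.0,
    cell: float = 10.0,
    level: float = 0.95,
) -> float:
    """Area (ha) of the ``level`` highest-density region of the kernel UD.

    A bivariate Gaussian kernel of bandwidth ``h`` is evaluated at the
    centres of the lake's ``cell``-metre raster, the density outside the
    shoreline is discarded, the remaining mass renormalized to one, and
    the smallest set of highest-density cells whose cumulative mass
    reaches ``level`` is counted.  All-coincident points return the
    single-cell area rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size == 0:
        return float("nan")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        return cell * cell / 1e4

    if cell == lake.cell:
        gx_all, gy_all = lake.x_centers, lake.y_centers
    else:
        gx_all = np.arange(lake.x_centers[0] - lake.cell / 2 + cell / 2,
                           lake.x_centers[-1] + lake.cell / 2, cell)
        gy_all = np.arange(lake.y_centers[0] - lake.cell / 2 + cell / 2,
                           lake.y_centers[-1] + lake.cell / 2, cell)
    # kernels are negligible beyond 5h; restrict to the bounding window
    pad = 5.0 * h
    gx = gx_all[(gx_all >= x.min() - pad) & (gx_all <= x.max() + pad)]
    gy = gy_all[(gy_all >= y.min() - pad) & (gy_all <= y.max() + pad)]
    if gx.size == 0 or gy.size == 0:
        return float("nan")
    # separable Gaussian: density = sum_i colvec_i (x) rowvec_i
    ax = np.exp(-0.5 * ((gx[None, :] - x[:, None]) / h) ** 2)
    ay = np.exp(-0.5 * ((gy[None, :] - y[:, None]) / h) ** 2)
    dens = np.einsum("iy,ix->yx", ay, ax)
    xx, yy = np.meshgrid(gx, gy)
    wet = lake.contains(xx.ravel(), yy.ravel()).reshape(dens.shape)
    mass = np.where(wet, dens, 0.0).ravel()
    total = mass.sum()
    if total <= 0:
        return float("nan")
    mass = mass / total
    order = np.sort(mass)[::-1]
    k = int(np.searchsorted(np.cumsum(order), level) + 1)
    k = min(k, order.size)
    return k * cell * cell / 1e4


def daily_hkud(
    qpos_day: pd.DataFrame,
    lake: LakeGrid,
    h: float = 50.0,
    cell: float = 10.0,
    level: float = 0.95,
    min_day: int = 12,
    min_night: int = 12,
) -> float:
    """dH-KUD for one tag-date, or NaN when the diel coverage rule fails.

    ``qpos_day`` is one day's diel-labelled q-positions of one fish;
    the area is computed from all positioned records, but only when the
    day has more than ``min_day`` daytime and ``min_night`` night-time
    positioned q-positions.
    """
    pos = qpos_day.loc[qpos_day["x"].notna() & qpos_day["y"].notna()]
    n_day = int((pos["diel"] == "day").sum())
    n_night = int((pos["diel"] == "night").sum())
    if n_day <= min_day or n_night <= min_night:
        return float("nan")
    return kud_area(pos["x"].to_numpy(), pos["y"].to_numpy(), lake, h=h, cell=cell, level=level)


def daily_vks(
    depths,
    bw: float = 0.4,
    level: float = 0.95,
    grid_step: float = 0.05,
) -> float:
    """Length (m) of the ``level`` highest-density set of the depth KDE.

    One-dimensional Gaussian kernel density with fixed bandwidth ``bw``
    metres on a ``grid_step`` grid; needs at least two depth values.
    """
    z = np.asarray(depths, dtype=float)
    z = z[~np.isnan(z)]
    if z.size < 2:
        return float("nan")
    lo = z.min() - 5 * bw
    hi = z.max() + 5 * bw
    grid = np.arange(lo, hi + grid_step, grid_step)
    dens = np.exp(-0.5 * ((grid[None, :] - z[:, None]) / bw) ** 2).sum(axis=0)
    mass = dens / dens.sum()
    order = np.sort(mass)[::-1]
    k = int(np.searchsorted(np.cumsum(order), level) + 1)
    k = min(k, order.size)
    return k * grid_step


def daily_activity(qpos: pd.DataFrame, body_length_cm: float) -> pd.DataFrame:
    """Mean horizontal (BL/s) and vertical (m/s) speed per tag-date.

    Speeds are computed between q-positions in *adjacent* 15-min
    intervals only (interpolated records participate); each pair counts
    toward the date of its earlier member.  Days without any adjacent
    pair are absent.
    """
    if body_length_cm <= 0:
        raise ValueError("body_length_cm must be > 0")
    bl_m = body_length_cm / 100.0
    rows = []
    for tag, g in qpos.groupby("tag_id", sort=False):
        g = g.sort_values("interval_start")
        t = g["interval_start"].to_numpy()
        adj = (np.diff(t) / np.timedelta64(1, "s")) == INTERVAL_S
        x = g["x"].to_numpy(dtype=float)
        y = g["y"].to_numpy(dtype=float)
        z = g["depth"].to_numpy(dtype=float)
        dist = np.hypot(np.diff(x), np.diff(y))
        dz = np.abs(np.diff(z))
        dates = g["date"].to_numpy()[:-1]
        hv = np.where(adj, dist / INTERVAL_S / bl_m, np.nan)
        vv = np.where(adj, dz / INTERVAL_S, np.nan)
        d = pd.DataFrame({"tag_id": tag, "date": dates, "horiz": hv, "vert": vv})
        rows.append(d)
    allpairs = pd.concat(rows, ignore_index=True)
    out = (
        allpairs.groupby(["tag_id", "date"])
        .agg(horiz_activity=("horiz", "mean"), vert_activity=("vert", "mean"))
        .reset_index()
    )
    return out.dropna(subset=["horiz_activity", "vert_activity"], how="all")


def daily_tow(dist_to_bottom) -> float:
    """Fraction of q-positions at least 5 m above the bottom (open water)."""
    d = np.asarray(dist_to_bottom, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        return float("nan")
    return float((d >= OPEN_WATER_DIST).mean())


def daily_mean_depth(depths) -> float:
    z = np.asarray(depths, dtype=float)
    z = z[~np.isnan(z)]
    if z.size == 0:
        return float("nan")
    return float(z.mean())


def daily_temperature(loggers: pd.DataFrame, max_depth: float = 3.0) -> pd.Series:
    """Daily mean temperature over all loggers at 0-``max_depth`` m."""
    df = loggers.loc[loggers["depth_m"] <= max_depth].copy()
    df["date"] = pd.to_datetime(df["timestamp"]).dt.date.astype(str)
    return df.groupby("date")["temp_c"].mean().rename("temp_c")


def day_length(row) -> float:
    """Day length in hours from a twilight-table row.

    Uses sunrise/sunset when the table carries them, otherwise the civil
    dawn/dusk columns.
    """
    a = row["sunrise"] if "sunrise" in row and not pd.isna(row["sunrise"]) else row["dawn"]
    b = row["sunset"] if "sunset" in row and not pd.isna(row["sunset"]) else row["dusk"]
    return (pd.to_timedelta(b) - pd.to_timedelta(a)) / pd.Timedelta(hours=1)


def daily_traits(
    qpos: pd.DataFrame,
    lake: LakeGrid,
    twilight: pd.DataFrame,
    body_lengths: dict[str, float],
    h: float = 50.0,
    cell: float = 10.0,
    level: float = 0.95,
    vks_bw: float = 0.4,
    min_day: int = 12,
    min_night: int = 12,
    compute_kud: bool = True,
) -> pd.DataFrame:
    """Assemble the full daily-trait table, one row per tag and date.

    ``qpos`` must already carry ``dist_to_bottom``; ``body_lengths``
    maps tag_id to body length in cm.
    """
    labelled = split_diel(qpos, twilight)
    act_parts = []
    for tag, g in labelled.groupby("tag_id", sort=False):
        act_parts.append(daily_activity(g, body_lengths[tag]))
    activity = (
        pd.concat(act_parts, ignore_index=True)
        if act_parts
        else pd.DataFrame(columns=["tag_id", "date", "horiz_activity", "vert_activity"])
    )

    rows = []
    for (tag, date), g in labelled.groupby(["tag_id", "date"], sort=True):
        pos = g.loc[g["x"].notna() & g["y"].notna()]
        rec = {
            "tag_id": tag,
            "date": date,
            "n_day_q": int((pos["diel"] == "day").sum()),
            "n_night_q": int((pos["diel"] == "night").sum()),
            "dH_KUD": float("nan"),
            "dV_KS": daily_vks(g["depth"], bw=vks_bw, level=level),
            "mean_depth": daily_mean_depth(g["depth"]),
            "TOW": daily_tow(g["dist_to_bottom"]) if "dist_to_bottom" in g else float("nan"),
        }
        if compute_kud:
            rec["dH_KUD"] = daily_hkud(
                g, lake, h=h, cell=cell, level=level, min_day=min_day, min_night=min_night
            )
        rows.append(rec)
    traits = pd.DataFrame(rows)
    traits = traits.merge(activity, on=["tag_id", "date"], how="left")
    cols = [
        "tag_id", "date", "dH_KUD", "dV_KS", "mean_depth",
        "horiz_activity", "vert_activity", "TOW", "n_day_q", "n_night_q",
    ]
    return traits[cols]
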