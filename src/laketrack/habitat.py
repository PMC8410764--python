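"""Structural Complexity Index (SCI) and gillnet catch standardization.

The SCI scores a quadrat by the product of discretized macrophyte
height (100 bins of 2 cm, capped at 2 m) and discretized coverage
(100 bins of 1%), so it ranges from 0 (bare bottom) to 10,000 (full
cover of plants at least 2 m tall).  Lake and lake-by-period contrasts
are tested by permutation of labels over quadrats, either exhaustively
or by Monte Carlo.  Gillnet catches are standardized to numbers (NPUE)
and biomass (BPUE) per 1000 m^2 of net per night.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "discretize",
    "sci",
    "quadrat_sci",
    "sci_profile",
    "sci_lake_test",
    "sci_interaction_test",
    "cpue",
]

SCI_MAX = 10_000


def discretize(height_cm: float, coverage_pct: float) -> tuple[int, int]:
    """Map height (cm) and coverage (%) to their 0-100 bin indices.

    Height bins are 2 cm wide from 0 to 200 cm; anything taller
    saturates at bin 100.  Coverage bins are 1% wide.  Exact zeros map
    to bin 0, so only true absence scores zero.
    """
    if height_cm < 0:
        raise ValueError(f"height must be >= 0, got {height_cm}")
    if not 0 <= coverage_pct <= 100:
        raise ValueError(f"coverage must lie in [0, 100], got {coverage_pct}")
    h_bin = min(math.ceil(height_cm / 2.0), 100)
    c_bin = min(math.ceil(coverage_pct), 100)
    return h_bin, c_bin


def sci(height_cm: float, coverage_pct: float) -> int:
    """SCI of one quadrat: discretized height times discretized coverage."""
    h_bin, c_bin = discretize(height_cm, coverage_pct)
    return h_bin * c_bin


def quadrat_sci(quadrats: pd.DataFrame) -> pd.DataFrame:
    """Per-quadrat SCI from a (possibly multi-species) transect table.

    Species within one quadrat (lake, period, transect, depth bin) are
    aggregated before discretization: total coverage is the capped sum
    of species coverages, aggregate height the coverage-weighted mean of
    the species' mid heights.  Returns one row per quadrat with its
    ``sci``.
    """
    df = quadrats.copy()
    df["height_mid"] = (df["height_min_cm"] + df["height_max_cm"]) / 2.0
    keys = ["lake", "period", "transect_id", "depth_bin"]

    def agg(g: pd.DataFrame) -> pd.Series:
        cov = g["coverage_pct"].sum()
        if cov > 0:
            height = float(np.average(g["height_mid"], weights=g["coverage_pct"]))
        else:
            height = 0.0
        cov = min(cov, 100.0)
        return pd.Series({"coverage_pct": cov, "height_cm": height, "sci": sci(height, cov)})

    out = df.groupby(keys, sort=True).apply(agg, include_groups=False).reset_index()
    out["sci"] = out["sci"].astype(int)
    return out


def sci_profile(quadrats: pd.DataFrame) -> pd.DataFrame:
    """Mean SCI per (lake, period, depth bin) stratum."""
    q = quadrat_sci(quadrats)
    return (
        q.groupby(["lake", "period", "depth_bin"])["sci"]
        .mean()
        .rename("mean_sci")
        .reset_index()
    )


def _perm_pvalue(obs: float, null: np.ndarray) -> float:
    return float((1 + np.sum(np.abs(null) >= abs(obs) - 1e-12)) / (1 + null.size))


def sci_lake_test(
    sci_a,
    sci_b,
    n_perm: int = 9999,
    seed: int = 0,
    method: str = "auto",
) -> dict:
    """Two-sided permutation test for a difference in mean SCI.

    The statistic is mean(A) - mean(B); the null permutes lake labels
    over quadrats.  ``method`` is ``"exhaustive"`` (enumerate all label
    assignments; p is the exact tail fraction), ``"montecarlo"`` (p with
    the add-one correction), or ``"auto"`` (exhaustive when there are at
    most ``n_perm`` distinct assignments).
    """
    a = np.asarray(sci_a, dtype=float)
    b = np.asarray(sci_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    obs = a.mean() - b.mean()
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    n_comb = math.comb(n, na)
    if method == "auto":
        method = "exhaustive" if n_comb <= max(n_perm, 20000) else "montecarlo"
    if method == "exhaustive":
        total = pooled.sum()
        hits = 0
        for idx in combinations(range(n), na):
            sa = pooled[list(idx)].sum()
            delta = sa / na - (total - sa) / (n - na)
            if abs(delta) >= abs(obs) - 1e-12:
                hits += 1
        p = hits / n_comb
        return {"statistic": obs, "p": p, "n_perm": n_comb, "method": "exhaustive", "seed": seed}
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(pooled)
        null[i] = perm[:na].mean() - perm[na:].mean()
    return {
        "statistic": obs,
        "p": _perm_pvalue(obs, null),
        "n_perm": n_perm,
        "method": "montecarlo",
        "seed": seed,
    }


def sci_interaction_test(
    quadrats: pd.DataFrame,
    n_perm: int = 9999,
    seed: int = 0,
    value_col: str = "sci",
    periods: tuple[str, str] | None = None,
) -> dict:
    """Permutation test of the lake-by-period interaction in mean SCI.

    Statistic: the between-lake difference of the period change,
    (mean_p2 - mean_p1)_lakeA - (mean_p2 - mean_p1)_lakeB.  The null is
    built by permuting period labels within each lake, which preserves
    lake main effects.  Expects per-quadrat values (see
    :func:`quadrat_sci`).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    df = quadrats[["lake", "period", value_col]].copy()
    lakes = sorted(df["lake"].unique())
    if len(lakes) != 2:
        raise ValueError(f"need exactly two lakes, got {lakes}")
    if periods is None:
        per = sorted(df["period"].unique())
        if len(per) != 2:
            raise ValueError(f"need exactly two periods, got {per}")
        periods = (per[0], per[1])

    vals = {}
    masks = {}
    for lk in lakes:
        sub = df.loc[df["lake"] == lk]
        vals[lk] = sub[value_col].to_numpy(dtype=float)
        masks[lk] = (sub["period"] == periods[1]).to_numpy()
        if masks[lk].sum() == 0 or (~masks[lk]).sum() == 0:
            raise ValueError(f"lake {lk} lacks quadrats in one of the periods")

    def period_change(v: np.ndarray, m: np.ndarray) -> float:
        return v[m].mean() - v[~m].mean()

    obs = period_change(vals[lakes[0]], masks[lakes[0]]) - period_change(
        vals[lakes[1]], masks[lakes[1]]
    )
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = period_change(
            vals[lakes[0]], rng.permutation(masks[lakes[0]])
        ) - period_change(vals[lakes[1]], rng.permutation(masks[lakes[1]]))
    return {
        "statistic": obs,
        "p": _perm_pvalue(obs, null),
        "n_perm": n_perm,
        "method": "montecarlo",
        "seed": seed,
    }


def cpue(catch: pd.DataFrame) -> pd.DataFrame:
    """Standardize gillnet catches to NPUE and BPUE.

    NPUE = fish per 1000 m^2 of net per night; BPUE the same in kg.
    Requires positive ``net_area`` and ``nights`` >= 1.
    """
    df = catch.copy()
    if (df["net_area"] <= 0).any():
        raise ValueError("net_area must be > 0")
    if (df["nights"] < 1).any():
        raise ValueError("nights must be >= 1")
    effort = df["net_area"] * df["nights"] / 1000.0
    df["NPUE"] = df["n_fish"] / effort
    df["BPUE"] = df["biomass"] / effort
    return df
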