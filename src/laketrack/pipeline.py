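"""End-to-end convenience pipeline: raw positions to daily traits."""

from __future__ import annotations

import pandas as pd

from .lake import LakeGrid
from . import positioning, traits

__all__ = ["process_positions", "compute_daily_traits"]


def process_positions(
    positions: pd.DataFrame,
    lake: LakeGrid,
    max_speed: float = 2.0,
    boundary_buffer: float = 50.0,
    interpolate: bool = True,
    drop_dead: bool = True,
) -> pd.DataFrame:
    """Filter, regularize, interpolate and annotate raw position estimates.

    Returns the q-position table with ``dist_to_bottom`` attached and,
    when ``drop_dead``, data after a mortality flag removed.
    """
    fixes = positioning.filter_positions(
        positions, lake, max_speed=max_speed, boundary_buffer=boundary_buffer
    )
    qpos = positioning.regularize(fixes)
    if interpolate:
        qpos = positioning.interpolate_gaps(qpos)
    qpos = positioning.distance_to_bottom(qpos, lake, fixes=fixes)
    if drop_dead and not qpos.empty:
        verdicts = positioning.flag_mortality(qpos)
        for _, v in verdicts.loc[verdicts["flagged"]].iterrows():
            drop = (qpos["tag_id"] == v["tag_id"]) & (qpos["interval_start"] >= v["onset"])
            qpos = qpos.loc[~drop]
        qpos = qpos.reset_index(drop=True)
    return qpos


def compute_daily_traits(
    qpos: pd.DataFrame,
    lake: LakeGrid,
    twilight: pd.DataFrame,
    body_lengths: dict[str, float],
    **trait_kwargs,
) -> pd.DataFrame:
    """Daily trait table for a processed q-position series."""
    return traits.daily_traits(qpos, lake, twilight, body_lengths, **trait_kwargs)
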