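"""Tidy CSV writers for trajectories and compartment series.

All floats are written at 10 significant digits so that reruns with
identical inputs produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .params import CompartmentSeries, Trajectory

__all__ = ["write_trajectory", "write_compartments", "write_frame"]

FLOAT_FORMAT = "%.10g"


def write_frame(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_trajectory(traj: Trajectory, path: Union[str, Path]) -> None:
    """Write the cumulative function as `tau,m`."""
    write_frame(traj.to_frame(), path)


def write_compartments(
    cs: CompartmentSeries,
    path: Union[str, Path],
    traj: Optional[Trajectory] = None,
) -> None:
    """Write `tau,s,e,i,r`; passing the source trajectory switches to the
    combined `tau,m,s,e,i,r` dialect."""
    df = cs.to_frame()
    if traj is not None:
        n = len(cs.tau_grid)
        df.insert(1, "m", traj.m_values[:n])
    write_frame(df, path)
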