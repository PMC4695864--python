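"""Trajectory completion and the structural-gap post-adjustment.

Completion fills every missing node of a scored trajectory using three
rules: linear interpolation in time between the nearest observed nodes,
first observation carried backward for leading gaps, and last observation
carried forward for trailing gaps (death nodes are already observed zeros
and act as interpolation anchors). The structural-gap adjustment rescales
imputed values inside an instrument-free window so the cohort mean over the
window agrees with the mean observed in the flanking anchor years.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd


@dataclass
class ScoredTrajectory:
    """A person's 0-100 score per scheduled grid node.

    ``values`` holds NaN at missing nodes until completion; ``provenance``
    records how each node got its value: observed, death (observed-by-
    death), interpolated, carried_back, carried_forward, or gap_adjusted.
    """

    person_id: int
    sex: str
    race: str
    baseline_age: float
    grid: np.ndarray
    values: np.ndarray
    provenance: np.ndarray
    death_time: Optional[float] = None
    kind: str = "health"

    @property
    def is_complete(self) -> bool:
        return not np.any(np.isnan(self.values))

    def alive_mask(self) -> np.ndarray:
        """Nodes strictly before death (all nodes if no death)."""
        if self.death_time is None:
            return np.ones(self.grid.size, dtype=bool)
        return self.grid < self.death_time - 1e-9

    def validate(self) -> None:
        v = self.values
        obs = ~np.isnan(v)
        if np.any(v[obs] < 0) or np.any(v[obs] > 100):
            raise ValueError(f"person {self.person_id}: score outside [0, 100]")
        if self.death_time is not None:
            dead = self.grid >= self.death_time - 1e-9
            if not np.all(v[dead] == 0.0):
                raise ValueError(f"person {self.person_id}: nonzero score after death")


class EmptyTrajectoryError(ValueError):
    """No observed node at all; the person must be excluded upstream."""


def complete_trajectory(traj: ScoredTrajectory) -> ScoredTrajectory:
    """Fill every missing node; idempotent on complete trajectories.

    Interior gaps are interpolated linearly in time between the nearest
    observed neighbours; leading gaps take the first observed value,
    trailing gaps the last. Nodes at or after death are forced to zero.
    """
    obs = ~np.isnan(traj.values)
    if not obs.any():
        raise EmptyTrajectoryError(
            f"person {traj.person_id}: no observed node to impute from"
        )
    if obs.all():
        return dataclasses.replace(traj)

    values = np.interp(traj.grid, traj.grid[obs], traj.values[obs])
    provenance = traj.provenance.copy()
    first, last = np.flatnonzero(obs)[[0, -1]]
    for i in np.flatnonzero(~obs):
        provenance[i] = (
            "carried_back" if i < first else "carried_forward" if i > last else "interpolated"
        )
    if traj.death_time is not None:
        dead = traj.grid >= traj.death_time - 1e-9
        values[dead] = 0.0
    out = dataclasses.replace(traj, values=values, provenance=provenance)
    out.validate()
    return out


_IMPUTED = ("interpolated", "carried_back", "carried_forward")


def adjust_structural_gap(
    cohort: Sequence[ScoredTrajectory],
    window: tuple,
    anchors: tuple,
    mode: str = "multiplicative",
) -> list:
    """Reweight imputed values inside an instrument-free window.

    A single cohort-level factor (multiplicative mode, the default) or
    offset (additive mode) maps the mean imputed value over the window onto
    the mean observed at the two anchor years, among person-nodes where the
    person is alive; adjusted values are clipped to [0, 100]. Persons dead
    through the window contribute zeros that are left untouched.

    Returns new trajectories; nodes that were rescaled are re-labelled
    ``gap_adjusted``. An empty window is a no-op.
    """
    if mode not in ("multiplicative", "additive"):
        raise ValueError("mode must be 'multiplicative' or 'additive'")
    lo, hi = window
    if hi < lo:
        raise ValueError("window end before start")

    anchor_vals = []
    window_vals = []
    for traj in cohort:
        if not traj.is_complete:
            raise ValueError("adjust_structural_gap requires completed trajectories")
        alive = traj.alive_mask()
        for a in anchors:
            i = int(np.argmin(np.abs(traj.grid - a)))
            if abs(traj.grid[i] - a) > 1e-9:
                raise ValueError(f"anchor year {a} is not a grid node")
            if alive[i]:
                anchor_vals.append(traj.values[i])
        in_win = (traj.grid >= lo - 1e-9) & (traj.grid <= hi + 1e-9)
        window_vals.extend(traj.values[in_win & alive])

    if not window_vals:
        return [dataclasses.replace(t) for t in cohort]
    if not anchor_vals:
        raise ValueError("no alive person at either anchor year")
    anchor_mean = float(np.mean(anchor_vals))
    window_mean = float(np.mean(window_vals))

    if mode == "multiplicative":
        if window_mean == 0.0 and anchor_mean != 0.0:
            raise ValueError("window mean is zero; cannot rescale multiplicatively")
        lam = 1.0 if anchor_mean == window_mean else anchor_mean / window_mean
    else:
        delta = anchor_mean - window_mean

    out = []
    for traj in cohort:
        values = traj.values.copy()
        provenance = traj.provenance.copy()
        in_win = (traj.grid >= lo - 1e-9) & (traj.grid <= hi + 1e-9)
        target = in_win & traj.alive_mask() & np.isin(provenance, _IMPUTED)
        if target.any():
            if mode == "multiplicative":
                values[target] = np.clip(values[target] * lam, 0.0, 100.0)
            else:
                values[target] = np.clip(values[target] + delta, 0.0, 100.0)
            provenance[target] = "gap_adjusted"
        out.append(dataclasses.replace(traj, values=values, provenance=provenance))
    return out


def trajectories_to_frame(cohort: Iterable[ScoredTrajectory]) -> pd.DataFrame:
    """Long CSV-ready form with the provenance audit column."""
    rows = []
    for t in cohort:
        for i, time in enumerate(t.grid):
            rows.append(
                {
                    "person_id": t.person_id,
                    "kind": t.kind,
                    "time": float(time),
                    "score": t.values[i],
                    "provenance": t.provenance[i],
                }
            )
    return pd.DataFrame(rows, columns=["person_id", "kind", "time", "score", "provenance"])
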