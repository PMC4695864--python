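"""Person-level years of life, healthy life, and able life.

Years of life (YOL) is the time from enrollment to death, censored at the
follow-up window. Years of healthy life (YHL) and years of able life (YAL)
are trapezoidal areas under the completed 0-100 score trajectories divided
by 100. When death falls between grid nodes a node is inserted at the death
time with value 0, so the score falls linearly to zero within the year of
death and stays zero after.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import PersonPanel
from .config import age_band_label
from .imputation import ScoredTrajectory


@dataclass
class PersonYears:
    person_id: int
    sex: str
    race: str
    age_band: str
    baseline_age: float
    yol: float
    yhl: float
    yal: float

    def validate(self, follow_up_years: float = 18.0) -> None:
        eps = 1e-9
        if not (0 - eps <= self.yhl <= self.yol + eps <= follow_up_years + eps):
            raise ValueError(f"person {self.person_id}: YHL/YOL invariant violated")
        if not (0 - eps <= self.yal <= self.yol + eps):
            raise ValueError(f"person {self.person_id}: YAL/YOL invariant violated")


def years_of_life(panel_or_death_time, follow_up_years: float = 18.0) -> float:
    """min(death_time, follow-up), or the full follow-up if still alive."""
    dt: Optional[float]
    if isinstance(panel_or_death_time, PersonPanel):
        dt = panel_or_death_time.death_time
    else:
        dt = panel_or_death_time
    if dt is None:
        return float(follow_up_years)
    if dt < 0:
        raise ValueError("negative death time")
    return float(min(dt, follow_up_years))


def integrate_years(traj: ScoredTrajectory) -> float:
    """Trapezoidal area under the completed score curve, in years.

    Exact for the piecewise-linear completed trajectories this pipeline
    produces (the trapezoid rule has zero error on linear pieces).
    """
    if not traj.is_complete:
        raise ValueError(f"person {traj.person_id}: trajectory not complete")
    times = traj.grid.astype(float)
    values = traj.values.astype(float)
    dt = traj.death_time
    if dt is not None and dt < times[-1] and dt not in times:
        # score falls linearly to 0 at the death time, 0 afterwards
        i = int(np.searchsorted(times, dt))
        times = np.insert(times, i, dt)
        values = np.insert(values, i, 0.0)
    return float(np.trapezoid(values, times)) / 100.0


def accumulate_cohort(
    panels: Sequence[PersonPanel],
    health_trajs: Iterable[ScoredTrajectory],
    ability_trajs: Iterable[ScoredTrajectory],
    follow_up_years: float = 18.0,
) -> list:
    """Combine both completed score sets into one PersonYears per person."""
    health = {t.person_id: t for t in health_trajs}
    ability = {t.person_id: t for t in ability_trajs}
    if set(health) != set(ability):
        odd = set(health) ^ set(ability)
        raise ValueError(f"persons present in only one scored set: {sorted(odd)[:5]}")
    out = []
    for p in panels:
        ht = health[p.person_id]
        at = ability[p.person_id]
        py = PersonYears(
            person_id=p.person_id,
            sex=p.sex,
            race=p.race,
            age_band=age_band_label(p.baseline_age),
            baseline_age=p.baseline_age,
            yol=years_of_life(p, follow_up_years),
            yhl=integrate_years(ht),
            yal=integrate_years(at),
        )
        py.validate(follow_up_years)
        out.append(py)
    return out


def person_years_frame(person_years: Iterable[PersonYears]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "person_id": p.person_id,
                "sex": p.sex,
                "race": p.race,
                "age_band": p.age_band,
                "baseline_age": p.baseline_age,
                "yol": p.yol,
                "yhl": p.yhl,
                "yal": p.yal,
            }
            for p in person_years
        ]
    )
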