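"""Recalibration of ordinal states to a 0-100 interval scale.

Each state's score is 100 times the empirical probability of being healthy
(for self-rated health) or able (for ADL difficulty counts) at the next
scheduled wave, pooled over all persons and waves. Death counts as a
next-wave outcome with healthy/able = 0, and the DEAD state itself scores
0 exactly. The resulting interval scale is what makes linear interpolation
and trapezoidal integration of ordinal panel data meaningful.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .cohort import MISSING, PersonPanel
from .config import HEALTHY_LEVELS, N_ADL, SRH_LEVELS
from .imputation import ScoredTrajectory

_HEALTHY_CODES = frozenset(i for i, s in enumerate(SRH_LEVELS) if s in HEALTHY_LEVELS)

HEALTH_STATES = tuple(SRH_LEVELS) + ("DEAD",)
ABILITY_STATES = tuple(str(k) for k in range(N_ADL + 1)) + ("DEAD",)


class UnscoredStateError(KeyError):
    """A panel contains a state the fitted scale map could not score."""


def classify_healthy(srh) -> int:
    """1 if the SRH response counts as healthy (E/VG/G), 0 if F/P."""
    if srh is None or (isinstance(srh, (int, np.integer)) and srh == MISSING):
        raise ValueError("cannot classify a missing SRH response")
    label = SRH_LEVELS[srh] if isinstance(srh, (int, np.integer)) else srh
    if label not in SRH_LEVELS:
        raise ValueError(f"unknown SRH state {srh!r}")
    return int(label in HEALTHY_LEVELS)


def classify_able(adl_items) -> int:
    """1 if no difficulty is reported on any of the six ADL items."""
    items = np.asarray(adl_items)
    if items.shape != (N_ADL,):
        raise ValueError(f"expected {N_ADL} ADL items")
    if np.any(items == MISSING):
        raise ValueError("cannot classify ability with a missing ADL item")
    return int(np.all(items == 0))


@dataclass
class HealthScaleMap:
    """Fitted state -> score map with the transition support behind it."""

    kind: str  # "health" or "ability"
    state_scores: dict = field(default_factory=dict)
    support_counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.state_scores["DEAD"] = 0.0
        for s, v in self.state_scores.items():
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"score for state {s} outside [0, 100]")

    def score(self, state: str) -> float:
        try:
            return self.state_scores[state]
        except KeyError:
            raise UnscoredStateError(
                f"state {state!r} has no fitted score (zero observed transitions?)"
            ) from None

    @property
    def unscored_states(self) -> list:
        all_states = HEALTH_STATES if self.kind == "health" else ABILITY_STATES
        return [s for s in all_states if s not in self.state_scores]

    def monotonicity_violations(self) -> list:
        """Adjacent state pairs where a worse state scores higher.

        Reported as a data-quality diagnostic, never enforced: with
        stochastically ordered dynamics the fitted scores should decrease
        from best to worst state.
        """
        order = [s for s in (HEALTH_STATES if self.kind == "health" else ABILITY_STATES)
                 if s in self.state_scores]
        return [
            (a, b)
            for a, b in zip(order, order[1:])
            if self.state_scores[a] < self.state_scores[b]
        ]

    def to_frame(self) -> pd.DataFrame:
        states = [s for s in (HEALTH_STATES if self.kind == "health" else ABILITY_STATES)]
        return pd.DataFrame(
            {
                "state": states,
                "score": [self.state_scores.get(s, np.nan) for s in states],
                "support": [self.support_counts.get(s, 0) for s in states],
            }
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "kind": self.kind,
                    "state_scores": self.state_scores,
                    "support_counts": self.support_counts,
                },
                fh,
                indent=2,
            )


def _nearest_scored(scale_map: HealthScaleMap, label: str) -> str:
    """Nearest scored living state in ordinal order; worse side wins ties."""
    order = list(
        (HEALTH_STATES if scale_map.kind == "health" else ABILITY_STATES)[:-1]
    )
    i = order.index(label)
    for d in range(1, len(order)):
        for j in (i + d, i - d):  # worse side first (higher index = worse)
            if 0 <= j < len(order) and order[j] in scale_map.state_scores:
                return order[j]
    raise UnscoredStateError(f"no scored state near {label!r}")


def _panel_states(panel: PersonPanel, kind: str) -> np.ndarray:
    """Per-wave state index (SRH code, or ADL difficulty count), -1 missing."""
    if kind == "health":
        return panel.srh.astype(int)
    counts = np.full(panel.times.size, MISSING, dtype=int)
    ok = np.all(panel.adl != MISSING, axis=1)
    counts[ok] = panel.adl[ok].sum(axis=1)
    return counts


def _good_outcome(panel: PersonPanel, k: int, kind: str) -> int:
    if kind == "health":
        return 1 if int(panel.srh[k]) in _HEALTHY_CODES else 0
    return classify_able(panel.adl[k])


def fit_scale_map(cohort: Iterable[PersonPanel], kind: str, grid_step: float = 1.0) -> HealthScaleMap:
    """Estimate score(s) = 100 * P(healthy or able at the next wave | s).

    Eligible pairs are consecutive scheduled waves where the state at t is
    observed and the outcome at t + grid_step is known — either the next
    wave is observed, or the person died before it (outcome 0). Pairs with
    a missing next wave are excluded (complete-pair estimator); every
    eligible pair is used exactly once.
    """
    if kind not in ("health", "ability"):
        raise ValueError("kind must be 'health' or 'ability'")
    labels = SRH_LEVELS if kind == "health" else tuple(str(k) for k in range(N_ADL + 1))
    n_states = len(labels)
    good = np.zeros(n_states)
    total = np.zeros(n_states)
    for panel in cohort:
        states = _panel_states(panel, kind)
        n_waves = states.size
        for k in range(n_waves):
            s = states[k]
            if s == MISSING:
                continue
            if k + 1 < n_waves:
                if states[k + 1] == MISSING:
                    continue  # outcome unknown: complete-pair estimator
                total[s] += 1
                good[s] += _good_outcome(panel, k + 1, kind)
            elif panel.death_time is not None:
                # died before the next scheduled wave: outcome not good
                total[s] += 1
    scores = {}
    support = {}
    for i, lab in enumerate(labels):
        support[lab] = int(total[i])
        if total[i] > 0:
            scores[lab] = 100.0 * good[i] / total[i]
    return HealthScaleMap(kind=kind, state_scores=scores, support_counts=support)


def apply_scale_map(
    panel: PersonPanel,
    scale_map: HealthScaleMap,
    grid: np.ndarray,
    on_unscored: str = "error",
) -> ScoredTrajectory:
    """Score a panel on the full scheduled grid.

    Observed waves carry their state's score; missing waves stay missing
    (NaN) for the imputation stage; every grid node at or after the death
    time carries exactly 0 and is marked as observed-by-death.

    ``on_unscored`` controls what happens when an observed state has no
    fitted score (zero complete transition pairs, typical for rare high
    ADL-difficulty counts): ``"error"`` raises; ``"nearest"`` borrows the
    score of the nearest scored state in the ordinal order, preferring the
    worse side so rare severe states are never scored optimistically.
    """
    if on_unscored not in ("error", "nearest"):
        raise ValueError("on_unscored must be 'error' or 'nearest'")
    grid = np.asarray(grid, dtype=float)
    values = np.full(grid.size, np.nan)
    provenance = np.full(grid.size, "missing", dtype=object)
    states = _panel_states(panel, scale_map.kind)
    node_of = {round(float(t), 10): i for i, t in enumerate(grid)}
    for k, t in enumerate(panel.times):
        i = node_of.get(round(float(t), 10))
        if i is None:
            raise ValueError(f"wave time {t} not on the scheduled grid")
        if states[k] != MISSING:
            label = (
                SRH_LEVELS[states[k]] if scale_map.kind == "health" else str(states[k])
            )
            try:
                values[i] = scale_map.score(label)
            except UnscoredStateError:
                if on_unscored == "error":
                    raise
                values[i] = scale_map.score(_nearest_scored(scale_map, label))
            provenance[i] = "observed"
    if panel.death_time is not None:
        dead = grid >= panel.death_time - 1e-9
        values[dead] = 0.0
        provenance[dead] = "death"
    return ScoredTrajectory(
        person_id=panel.person_id,
        sex=panel.sex,
        race=panel.race,
        baseline_age=panel.baseline_age,
        grid=grid,
        values=values,
        provenance=provenance,
        death_time=panel.death_time,
        kind=scale_map.kind,
    )
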