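"""Synthetic person-wave panels and panel CSV input/output.

A :class:`PersonPanel` holds one person's scheduled interview waves: the
ordinal self-rated health (SRH) response, six ADL-difficulty indicators, and
the death time if the person died during follow-up. Missing responses are
coded ``-1`` internally and written as empty CSV fields.

The generator evolves SRH by a per-group Markov transition matrix with an
additive per-year-of-age drift toward worse categories, flips independent
ADL items with age-increasing acquisition probabilities, and draws death
from a per-group Gompertz hazard; death is absorbing and the death time is
uniform within the year of the death event so partial-year survival is
exercised downstream.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .config import (
    GROUPS,
    N_ADL,
    SRH_LEVELS,
    ConfigurationError,
    SimulationConfig,
    age_band_label,
)

MISSING = -1  # internal code for an unobserved response

_SRH_CODE = {lab: i for i, lab in enumerate(SRH_LEVELS)}


@dataclass
class PersonPanel:
    """One person's observed waves plus vital status.

    ``times`` are years since enrollment on the scheduled grid; waves stop
    at the last scheduled time before death. ``srh`` holds codes 0..4 for
    E..P (−1 when the wave is missing); ``adl`` is an (n_waves, 6) array of
    0/1 difficulty indicators (−1 when missing).
    """

    person_id: int
    sex: str
    race: str
    baseline_age: float
    times: np.ndarray
    srh: np.ndarray
    adl: np.ndarray
    death_time: Optional[float] = None

    @property
    def group(self) -> tuple:
        return (self.sex, self.race)

    @property
    def age_band(self) -> str:
        return age_band_label(self.baseline_age)

    def srh_label(self, k: int) -> Optional[str]:
        code = int(self.srh[k])
        return None if code == MISSING else SRH_LEVELS[code]

    def validate(self, follow_up_years: float = 18.0) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.size == 0 or t[0] != 0.0:
            raise ValueError(f"person {self.person_id}: baseline wave (time 0) required")
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"person {self.person_id}: wave times not strictly increasing")
        if t[-1] > follow_up_years + 1e-9 or t[0] < 0:
            raise ValueError(f"person {self.person_id}: wave outside [0, {follow_up_years}]")
        if self.death_time is not None:
            if self.death_time < 0:
                raise ValueError(f"person {self.person_id}: negative death_time")
            if np.any(t > self.death_time + 1e-9):
                raise ValueError(f"person {self.person_id}: wave after death_time")
        if self.srh.shape != t.shape or self.adl.shape != (t.size, N_ADL):
            raise ValueError(f"person {self.person_id}: wave array shapes inconsistent")


# ----------------------------------------------------------------------
# Generation

def _draw_categorical(rng: np.random.Generator, probs: np.ndarray, n: int) -> np.ndarray:
    """Vectorized categorical draw: n samples from one probability row."""
    edges = np.cumsum(probs)
    return np.searchsorted(edges, rng.random(n) * edges[-1], side="right").astype(np.int8)


def _drifted_rows(matrix: np.ndarray, drift: float) -> np.ndarray:
    """Transition rows with mass ``drift`` shifted one category worse."""
    d = min(max(drift, 0.0), 0.9)
    out = matrix * (1.0 - d)
    out[:, 1:] += matrix[:, :-1] * d
    out[:, -1] += matrix[:, -1] * d
    return out


def generate_cohort(config: SimulationConfig) -> list:
    """Simulate ``config.n_persons`` complete (fully observed) panels.

    Identical config and seed produce identical output. Missingness is
    injected separately by :func:`inject_missingness`, so the return value
    doubles as the ground-truth cohort for masking experiments.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_persons
    grid = config.grid
    n_nodes = grid.size
    dt = config.grid_step

    group_keys = list(config.group_fractions)
    group_probs = np.array([config.group_fractions[g] for g in group_keys])
    group_idx = _draw_categorical(rng, group_probs, n)

    band_keys = list(config.baseline_age_distribution)
    band_probs = np.array([config.baseline_age_distribution[b] for b in band_keys])
    band_idx = _draw_categorical(rng, band_probs, n)
    ages = np.empty(n)
    for bi, band in enumerate(band_keys):
        lo, hi = (int(x) for x in band.split("-"))
        sel = band_idx == bi
        # integer ages uniform in the band; open-ended band capped at 89
        ages[sel] = rng.integers(lo, min(hi, 89) + 1, size=int(sel.sum()))

    srh = np.full((n, n_nodes), MISSING, dtype=np.int8)
    adl = np.full((n, n_nodes, N_ADL), MISSING, dtype=np.int8)
    death = np.full(n, np.nan)

    # baseline wave
    for gi, g in enumerate(group_keys):
        sel = group_idx == gi
        m = int(sel.sum())
        if m == 0:
            continue
        srh[sel, 0] = _draw_categorical(rng, np.asarray(config.srh_baseline[g]), m)
        p0 = config.adl_incidence[g]["p0"]
        adl[sel, 0, :] = (rng.random((m, N_ADL)) < p0).astype(np.int8)

    alive = np.ones(n, dtype=bool)
    for k in range(n_nodes - 1):
        t = grid[k]
        cur_age = ages + t
        # death in (t, t + dt]
        u_die = rng.random(n)
        u_when = rng.random(n)
        for gi, g in enumerate(group_keys):
            spec = config.mortality[g]
            sel = alive & (group_idx == gi)
            if not sel.any():
                continue
            h = spec["rate"] * np.exp(spec["age_slope"] * (cur_age[sel] - 65.0))
            p_die = 1.0 - np.exp(-h * dt)
            dies = u_die[sel] < p_die
            idx = np.where(sel)[0][dies]
            death[idx] = t + u_when[idx] * dt
            alive[idx] = False

        # SRH transition and ADL update for survivors, bucketed by
        # (group, integer age) so each bucket shares one transition row set
        u_srh = rng.random(n)
        u_adl = rng.random((n, N_ADL))
        for gi, g in enumerate(group_keys):
            sel = alive & (group_idx == gi)
            if not sel.any():
                continue
            base = np.asarray(config.srh_transition[g], dtype=float)
            inc = config.adl_incidence[g]
            for a in np.unique(cur_age[sel]):
                bsel = sel & (cur_age == a)
                rows = _drifted_rows(base, config.srh_age_drift * (a - 65.0))
                edges = np.cumsum(rows, axis=1)
                prev = srh[bsel, k].astype(int)
                e = edges[prev]
                srh[bsel, k + 1] = (
                    np.sum(u_srh[bsel][:, None] * e[:, -1:] >= e[:, :-1], axis=1)
                ).astype(np.int8)
                p_acq = min(inc["acquire"] * np.exp(config.adl_age_slope * (a - 65.0)), 0.95)
                prev_adl = adl[bsel, k, :]
                new_adl = np.where(
                    prev_adl == 1,
                    (u_adl[bsel] >= inc["recover"]).astype(np.int8),
                    (u_adl[bsel] < p_acq).astype(np.int8),
                )
                adl[np.where(bsel)[0][:, None], k + 1, np.arange(N_ADL)] = new_adl

    panels = []
    for i in range(n):
        dt_i = None if np.isnan(death[i]) else float(death[i])
        n_waves = n_nodes if dt_i is None else int(np.searchsorted(grid, dt_i, side="right"))
        panels.append(
            PersonPanel(
                person_id=i,
                sex=group_keys[group_idx[i]][0],
                race=group_keys[group_idx[i]][1],
                baseline_age=float(ages[i]),
                times=grid[:n_waves].copy(),
                srh=srh[i, :n_waves].copy(),
                adl=adl[i, :n_waves, :].copy(),
                death_time=dt_i,
            )
        )
    return panels


# ----------------------------------------------------------------------
# Missingness

def inject_missingness(cohort: Iterable[PersonPanel], config: SimulationConfig) -> list:
    """Return a masked copy of the cohort.

    Each non-baseline scheduled wave is unobserved independently with
    probability ``config.missing_rate`` (the whole interview is skipped, so
    SRH and ADL go missing together). Inside ``config.structural_gap`` the
    ADL instrument is absent for everyone. Vital status is never masked.
    The input panels are left untouched.
    """
    if config.structural_gap is not None:
        lo, hi = config.structural_gap
        if not 0.0 <= lo <= hi <= config.follow_up_years:
            raise ConfigurationError("structural_gap outside the follow-up window")
    rng = np.random.default_rng([config.seed, 1])
    out = []
    for p in cohort:
        srh = p.srh.copy()
        adl = p.adl.copy()
        if config.missing_rate > 0:
            mask = rng.random(p.times.size) < config.missing_rate
            mask[0] = False  # baseline is always observed
            srh[mask] = MISSING
            adl[mask, :] = MISSING
        if config.structural_gap is not None:
            lo, hi = config.structural_gap
            in_gap = (p.times >= lo - 1e-9) & (p.times <= hi + 1e-9)
            adl[in_gap, :] = MISSING
        out.append(dataclasses.replace(p, srh=srh, adl=adl))
    return out


def intervening_missing_fraction(cohort: Iterable[PersonPanel]) -> float:
    """Fraction of observed SRH responses that flank an intervening missing
    value, found by brute-force scan of every panel.

    An observed wave "flanks" a missing value when it is the nearest
    observed neighbour, on either side, of at least one missing wave —
    i.e. linear interpolation of that missing wave would use it.
    """
    involved = 0
    total = 0
    for p in cohort:
        obs = p.srh != MISSING
        total += int(obs.sum())
        missing_idx = np.where(~obs)[0]
        flankers = set()
        for mi in missing_idx:
            for j in range(mi - 1, -1, -1):
                if obs[j]:
                    flankers.add(j)
                    break
            for j in range(mi + 1, obs.size):
                if obs[j]:
                    flankers.add(j)
                    break
        involved += len(flankers)
    return involved / total if total else 0.0


# ----------------------------------------------------------------------
# CSV round-trip

_COLUMNS = (
    ["person_id", "sex", "race", "baseline_age", "time", "srh"]
    + [f"adl_{j}" for j in range(1, N_ADL + 1)]
    + ["death_time"]
)


def cohort_to_frame(cohort: Iterable[PersonPanel]) -> pd.DataFrame:
    """Long (tidy) one-row-per-person-wave representation."""
    rows = []
    for p in cohort:
        for k, t in enumerate(p.times):
            row = {
                "person_id": p.person_id,
                "sex": p.sex,
                "race": p.race,
                "baseline_age": p.baseline_age,
                "time": float(t),
                "srh": p.srh_label(k),
                "death_time": p.death_time,
            }
            for j in range(N_ADL):
                v = int(p.adl[k, j])
                row[f"adl_{j + 1}"] = None if v == MISSING else v
            rows.append(row)
    return pd.DataFrame(rows, columns=_COLUMNS)


def write_panel(cohort: Iterable[PersonPanel], path, config: Optional[SimulationConfig] = None) -> None:
    """Write the cohort as long CSV; optionally echo the config as JSON."""
    cohort_to_frame(cohort).to_csv(path, index=False)
    if config is not None:
        sidecar = str(path).rsplit(".", 1)[0] + ".config.json"
        config.to_json(sidecar)


def frame_to_cohort(df: pd.DataFrame, follow_up_years: float = 18.0) -> list:
    panels = []
    errors = []
    for pid, g in df.groupby("person_id", sort=True):
        g = g.sort_values("time")
        srh = np.full(len(g), MISSING, dtype=np.int8)
        for i, v in enumerate(g["srh"]):
            if isinstance(v, str) and v:
                if v not in _SRH_CODE:
                    errors.append(f"person {pid}: unknown SRH label {v!r}")
                    break
                srh[i] = _SRH_CODE[v]
        adl = np.full((len(g), N_ADL), MISSING, dtype=np.int8)
        for j in range(N_ADL):
            col = pd.to_numeric(g[f"adl_{j + 1}"], errors="coerce")
            ok = col.notna().to_numpy()
            adl[ok, j] = col.to_numpy()[ok].astype(np.int8)
        dtimes = pd.to_numeric(g["death_time"], errors="coerce").dropna().unique()
        panel = PersonPanel(
            person_id=pid,
            sex=str(g["sex"].iloc[0]),
            race=str(g["race"].iloc[0]),
            baseline_age=float(g["baseline_age"].iloc[0]),
            times=g["time"].to_numpy(dtype=float),
            srh=srh,
            adl=adl,
            death_time=float(dtimes[0]) if dtimes.size else None,
        )
        try:
            panel.validate(follow_up_years)
        except ValueError as exc:
            errors.append(str(exc))
            continue
        panels.append(panel)
    if errors:
        raise ValueError("panel validation failed:\n" + "\n".join(errors))
    return panels


def read_panel(path, follow_up_years: float = 18.0) -> list:
    """Read a long-format panel CSV back into validated panels."""
    df = pd.read_csv(
        path,
        dtype={"srh": "string"},
        keep_default_na=True,
    )
    missing_cols = [c for c in _COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"panel CSV missing columns: {missing_cols}")
    df["srh"] = df["srh"].fillna("")
    return frame_to_cohort(df, follow_up_years)
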