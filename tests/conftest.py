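import dataclasses

import numpy as np
import pytest

import ablelife as al


@pytest.fixture(scope="session")
def small_sim():
    return al.SimulationConfig(n_persons=300, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_sim):
    """Complete (unmasked) 300-person cohort."""
    return al.generate_cohort(small_sim)


@pytest.fixture(scope="session")
def small_masked(small_sim, small_cohort):
    return al.inject_missingness(small_cohort, small_sim)


@pytest.fixture(scope="session")
def mid_sim():
    return al.SimulationConfig(n_persons=2000, seed=42)


@pytest.fixture(scope="session")
def mid_cohort(mid_sim):
    return al.generate_cohort(mid_sim)


@pytest.fixture(scope="session")
def mid_masked(mid_sim, mid_cohort):
    return al.inject_missingness(mid_cohort, mid_sim)


def make_panel(
    person_id=0,
    sex="F",
    race="white",
    baseline_age=70.0,
    srh_labels=("E", "E", "E"),
    adl_rows=None,
    death_time=None,
    grid_step=1.0,
):
    """Hand-build a panel from SRH labels; None marks a missing wave."""
    n = len(srh_labels)
    srh = np.array(
        [al.SRH_LEVELS.index(s) if s is not None else al.MISSING for s in srh_labels],
        dtype=np.int8,
    )
    if adl_rows is None:
        adl = np.zeros((n, al.N_ADL), dtype=np.int8)
        adl[srh == al.MISSING] = al.MISSING
    else:
        adl = np.array(adl_rows, dtype=np.int8)
    return al.PersonPanel(
        person_id=person_id,
        sex=sex,
        race=race,
        baseline_age=baseline_age,
        times=np.arange(n, dtype=float) * grid_step,
        srh=srh,
        adl=adl,
        death_time=death_time,
    )


def make_trajectory(values, death_time=None, person_id=0, kind="health"):
    """ScoredTrajectory on an integer grid; np.nan marks missing nodes."""
    values = np.asarray(values, dtype=float)
    provenance = np.where(np.isnan(values), "missing", "observed").astype(object)
    if death_time is not None:
        dead = np.arange(values.size, dtype=float) >= death_time - 1e-9
        provenance[dead] = "death"
    return al.ScoredTrajectory(
        person_id=person_id,
        sex="F",
        race="white",
        baseline_age=70.0,
        grid=np.arange(values.size, dtype=float),
        values=values,
        provenance=provenance,
        death_time=death_time,
        kind=kind,
    )


def neighbor_scan_completion(values, death_time=None):
    """Independent brute-force reference for trajectory completion.

    For each missing node scan outward for the nearest observed node on
    each side, then apply: linear interpolation when both exist, carry
    backward/forward when only one does. Death nodes are forced to zero.
    """
    v = np.asarray(values, dtype=float).copy()
    grid = np.arange(v.size, dtype=float)
    obs = np.where(~np.isnan(v))[0]
    out = v.copy()
    for i in range(v.size):
        if not np.isnan(v[i]):
            continue
        before = [j for j in obs if j < i]
        after = [j for j in obs if j > i]
        if before and after:
            j0, j1 = before[-1], after[0]
            t = (grid[i] - grid[j0]) / (grid[j1] - grid[j0])
            out[i] = v[j0] + t * (v[j1] - v[j0])
        elif after:
            out[i] = v[after[0]]
        else:
            out[i] = v[before[-1]]
    if death_time is not None:
        out[grid >= death_time - 1e-9] = 0.0
    return out


def random_masked_trajectory(rng, max_len=25):
    """Random 0-100 trajectory with random missingness and optional death."""
    n = int(rng.integers(3, max_len))
    values = rng.uniform(0.0, 100.0, n)
    death_time = None
    if rng.random() < 0.4:
        death_time = float(rng.uniform(1.0, n - 1))
        values[np.arange(n) >= death_time] = 0.0
    miss = rng.random(n) < rng.uniform(0.1, 0.6)
    if death_time is not None:
        miss &= np.arange(n) < death_time  # death nodes are never missing
    if miss.all():
        miss[int(rng.integers(0, n))] = False  # keep at least one observation
    masked = np.where(miss, np.nan, values)
    return masked, death_time
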