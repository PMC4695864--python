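"""Recalibration of ordinal states to next-wave probability scores."""

import numpy as np
import pytest

import ablelife as al
from ablelife.recalibration import UnscoredStateError, _nearest_scored

from conftest import make_panel


@pytest.mark.parametrize(
    "srh, expected",
    [("E", 1), ("VG", 1), ("G", 1), ("F", 0), ("P", 0)],
)
def test_classify_healthy(srh, expected):
    assert al.classify_healthy(srh) == expected


def test_classify_healthy_rejects_missing():
    with pytest.raises(ValueError):
        al.classify_healthy(None)
    with pytest.raises(ValueError):
        al.classify_healthy(al.MISSING)


@pytest.mark.parametrize(
    "items, expected",
    [
        ((0, 0, 0, 0, 0, 0), 1),
        ((0, 0, 1, 0, 0, 0), 0),
        ((1, 1, 1, 1, 1, 1), 0),
    ],
)
def test_classify_able(items, expected):
    assert al.classify_able(items) == expected


def test_classify_able_rejects_missing_item():
    with pytest.raises(ValueError):
        al.classify_able((0, 0, al.MISSING, 0, 0, 0))


def test_toy_panel_score_from_pair_counts():
    """Four F-state pairs with next waves (G, P, P, death) score F at 25."""
    panels = [
        make_panel(person_id=1, srh_labels=("F", "G")),
        make_panel(person_id=2, srh_labels=("F", "P")),
        make_panel(person_id=3, srh_labels=("F", "P")),
        make_panel(person_id=4, srh_labels=("F",), death_time=0.6),
    ]
    smap = al.fit_scale_map(panels, "health")
    assert smap.score("F") == pytest.approx(25.0)
    assert smap.support_counts["F"] == 4
    assert smap.score("DEAD") == 0.0


def test_degenerate_certainty_scores_100():
    """If every next wave is healthy and nobody dies, living states score 100."""
    panels = [
        make_panel(person_id=1, srh_labels=("F", "G", "E", "G")),
        make_panel(person_id=2, srh_labels=("P", "E", "VG", "G")),
    ]
    smap = al.fit_scale_map(panels, "health")
    for s in ("E", "VG", "G", "F", "P"):
        if smap.support_counts[s] > 0:
            assert smap.score(s) == 100.0


def test_pair_conservation_brute_force(small_masked):
    """fit_scale_map uses every eligible consecutive pair exactly once."""
    smap = al.fit_scale_map(small_masked, "health")
    expected = {s: 0 for s in al.SRH_LEVELS}
    for p in small_masked:
        n = p.times.size
        for k in range(n):
            if p.srh[k] == al.MISSING:
                continue
            label = al.SRH_LEVELS[p.srh[k]]
            if k + 1 < n:
                if p.srh[k + 1] != al.MISSING:
                    expected[label] += 1
            elif p.death_time is not None:
                expected[label] += 1
    assert {s: smap.support_counts[s] for s in al.SRH_LEVELS} == expected


def test_fitted_scores_match_closed_form():
    """With constant hazard and no drift, score(s) must sit within 3
    binomial SEs of 100 * exp(-h) * P(healthy next state | s)."""
    h = 0.05
    sim = al.SimulationConfig(
        n_persons=8000,
        seed=29,
        srh_age_drift=0.0,
        mortality={g: {"rate": h, "age_slope": 0.0} for g in al.GROUPS},
        missing_rate=0.0,
        structural_gap=None,
        group_fractions={g: (1.0 if g == ("F", "white") else 0.0) for g in al.GROUPS},
    )
    cohort = al.generate_cohort(sim)
    smap = al.fit_scale_map(cohort, "health")
    T = np.asarray(sim.srh_transition[("F", "white")])
    healthy_cols = [al.SRH_LEVELS.index(s) for s in ("E", "VG", "G")]
    for i, s in enumerate(al.SRH_LEVELS):
        p_true = np.exp(-h) * T[i, healthy_cols].sum()
        n_pairs = smap.support_counts[s]
        assert n_pairs > 100
        se = np.sqrt(p_true * (1 - p_true) / n_pairs)
        assert abs(smap.score(s) / 100.0 - p_true) < 3 * se, s


def test_monotonicity_diagnostic_on_default_cohort(mid_cohort):
    smap = al.fit_scale_map(mid_cohort, "health")
    assert smap.monotonicity_violations() == []


def test_apply_scale_map_constant_panel():
    p = make_panel(srh_labels=("E", "E", "E"))
    smap = al.HealthScaleMap(kind="health", state_scores={"E": 95.0})
    traj = al.apply_scale_map(p, smap, np.arange(5.0))
    assert np.allclose(traj.values[:3], 95.0)
    assert np.all(np.isnan(traj.values[3:]))


def test_apply_scale_map_death_forces_zero():
    p = make_panel(srh_labels=("E", "E"), death_time=1.4)
    smap = al.HealthScaleMap(kind="health", state_scores={"E": 95.0})
    traj = al.apply_scale_map(p, smap, np.arange(5.0))
    assert traj.values[1] == 95.0
    assert np.all(traj.values[2:] == 0.0)
    assert list(traj.provenance[2:]) == ["death"] * 3


def test_apply_scale_map_node_by_node(small_masked):
    """Scored nodes equal a direct per-node lookup against the map."""
    smap = al.fit_scale_map(small_masked, "health")
    grid = np.arange(19.0)
    for p in small_masked[:50]:
        traj = al.apply_scale_map(p, smap, grid)
        for k, t in enumerate(p.times):
            i = int(t)
            if p.srh[k] != al.MISSING and (p.death_time is None or t < p.death_time):
                assert traj.values[i] == smap.state_scores[al.SRH_LEVELS[p.srh[k]]]
        obs_nodes = {int(t) for k, t in enumerate(p.times) if p.srh[k] != al.MISSING}
        for i in range(19):
            if i not in obs_nodes and (p.death_time is None or grid[i] < p.death_time):
                assert np.isnan(traj.values[i])


def test_unscored_state_errors_and_nearest_fallback():
    p = make_panel(srh_labels=("F", "G"))
    smap = al.HealthScaleMap(kind="health", state_scores={"G": 80.0, "P": 10.0})
    with pytest.raises(UnscoredStateError, match="F"):
        al.apply_scale_map(p, smap, np.arange(2.0))
    traj = al.apply_scale_map(p, smap, np.arange(2.0), on_unscored="nearest")
    assert traj.values[0] == 10.0  # worse neighbour (P) preferred over G
    assert _nearest_scored(smap, "E") == "G"


def test_ability_map_keys_on_difficulty_count():
    rows = [(0, 0, 0, 0, 0, 0), (1, 0, 0, 0, 0, 0), (0, 0, 0, 0, 0, 0)]
    p = make_panel(srh_labels=("G", "G", "G"), adl_rows=rows)
    smap = al.fit_scale_map([p], "ability")
    # state 0 -> next waves: one not-able, then at the middle wave state 1 -> able
    assert smap.score("0") == pytest.approx(0.0)
    assert smap.score("1") == pytest.approx(100.0)
    assert smap.support_counts["0"] == 1
    assert smap.support_counts["1"] == 1


def test_scale_map_serialization(tmp_path, small_masked):
    smap = al.fit_scale_map(small_masked, "ability")
    df = smap.to_frame()
    assert set(df["state"]) == {"0", "1", "2", "3", "4", "5", "6", "DEAD"}
    out = tmp_path / "map.json"
    smap.to_json(out)
    import json

    data = json.loads(out.read_text())
    assert data["kind"] == "ability"
    assert data["state_scores"]["DEAD"] == 0.0
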