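"""Simulation and pipeline run configuration.

The synthetic cohort emulates an 18-year longitudinal panel of older adults
(65+) with annual interviews: a 5-level ordinal self-rated-health (SRH) item
that drifts toward worse categories with age, six binary activities-of-daily-
living (ADL) difficulty items, group-specific Gompertz-like mortality,
intermittent missing waves, and a multi-year structural window in which the
ADL instrument was not administered.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Ordinal self-rated health levels, best to worst.
SRH_LEVELS = ("E", "VG", "G", "F", "P")
#: Levels counted as "healthy".
HEALTHY_LEVELS = frozenset({"E", "VG", "G"})
#: Number of ADL items (walking, bed, eating, dressing, bathing, toilet).
N_ADL = 6

#: (sex, race) groups; sex in {F, M}, race in {white, non-white}.
GROUPS = (("F", "white"), ("M", "white"), ("F", "non-white"), ("M", "non-white"))

#: Baseline 5-year age bands (last band is open-ended).
AGE_BANDS = ((65, 69), (70, 74), (75, 79), (80, 100))


def age_band_label(age: float) -> str:
    """5-year baseline age band a person falls into, e.g. ``"70-74"``."""
    for lo, hi in AGE_BANDS:
        if lo <= age <= hi:
            return f"{lo}-{hi}"
    raise ValueError(f"baseline age {age} outside supported range 65-100")


class ConfigurationError(ValueError):
    """A simulation parameter violates its invariant; names the field."""


def _default_group_fractions() -> dict:
    # Baseline composition of a CHS-like cohort of 5888: counts
    # 2790 / 2135 / 603 / 360 for WF / WM / NWF / NWM.
    return {
        ("F", "white"): 2790 / 5888,
        ("M", "white"): 2135 / 5888,
        ("F", "non-white"): 603 / 5888,
        ("M", "non-white"): 360 / 5888,
    }


def _default_age_distribution() -> dict:
    # Marginal baseline age-band mix of the same cohort.
    return {
        "65-69": 2021 / 5888,
        "70-74": 1874 / 5888,
        "75-79": 1197 / 5888,
        "80-100": 796 / 5888,
    }


def _shift_worse(matrix: np.ndarray, d: float) -> np.ndarray:
    """Move fraction ``d`` of each row's mass one category toward worse."""
    m = np.asarray(matrix, dtype=float)
    out = m * (1.0 - d)
    out[:, 1:] += m[:, :-1] * d
    out[:, -1] += m[:, -1] * d  # worst category keeps its shifted mass
    return out / out.sum(axis=1, keepdims=True)


# Annual SRH transition rows (E, VG, G, F, P) for a generally healthy
# older cohort; rows are diagonally dominant with gradual worsening.
# Together with the mortality and drift defaults below these give a
# cohort spending ~69% of its remaining life healthy.
_BASE_SRH_TRANSITION = np.array(
    [
        [0.64, 0.25, 0.08, 0.02, 0.01],
        [0.21, 0.49, 0.23, 0.05, 0.02],
        [0.06, 0.23, 0.53, 0.15, 0.03],
        [0.02, 0.09, 0.32, 0.43, 0.14],
        [0.01, 0.04, 0.15, 0.37, 0.43],
    ]
)

# Baseline SRH distributions: non-white participants report worse SRH on
# average, consistent with the morbidity gradient the analysis studies.
_BASE_SRH_START = {
    "white": np.array([0.19, 0.31, 0.33, 0.13, 0.04]),
    "non-white": np.array([0.11, 0.21, 0.34, 0.23, 0.11]),
}


def _default_srh_transition() -> dict:
    return {
        ("F", "white"): _BASE_SRH_TRANSITION.copy(),
        ("M", "white"): _BASE_SRH_TRANSITION.copy(),
        ("F", "non-white"): _shift_worse(_BASE_SRH_TRANSITION, 0.09),
        ("M", "non-white"): _shift_worse(_BASE_SRH_TRANSITION, 0.11),
    }


def _default_srh_baseline() -> dict:
    return {
        (sex, race): _BASE_SRH_START[race].copy() for sex, race in GROUPS
    }


def _default_adl_incidence() -> dict:
    # Per-item annual probabilities: (baseline difficulty prevalence,
    # acquisition at age 65, recovery). Acquisition grows with age in the
    # generator (see cohort.generate_cohort); defaults give ~75% of
    # remaining life spent able.
    return {
        ("F", "white"): {"p0": 0.016, "acquire": 0.0055, "recover": 0.42},
        ("M", "white"): {"p0": 0.015, "acquire": 0.0050, "recover": 0.42},
        ("F", "non-white"): {"p0": 0.025, "acquire": 0.0085, "recover": 0.36},
        ("M", "non-white"): {"p0": 0.022, "acquire": 0.0075, "recover": 0.36},
    }


def _default_mortality() -> dict:
    # Gompertz hazard h(age) = rate * exp(age_slope * (age - 65)), per year.
    # Rates solved (bisection on the closed-form truncated mean survival
    # over the default baseline-age mix) so 18-year mean YOL is about
    # 13.1 / 11.0 / 12.5 / 10.4 years for WF / WM / NWF / NWM.
    return {
        ("F", "white"): {"rate": 0.0089, "age_slope": 0.095},
        ("M", "white"): {"rate": 0.0154, "age_slope": 0.095},
        ("F", "non-white"): {"rate": 0.0105, "age_slope": 0.095},
        ("M", "non-white"): {"rate": 0.0178, "age_slope": 0.095},
    }


@dataclass
class SimulationConfig:
    """Parameters of the synthetic person-wave panel generator.

    Defaults emulate the study conditions of an 18-year cohort of 5888
    adults aged 65+: the group mix and age mix of the cohort at baseline,
    worsening SRH dynamics, group-specific mortality, ~26% per-wave
    intermittent missingness (calibrated so ~45% of observations flank an
    intervening missing value), and a structural ADL gap in study years
    11-15 anchored by observed years 10 and 16.
    """

    n_persons: int = 5888
    group_fractions: dict = field(default_factory=_default_group_fractions)
    baseline_age_distribution: dict = field(default_factory=_default_age_distribution)
    follow_up_years: float = 18.0
    grid_step: float = 1.0
    srh_transition: dict = field(default_factory=_default_srh_transition)
    srh_baseline: dict = field(default_factory=_default_srh_baseline)
    srh_age_drift: float = 0.0022  # extra per-year-of-age shift toward worse
    adl_incidence: dict = field(default_factory=_default_adl_incidence)
    adl_age_slope: float = 0.07  # exponential age slope of ADL acquisition
    mortality: dict = field(default_factory=_default_mortality)
    missing_rate: float = 0.30  # gives ~45% of observations flanking a gap
    structural_gap: Optional[tuple] = (11.0, 15.0)
    gap_anchors: tuple = (10.0, 16.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.n_persons < 0:
            raise ConfigurationError("n_persons must be >= 0")
        if self.grid_step <= 0:
            raise ConfigurationError("grid_step must be positive")
        if self.follow_up_years <= 0:
            raise ConfigurationError("follow_up_years must be positive")
        for name, dist in (
            ("group_fractions", self.group_fractions),
            ("baseline_age_distribution", self.baseline_age_distribution),
        ):
            total = float(sum(dist.values()))
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} must sum to 1, got {total}")
            if any(v < 0 for v in dist.values()):
                raise ConfigurationError(f"{name} has a negative proportion")
        for g, m in self.srh_transition.items():
            m = np.asarray(m, dtype=float)
            if m.shape != (5, 5) or np.any(m < 0):
                raise ConfigurationError(f"srh_transition[{g}] is not a 5x5 nonnegative matrix")
            if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
                raise ConfigurationError(f"srh_transition[{g}] rows must sum to 1")
        for g, p in self.srh_baseline.items():
            p = np.asarray(p, dtype=float)
            if p.shape != (5,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise ConfigurationError(f"srh_baseline[{g}] is not a probability vector")
        for g, spec in self.mortality.items():
            if spec["rate"] < 0:
                raise ConfigurationError(f"mortality[{g}].rate must be nonnegative")
        for g, spec in self.adl_incidence.items():
            for k in ("p0", "acquire", "recover"):
                if not 0.0 <= spec[k] <= 1.0:
                    raise ConfigurationError(f"adl_incidence[{g}].{k} outside [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if self.structural_gap is not None:
            lo, hi = self.structural_gap
            if not (0.0 <= lo <= hi <= self.follow_up_years):
                raise ConfigurationError(
                    "structural_gap must lie within [0, follow_up_years]"
                )

    # ------------------------------------------------------------------
    @property
    def grid(self) -> np.ndarray:
        """Scheduled wave times: 0, grid_step, ..., follow_up_years."""
        n = int(round(self.follow_up_years / self.grid_step))
        return np.round(np.arange(n + 1) * self.grid_step, 10)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["group_fractions"] = {f"{s}|{r}": v for (s, r), v in self.group_fractions.items()}
        for key in ("srh_transition", "srh_baseline", "adl_incidence", "mortality"):
            d[key] = {
                f"{s}|{r}": np.asarray(v).tolist() if key in ("srh_transition", "srh_baseline") else dict(v)
                for (s, r), v in getattr(self, key).items()
            }
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
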