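"""Synthetic assessment data with the structure the analysis assumes.

Generates cohorts with a right-skewed (mistargeted) ability law, two item
clusters sharing within-cluster person random effects (local dependence),
optional uniform DIF on one item, one to three observations per patient
with within-person correlation, and EDSS/ABC/fall covariates linked
monotonically to ability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_types import N_ITEMS, AssessmentRecord
from .rasch_core.pcm import ItemParameters
from .rasch_core.testlets import DEFAULT_TESTLETS


def _default_delta() -> np.ndarray:
    d = np.linspace(-1.6, 1.6, N_ITEMS)
    return d - d.mean()


def _default_tau() -> list[np.ndarray]:
    return [np.array([-1.35, -0.45, 0.45, 1.35]) for _ in range(N_ITEMS)]


@dataclass
class AbilityDist:
    """Skew-normal ability law specified by target moments (logits)."""

    mean: float = 0.75
    sd: float = 1.5
    skew: float = 0.22  # Fisher skewness; |skew| < 0.99 for a skew-normal

    def skewnorm_params(self) -> tuple[float, float, float]:
        """(shape, loc, scale) of the scipy skewnorm with these moments."""
        g = self.skew
        if abs(g) < 1e-12:
            return 0.0, self.mean, self.sd
        if abs(g) >= 0.99:
            raise ValueError("skew-normal cannot reach |skewness| >= 0.99")

        def skew_of_shape(a: float) -> float:
            d = a / np.sqrt(1 + a**2)
            num = (4 - np.pi) / 2 * (d * np.sqrt(2 / np.pi)) ** 3
            return num / (1 - 2 * d**2 / np.pi) ** 1.5

        a = optimize.brentq(lambda a: skew_of_shape(a) - g, -60, 60)
        d = a / np.sqrt(1 + a**2)
        scale = self.sd / np.sqrt(1 - 2 * d**2 / np.pi)
        loc = self.mean - scale * d * np.sqrt(2 / np.pi)
        return a, loc, scale

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        a, loc, scale = self.skewnorm_params()
        return stats.skewnorm.rvs(a, loc=loc, scale=scale, size=n, random_state=rng)


@dataclass
class DIFSpec:
    item: int  # 0-based item index
    factor: str  # column of the person table, e.g. "gender"
    level: str  # level made harder
    shift: float  # uniform location shift in logits


@dataclass
class CovariateLink:
    """Monotone links from ability to EDSS (down), ABC (up), falls (down)."""

    edss_center: float = 5.5
    edss_slope: float = 0.8
    edss_noise: float = 1.7
    abc_center: float = 55.0
    abc_slope: float = 12.0
    abc_noise: float = 29.0
    falls_log_rate: float = -0.3
    falls_slope: float = 0.5


@dataclass
class SimulationConfig:
    n_patients: int = 500
    obs_per_patient_probs: tuple[float, float, float] = (0.586, 0.329, 0.085)
    ability: AbilityDist = field(default_factory=AbilityDist)
    item_locations: np.ndarray = field(default_factory=_default_delta)
    item_thresholds: list[np.ndarray] = field(default_factory=_default_tau)
    testlet_assignment: tuple[tuple[int, ...], ...] = DEFAULT_TESTLETS
    testlet_sd: float = 0.0
    dif: DIFSpec | None = None
    covariates: CovariateLink = field(default_factory=CovariateLink)
    obs_sd: float = 0.3  # within-person observation-level ability noise
    female_prob: float = 0.66
    course_probs: tuple[float, float, float] = (0.415, 0.451, 0.134)  # RR/SP/PP
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.obs_per_patient_probs, dtype=float)
        if not np.isclose(p.sum(), 1.0):
            raise ValueError("obs_per_patient_probs must sum to 1")
        if abs(float(np.sum(self.item_locations))) > 1e-8:
            raise ValueError("item locations must sum to zero")
        for t in self.item_thresholds:
            if abs(float(np.sum(t))) > 1e-8:
                raise ValueError("item thresholds must be centered (sum zero)")
        if self.testlet_sd < 0:
            raise ValueError("testlet_sd must be >= 0")

    def item_parameters(self) -> ItemParameters:
        return ItemParameters(
            delta=np.asarray(self.item_locations, dtype=float).copy(),
            tau=[np.asarray(t, dtype=float).copy() for t in self.item_thresholds],
        )


def simulate_persons(config: SimulationConfig,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Person table: patient_id, theta, gender, age, course, duration, n_obs."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_patients
    theta = config.ability.sample(n, rng)
    gender = np.where(rng.random(n) < config.female_prob, "female", "male")
    age = np.clip(rng.normal(51.5, 11.8, n), 18.0, 90.0).round(1)
    course = rng.choice(["RR", "SP", "PP"], size=n, p=config.course_probs)
    duration = np.clip(rng.gamma(2.0, 6.3, n), 0.0, 45.0).round(1)
    n_obs = rng.choice([1, 2, 3], size=n, p=config.obs_per_patient_probs)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:05d}" for i in range(n)],
            "theta": theta,
            "gender": gender,
            "age": age,
            "course": course,
            "duration": duration,
            "n_obs": n_obs,
        }
    )


def _draw_pcm_scores(theta_eff: np.ndarray, beta: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """theta_eff: (n,) effective abilities for one item; beta: (m+1,)."""
    h = np.arange(len(beta))
    logits = theta_eff[:, None] * h[None, :] - beta[None, :]
    logits -= logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random(len(theta_eff))
    return (u[:, None] > np.cumsum(p, axis=1)).sum(axis=1)


def simulate_responses(
    persons: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[AssessmentRecord]:
    """PCM responses with testlet random effects, DIF, repeated observations."""
    if persons.empty:
        raise ValueError("person table is empty")
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    params = config.item_parameters()
    beta = params.beta()
    cluster_of = np.empty(N_ITEMS, dtype=int)
    for c, grp in enumerate(config.testlet_assignment):
        cluster_of[list(grp)] = c
    n_clusters = len(config.testlet_assignment)

    has_cov = {"edss", "abc", "falls"}.issubset(persons.columns)

    # observation-level expansion (vectorized draws)
    n_obs = persons["n_obs"].to_numpy(int)
    rep = np.repeat(np.arange(len(persons)), n_obs)
    obs_index = np.concatenate([np.arange(1, k + 1) for k in n_obs])
    theta = persons["theta"].to_numpy()[rep]
    multi = (n_obs > 1)[rep]
    theta_obs = theta + np.where(multi, rng.normal(0.0, config.obs_sd, len(rep)), 0.0)
    u = rng.normal(0.0, config.testlet_sd, (len(rep), n_clusters))

    scores = np.empty((len(rep), N_ITEMS), dtype=int)
    for i in range(N_ITEMS):
        eff = theta_obs + u[:, cluster_of[i]]
        if config.dif is not None and i == config.dif.item:
            in_level = (
                persons[config.dif.factor].astype(str).to_numpy()[rep]
                == config.dif.level
            )
            eff = eff - config.dif.shift * in_level
        scores[:, i] = _draw_pcm_scores(eff, beta[i], rng)

    records: list[AssessmentRecord] = []
    cols = persons.iloc[rep].reset_index(drop=True)
    for v in range(len(rep)):
        row = cols.iloc[v]
        records.append(
            AssessmentRecord(
                patient_id=row["patient_id"],
                center="SIM",
                obs_index=int(obs_index[v]),
                gender=row["gender"],
                age=float(row["age"]),
                course=row["course"],
                duration=float(row["duration"]),
                edss=float(row["edss"]) if has_cov else None,
                abc=float(row["abc"]) if has_cov else None,
                falls=int(row["falls"]) if has_cov else None,
                items=tuple(int(x) for x in scores[v]),
            )
        )
    return records


def simulate_covariates(
    persons: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Attach EDSS (decreasing in theta), ABC (increasing), falls (decreasing)."""
    if "theta" not in persons.columns:
        raise ValueError("person table must carry theta")
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    link = config.covariates
    th = persons["theta"].to_numpy()
    n = len(persons)
    edss = link.edss_center - link.edss_slope * th + rng.normal(0, link.edss_noise, n)
    edss = np.clip(np.round(edss * 2) / 2, 0.0, 10.0)
    abc = link.abc_center + link.abc_slope * th + rng.normal(0, link.abc_noise, n)
    abc = np.clip(abc, 0.0, 100.0).round(1)
    falls = rng.poisson(np.exp(link.falls_log_rate - link.falls_slope * th))
    out = persons.copy()
    out["edss"] = edss
    out["abc"] = abc
    out["falls"] = falls
    return out


def simulate_dataset(config: SimulationConfig) -> list[AssessmentRecord]:
    """Full seed-reproducible cohort: persons + covariates + responses."""
    rng = np.random.default_rng(config.seed)
    persons = simulate_persons(config, rng)
    persons = simulate_covariates(persons, config, rng)
    return simulate_responses(persons, config, rng)
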