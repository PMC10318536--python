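"""Reliability and targeting: PSI, Cronbach's alpha, SEM, targeting index,
floor/ceiling effects, distinct levels of performance ability (DLPA) and
the distribution-independent person separation index (DI-PSI).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pcm import ItemParameters, PersonEstimate, score_conversion_table


@dataclass
class ReliabilityTargeting:
    psi: float  # without extreme persons
    psi_with_extremes: float
    alpha: float | None
    sem: float
    targeting_index: float
    floor_pct: float
    ceiling_pct: float
    dlpa: int | None
    di_psi: float | None


def cronbach_alpha(values: np.ndarray) -> float:
    """Classical alpha from the raw item-score matrix."""
    values = np.asarray(values, dtype=float)
    k = values.shape[1]
    if k < 2:
        return float("nan")
    item_var = values.var(axis=0, ddof=1)
    total_var = values.sum(axis=1).var(ddof=1)
    if total_var == 0:
        return float("nan")
    return k / (k - 1) * (1.0 - item_var.sum() / total_var)


def person_separation_index(theta: np.ndarray, se: np.ndarray) -> float:
    """(observed person variance - mean error variance) / observed variance."""
    var = float(np.var(theta, ddof=1))
    if var == 0:
        return float("nan")
    return (var - float(np.mean(se**2))) / var


def di_psi_from_strata(g: int | float) -> float:
    """Reliability implied by G statistically distinct strata: G^2/(1+G^2)."""
    return g**2 / (1.0 + g**2)


def distinct_ability_levels(
    params: ItemParameters, z: float = 1.96
) -> int:
    """Distribution-free strata count from the raw-score conversion table.

    Greedy pass over score-level measures in ascending order: accept the
    lowest; accept each subsequent score whose measure exceeds the last
    accepted one by at least z * sqrt(SE_a^2 + SE_b^2).
    """
    table = score_conversion_table(params)
    if len(table) < 3:
        raise ValueError("DLPA undefined with fewer than 3 raw scores")
    thetas = table["theta"].to_numpy()
    ses = table["se"].to_numpy()
    count = 1
    last = 0
    for i in range(1, len(thetas)):
        gap = thetas[i] - thetas[last]
        if gap >= z * np.sqrt(ses[i] ** 2 + ses[last] ** 2):
            count += 1
            last = i
    return count


def reliability_targeting(
    persons: list[PersonEstimate],
    params: ItemParameters,
    values: np.ndarray | None = None,
) -> ReliabilityTargeting:
    theta_all = np.array([p.theta for p in persons])
    se_all = np.array([p.se for p in persons])
    extreme = np.array([p.extreme for p in persons])
    raw = np.array([p.raw for p in persons])

    psi_wo = person_separation_index(theta_all[~extreme], se_all[~extreme])
    psi_with = person_separation_index(theta_all, se_all)
    alpha = cronbach_alpha(values) if values is not None else None

    sd = float(np.std(theta_all, ddof=1))
    sem = sd * np.sqrt(max(1.0 - psi_with, 0.0))
    ti = float(np.mean(theta_all)) / sem if sem > 0 else float("nan")

    max_total = params.max_total
    floor_pct = 100.0 * float(np.mean(raw == 0))
    ceiling_pct = 100.0 * float(np.mean(raw == max_total))

    try:
        g = distinct_ability_levels(params)
        dipsi = di_psi_from_strata(g)
    except ValueError:
        g, dipsi = None, None

    return ReliabilityTargeting(
        psi=psi_wo,
        psi_with_extremes=psi_with,
        alpha=alpha,
        sem=sem,
        targeting_index=ti,
        floor_pct=floor_pct,
        ceiling_pct=ceiling_pct,
        dlpa=g,
        di_psi=dipsi,
    )
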