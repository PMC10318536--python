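"""Differential item functioning: residual two-way ANOVA and split impact.

Uniform DIF shows as a main effect of the person factor on an item's
standardized residuals; non-uniform DIF as a factor-by-class-interval
interaction.  The impact of splitting a flagged item into group-specific
versions is quantified as the Cohen's d of the paired shift in person
estimates after anchoring the split solution on DIF-free items.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fit import class_interval_labels, default_class_interval_count, standardized_residuals
from .pcm import (
    ItemParameters,
    PersonEstimate,
    estimate_item_parameters,
    estimate_person_measures,
    theta_array,
)

MIN_LEVEL_SIZE = 10


@dataclass
class DIFResult:
    item: int
    factor: str
    main_F: float
    main_p: float
    interaction_F: float
    interaction_p: float


@dataclass
class DIFReport:
    results: list[DIFResult]
    bonferroni_cutoff: float
    n_class_intervals: int

    def flagged(self) -> list[DIFResult]:
        return [
            r
            for r in self.results
            if r.main_p < self.bonferroni_cutoff
            or r.interaction_p < self.bonferroni_cutoff
        ]

    def classify(self, r: DIFResult) -> str:
        if r.interaction_p < self.bonferroni_cutoff:
            return "non-uniform"
        if r.main_p < self.bonferroni_cutoff:
            return "uniform"
        return "none"


def _two_way_anova(y: np.ndarray, a: np.ndarray, b: np.ndarray):
    """Balanced-design-free two-way ANOVA (regression sums of squares).

    Returns (F_a, p_a, F_ab, p_ab): the main effect of `a` adjusted for
    `b`, and the interaction adjusted for both main effects.
    """

    def design(*factor_sets):
        cols = [np.ones((len(y), 1))]
        for fs in factor_sets:
            cols.append(fs)
        return np.hstack(cols)

    def dummies(f):
        levels = np.unique(f)
        return np.column_stack([(f == l).astype(float) for l in levels[1:]])

    def inter(da, db):
        return np.hstack([da * db[:, [j]] for j in range(db.shape[1])])

    def rss(Xd):
        beta, res, rank, _ = np.linalg.lstsq(Xd, y, rcond=None)
        fitted = Xd @ beta
        return float(np.sum((y - fitted) ** 2)), int(rank)

    da, db = dummies(a), dummies(b)
    dab = inter(da, db)
    rss_full, rank_full = rss(design(da, db, dab))
    rss_main, rank_main = rss(design(da, db))
    rss_b, rank_b = rss(design(db))
    n = len(y)
    df_err = n - rank_full
    if df_err <= 0:
        return np.nan, np.nan, np.nan, np.nan
    mse = rss_full / df_err

    df_a = rank_main - rank_b
    F_a = ((rss_b - rss_main) / df_a) / mse if df_a > 0 else np.nan
    p_a = stats.f.sf(F_a, df_a, df_err) if df_a > 0 else np.nan
    df_ab = rank_full - rank_main
    F_ab = ((rss_main - rss_full) / df_ab) / mse if df_ab > 0 else np.nan
    p_ab = stats.f.sf(F_ab, df_ab, df_err) if df_ab > 0 else np.nan
    return F_a, p_a, F_ab, p_ab


def prepare_factor(values, min_size: int = MIN_LEVEL_SIZE) -> np.ndarray | None:
    """Drop levels with fewer than `min_size` members (with a warning)."""
    f = np.asarray(values, dtype=object)
    keep = np.ones(len(f), dtype=bool)
    levels, counts = np.unique(f[f != None], return_counts=True)  # noqa: E711
    small = [l for l, c in zip(levels, counts) if c < min_size]
    if small:
        warnings.warn(f"factor levels dropped (too small): {small}", stacklevel=2)
        for l in small:
            keep &= f != l
    keep &= np.array([v is not None and not pd.isna(v) for v in f])
    if len(np.unique(f[keep])) < 2:
        return None
    out = np.where(keep, f, None)
    return out


def dif_analysis(
    values: np.ndarray,
    params: ItemParameters,
    persons: list[PersonEstimate],
    factors: pd.DataFrame,
    n_class_intervals: int | None = None,
) -> DIFReport:
    """Two-way ANOVA of standardized residuals on factor x class interval."""
    values = np.asarray(values, dtype=int)
    z, mask = standardized_residuals(values, params, persons)
    theta = theta_array(persons)[mask]
    z = z[mask]
    factors = factors.loc[np.asarray(mask)].reset_index(drop=True)
    if n_class_intervals is None:
        n_class_intervals = default_class_interval_count(z.shape[0])
    intervals = class_interval_labels(theta, n_class_intervals)

    K = params.n_items
    usable = {}
    for name in factors.columns:
        f = prepare_factor(factors[name].to_numpy())
        if f is None:
            warnings.warn(f"factor {name!r} skipped (single usable level)",
                          stacklevel=2)
            continue
        usable[name] = f
    n_tests = K * len(usable) * 2
    cutoff = 0.05 / n_tests if n_tests else np.nan

    results = []
    for name, f in usable.items():
        sel = np.array([v is not None for v in f])
        fa = np.array([str(v) for v in f[sel]])
        for i in range(K):
            F_a, p_a, F_ab, p_ab = _two_way_anova(z[sel, i], fa, intervals[sel])
            results.append(
                DIFResult(
                    item=i, factor=name,
                    main_F=F_a, main_p=p_a,
                    interaction_F=F_ab, interaction_p=p_ab,
                )
            )
    return DIFReport(
        results=results,
        bonferroni_cutoff=cutoff,
        n_class_intervals=n_class_intervals,
    )


def dif_split_impact(
    values: np.ndarray,
    params: ItemParameters,
    item: int,
    factor: np.ndarray,
    anchor_items: list[int] | None = None,
) -> float:
    """Cohen's d of the anchored person-estimate shift after splitting.

    The flagged item is re-estimated within each factor level (full CML
    on the level's subsample); each level's solution is aligned to the
    unsplit calibration through the mean location shift on the DIF-free
    anchor items; persons are then re-measured with their own level's
    version of the split item.  d = mean(paired difference) / SD.
    """
    values = np.asarray(values, dtype=int)
    K = params.n_items
    if anchor_items is None:
        anchor_items = [i for i in range(K) if i != item]
    if not anchor_items:
        raise ValueError("no DIF-free anchor items available")

    base_persons = estimate_person_measures(values, params)
    base_theta = theta_array(base_persons)

    factor = np.asarray(factor)
    split_theta = np.full(len(factor), np.nan)
    for level in np.unique(factor):
        sel = factor == level
        sub = values[sel]
        try:
            sub_params = estimate_item_parameters(sub, item_max=params.item_max)
        except ValueError:
            # level too degenerate to recalibrate: keep unsplit estimates
            split_theta[sel] = base_theta[sel]
            continue
        if sub_params.score_maps is not None:
            # collapsed categories make the level-specific item scale
            # incomparable; keep unsplit estimates for this level
            split_theta[sel] = base_theta[sel]
            continue
        shift = float(
            np.mean(params.delta[anchor_items] - sub_params.delta[anchor_items])
        )
        level_params = ItemParameters(
            delta=params.delta.copy(), tau=[t.copy() for t in params.tau]
        )
        level_params.delta[item] = sub_params.delta[item] + shift
        level_params.tau[item] = sub_params.tau[item].copy()
        est = estimate_person_measures(sub, level_params)
        split_theta[sel] = theta_array(est)

    diff = split_theta - base_theta
    sd = float(np.std(diff, ddof=1))
    if sd == 0.0:
        return 0.0
    return float(abs(np.mean(diff)) / sd)
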