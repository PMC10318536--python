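"""Model-fit diagnostics: standardized residuals, fit residuals,
item-trait chi-square over ability class intervals, threshold ordering,
residual structure (local dependence and the unidimensionality t-test),
and anchored re-fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .pcm import (
    ItemParameters,
    PersonEstimate,
    _prob_table,
    estimate_person_measures,
    expected_and_variance,
    theta_array,
)

PROB_ALPHA = 0.05


def default_class_interval_count(n_persons: int) -> int:
    """clamp(floor(n/50), 2, 10); gives 5 intervals at n = 288."""
    return int(np.clip(n_persons // 50, 2, 10))


@dataclass
class FitReport:
    item_fit_residuals: np.ndarray
    person_fit_residuals: np.ndarray
    item_fit_mean: float
    item_fit_sd: float
    person_fit_mean: float
    person_fit_sd: float
    item_chi2: np.ndarray
    item_df: np.ndarray
    item_p: np.ndarray
    total_chi2: float
    total_df: int
    total_p: float
    bonferroni_cutoff: float
    n_class_intervals: int
    disordered_items: list[int]
    disordered_pct: float
    icc_data: dict = field(default_factory=dict)
    n_persons: int = 0


@dataclass
class ResidualStructure:
    residual_corr: np.ndarray
    ldrc: float
    pc1_loadings: np.ndarray
    pst: float
    bci_lower: float
    positive_items: list[int]
    negative_items: list[int]
    computable: bool = True


def standardized_residuals(
    values: np.ndarray, params: ItemParameters, persons: list[PersonEstimate]
) -> tuple[np.ndarray, np.ndarray]:
    """(z, mask) where z is (n, K) and mask flags non-extreme persons."""
    theta = theta_array(persons)
    E, V = expected_and_variance(theta, params)
    z = (values - E) / np.sqrt(V)
    mask = ~np.array([p.extreme for p in persons])
    return z, mask


def _residual_kurtosis(
    values: np.ndarray, params: ItemParameters, theta: np.ndarray
) -> np.ndarray:
    """Model kurtosis E[(X-E)^4]/V^2 of each cell, shape (n, K)."""
    probs = _prob_table(theta, params)
    n = theta.shape[0]
    K = params.n_items
    kurt = np.empty((n, K))
    for i, p in enumerate(probs):
        h = np.arange(p.shape[1])
        mu = p @ h
        v = p @ h**2 - mu**2
        m4 = np.sum(p * (h[None, :] - mu[:, None]) ** 4, axis=1)
        kurt[:, i] = m4 / v**2
    return kurt


def _wh(S: np.ndarray, mu: np.ndarray, var: np.ndarray) -> np.ndarray:
    # X^(1/3) ~ Normal(mu^(1/3) (1 - var/(9 mu^2)), mu^(1/3) sqrt(var)/(3 mu))
    ratio = np.maximum(S / mu, 1e-12)
    cv = np.sqrt(var) / mu
    return (np.cbrt(ratio) - 1.0 + cv**2 / 9.0) * 3.0 / cv


def fit_residuals(
    values: np.ndarray, params: ItemParameters, persons: list[PersonEstimate]
) -> tuple[np.ndarray, np.ndarray]:
    """Wilson-Hilferty-standardized residual mean squares.

    Returns (item_fitres, person_fitres) computed over non-extreme
    persons; null mean is ~0 and null SD ~1 by construction, since the
    variance of each squared standardized residual is taken from the
    model's cell kurtosis rather than a chi-square assumption.
    """
    z, mask = standardized_residuals(values, params, persons)
    theta = theta_array(persons)[mask]
    z = z[mask]
    kurt = _residual_kurtosis(values[mask], params, theta)
    # leverage: estimating theta from the person's total absorbs a share
    # h_vi = V_vi / sum_j V_vj of each cell's variance, so E[z^2] = 1 - h
    _, V = expected_and_variance(theta, params)
    h = V / V.sum(axis=1, keepdims=True)
    mean_z2 = 1.0 - h
    var_z2 = (kurt - 1.0) * mean_z2**2
    S_item = (z**2).sum(axis=0)
    item_fr = _wh(S_item, mean_z2.sum(axis=0), var_z2.sum(axis=0))
    S_pers = (z**2).sum(axis=1)
    pers_fr = _wh(S_pers, mean_z2.sum(axis=1), var_z2.sum(axis=1))
    return item_fr, pers_fr


def class_interval_labels(theta: np.ndarray, n_intervals: int) -> np.ndarray:
    """Quantile-based ability class intervals; merges degenerate cuts."""
    qs = np.quantile(theta, np.linspace(0, 1, n_intervals + 1)[1:-1])
    qs = np.unique(qs)
    labels = np.searchsorted(qs, theta, side="right")
    # merge intervals with < 2 persons into their neighbor
    while True:
        uniq, counts = np.unique(labels, return_counts=True)
        if len(uniq) <= 2 or counts.min() >= 2:
            break
        warnings.warn("class interval with < 2 persons merged", stacklevel=2)
        k = uniq[np.argmin(counts)]
        target = uniq[max(0, int(np.where(uniq == k)[0][0]) - 1)]
        if target == k:
            target = uniq[1]
        labels[labels == k] = target
        # re-densify
        _, labels = np.unique(labels, return_inverse=True)
    _, labels = np.unique(labels, return_inverse=True)
    return labels


def disordered_threshold_items(params: ItemParameters) -> list[int]:
    """Items whose adjacent-category thresholds are not strictly increasing."""
    out = []
    for i, thr in enumerate(params.adjacent_thresholds()):
        if len(thr) > 1 and np.any(np.diff(thr) <= 0):
            out.append(i)
    return out


def fit_statistics(
    values: np.ndarray,
    params: ItemParameters,
    persons: list[PersonEstimate],
    n_class_intervals: int | None = None,
) -> FitReport:
    values = np.asarray(values, dtype=int)
    mask = ~np.array([p.extreme for p in persons])
    theta = theta_array(persons)
    theta_in = theta[mask]
    X = values[mask]
    n_in = X.shape[0]
    K = params.n_items
    if n_class_intervals is None:
        n_class_intervals = default_class_interval_count(n_in)
    labels = class_interval_labels(theta_in, n_class_intervals)
    C = int(labels.max()) + 1

    E, V = expected_and_variance(theta_in, params)
    item_chi2 = np.zeros(K)
    icc = {}
    for i in range(K):
        obs = np.zeros(C)
        exp_ = np.zeros(C)
        var_ = np.zeros(C)
        for c in range(C):
            sel = labels == c
            obs[c] = X[sel, i].sum()
            exp_[c] = E[sel, i].sum()
            var_[c] = V[sel, i].sum()
        item_chi2[i] = float(np.sum((obs - exp_) ** 2 / var_))
        icc[i] = {
            "interval_mean_theta": np.array(
                [theta_in[labels == c].mean() for c in range(C)]
            ),
            "observed_mean": np.array(
                [X[labels == c, i].mean() for c in range(C)]
            ),
            "expected_mean": np.array(
                [E[labels == c, i].mean() for c in range(C)]
            ),
        }
    item_df = np.full(K, C - 1)
    item_p = stats.chi2.sf(item_chi2, item_df)
    total_chi2 = float(item_chi2.sum())
    total_df = int(item_df.sum())
    total_p = float(stats.chi2.sf(total_chi2, total_df))

    item_fr, pers_fr = fit_residuals(values, params, persons)
    disordered = disordered_threshold_items(params)

    return FitReport(
        item_fit_residuals=item_fr,
        person_fit_residuals=pers_fr,
        item_fit_mean=float(item_fr.mean()),
        item_fit_sd=float(item_fr.std(ddof=1)) if K > 1 else 0.0,
        person_fit_mean=float(pers_fr.mean()),
        person_fit_sd=float(pers_fr.std(ddof=1)),
        item_chi2=item_chi2,
        item_df=item_df,
        item_p=item_p,
        total_chi2=total_chi2,
        total_df=total_df,
        total_p=total_p,
        bonferroni_cutoff=PROB_ALPHA / K,
        n_class_intervals=C,
        disordered_items=disordered,
        disordered_pct=100.0 * len(disordered) / K,
        icc_data=icc,
        n_persons=n_in,
    )


def _subset_params(params: ItemParameters, items: list[int]) -> ItemParameters:
    return ItemParameters(
        delta=params.delta[items], tau=[params.tau[i] for i in items]
    )


def residual_structure(
    values: np.ndarray,
    params: ItemParameters,
    persons: list[PersonEstimate],
    loading_cut: float = 0.3,
    ldrc_offset: float = 0.2,
) -> ResidualStructure:
    values = np.asarray(values, dtype=int)
    z, mask = standardized_residuals(values, params, persons)
    z = z[mask]
    corr = np.corrcoef(z, rowvar=False)
    K = corr.shape[0]
    off = corr[~np.eye(K, dtype=bool)]
    ldrc = float(off.mean() + ldrc_offset)

    evals, evecs = np.linalg.eigh(corr)
    pc1 = evecs[:, -1] * np.sqrt(max(evals[-1], 0.0))
    if pc1.sum() < 0:
        pc1 = -pc1

    pos = [i for i in range(K) if pc1[i] > loading_cut]
    neg = [i for i in range(K) if pc1[i] < -loading_cut]
    if len(pos) < 2 or len(neg) < 2:
        return ResidualStructure(
            residual_corr=corr,
            ldrc=ldrc,
            pc1_loadings=pc1,
            pst=float("nan"),
            bci_lower=float("nan"),
            positive_items=pos,
            negative_items=neg,
            computable=False,
        )

    t_stats = _split_t_tests(values, params, pos, neg)
    pst = float(np.mean(np.abs(t_stats) > 1.96))
    n = len(t_stats)
    bci = pst - 1.96 * np.sqrt(max(pst * (1 - pst), 1e-12) / n)
    return ResidualStructure(
        residual_corr=corr,
        ldrc=ldrc,
        pc1_loadings=pc1,
        pst=100.0 * pst,
        bci_lower=100.0 * max(bci, 0.0),
        positive_items=pos,
        negative_items=neg,
    )


def _split_t_tests(
    X: np.ndarray, params: ItemParameters, pos: list[int], neg: list[int]
) -> np.ndarray:
    """Per-person t comparing subset abilities (Warm-weighted estimates;
    plain ML on short subsets is anti-conservative)."""
    from .pcm import wle_for_raw

    series = []
    for items in (pos, neg):
        sub = _subset_params(params, items)
        cache: dict[int, tuple[float, float]] = {}
        raws = X[:, items].sum(axis=1)
        th = np.empty(len(raws))
        se = np.empty(len(raws))
        for v, r in enumerate(raws):
            r = int(r)
            if r not in cache:
                cache[r] = wle_for_raw(r, sub)
            th[v], se[v] = cache[r]
        series.append((th, se))
    (tp, sp), (tn, sn) = series
    return (tp - tn) / np.sqrt(sp**2 + sn**2)


def anchor_and_refit(
    values: np.ndarray,
    anchored: ItemParameters,
    n_class_intervals: int | None = None,
):
    """Hold item parameters fixed, re-estimate persons, re-run fit battery."""
    from .reliability import reliability_targeting

    values = np.asarray(values, dtype=int)
    if values.shape[1] != anchored.n_items:
        raise ValueError(
            "sample has items absent from the anchor (column count mismatch)"
        )
    if (values.max(axis=0) > anchored.item_max).any():
        raise ValueError("observed category exceeds anchored item maximum")
    persons = estimate_person_measures(values, anchored)
    report = fit_statistics(values, anchored, persons, n_class_intervals)
    reli = reliability_targeting(persons, anchored, values=values)
    return persons, report, reli
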