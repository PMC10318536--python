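"""Preliminary unidimensionality battery.

Classical item statistics (Cronbach's alpha, item-rest correlations),
Mokken scalability coefficients with the automated item selection
procedure, polychoric correlations, and a one-factor ordinal factor
analysis fitted by unweighted least squares to the polychoric matrix.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .rasch_core.reliability import cronbach_alpha


@dataclass
class ClassicalItemStats:
    alpha: float
    alpha_if_deleted: np.ndarray
    item_rest_rho: np.ndarray
    mean_interitem_rho: float


@dataclass
class MokkenResult:
    H: float
    Hj: np.ndarray
    Hij: np.ndarray
    aisp_partition: np.ndarray | None = None  # 0 = unscalable, 1.. = scale id


@dataclass
class OrdinalFactorFit:
    polychoric: np.ndarray
    loadings: np.ndarray
    chi2: float
    df: int
    p: float
    rmsea: float
    srmr: float
    cfi: float
    tli: float
    flagged_pairs: list[tuple[int, int]]
    residuals: np.ndarray
    converged: bool


# ---------------------------------------------------------------------------
# classical item statistics
# ---------------------------------------------------------------------------


def classical_item_stats(values: np.ndarray) -> ClassicalItemStats:
    values = np.asarray(values, dtype=float)
    n, K = values.shape
    if K < 2 or n < 3:
        raise ValueError("need at least 2 items and 3 persons")
    alpha = cronbach_alpha(values)
    alpha_del = np.empty(K)
    rest_rho = np.empty(K)
    total = values.sum(axis=1)
    for i in range(K):
        others = np.delete(values, i, axis=1)
        alpha_del[i] = cronbach_alpha(others)
        rest = total - values[:, i]
        if values[:, i].std() == 0:
            warnings.warn(f"item {i} has zero variance; correlations undefined",
                          stacklevel=2)
            rest_rho[i] = np.nan
        else:
            rest_rho[i] = stats.spearmanr(values[:, i], rest).statistic
    pair_rhos = []
    for i, j in itertools.combinations(range(K), 2):
        if values[:, i].std() and values[:, j].std():
            pair_rhos.append(stats.spearmanr(values[:, i], values[:, j]).statistic)
    return ClassicalItemStats(
        alpha=alpha,
        alpha_if_deleted=alpha_del,
        item_rest_rho=rest_rho,
        mean_interitem_rho=float(np.mean(pair_rhos)),
    )


# ---------------------------------------------------------------------------
# Mokken scalability
# ---------------------------------------------------------------------------


def _max_covariance(x: np.ndarray, y: np.ndarray) -> float:
    """Largest covariance attainable given the two marginals
    (comonotonic coupling: pair the sorted samples)."""
    xs = np.sort(x)
    ys = np.sort(y)
    return float(np.mean(xs * ys) - np.mean(xs) * np.mean(ys))


def mokken_coefficients(values: np.ndarray) -> MokkenResult:
    """Normed-covariance scalability coefficients Hij, Hj, H."""
    values = np.asarray(values, dtype=float)
    n, K = values.shape
    cov = np.cov(values, rowvar=False, ddof=0)
    covmax = np.zeros((K, K))
    for i, j in itertools.combinations(range(K), 2):
        covmax[i, j] = covmax[j, i] = _max_covariance(values[:, i], values[:, j])
    Hij = np.full((K, K), np.nan)
    for i, j in itertools.combinations(range(K), 2):
        if covmax[i, j] <= 0:
            warnings.warn(
                f"degenerate marginals for item pair ({i}, {j}); Hij undefined",
                stacklevel=2,
            )
            continue
        Hij[i, j] = Hij[j, i] = cov[i, j] / covmax[i, j]
    off = ~np.eye(K, dtype=bool)
    Hj = np.array(
        [cov[i, off[i]].sum() / covmax[i, off[i]].sum() for i in range(K)]
    )
    num = sum(cov[i, j] for i, j in itertools.combinations(range(K), 2))
    den = sum(covmax[i, j] for i, j in itertools.combinations(range(K), 2))
    return MokkenResult(H=float(num / den), Hj=Hj, Hij=Hij)


def mokken_aisp(values: np.ndarray, lower_bound: float = 0.3) -> np.ndarray:
    """Automated item selection: greedy scale growth maximizing H.

    Returns an item -> scale-id partition (0 marks unscalable items).
    A selected item must keep Hj >= lower_bound within its scale and have
    positive Hij with every current scale member.
    """
    values = np.asarray(values, dtype=float)
    K = values.shape[1]
    res = mokken_coefficients(values)
    partition = np.zeros(K, dtype=int)
    remaining = set(range(K))
    scale_id = 0

    def scale_ok(members: list[int]) -> bool:
        sub = mokken_coefficients(values[:, members])
        if np.any(sub.Hj < lower_bound):
            return False
        iu = np.triu_indices(len(members), k=1)
        return bool(np.all(sub.Hij[iu] > 0))

    while True:
        # best admissible starting pair among remaining items
        best_pair, best_h = None, -np.inf
        for i, j in itertools.combinations(sorted(remaining), 2):
            h = res.Hij[i, j]
            if np.isnan(h) or h <= 0:
                continue
            if h > best_h and scale_ok([i, j]):
                best_pair, best_h = (i, j), h
        if best_pair is None or best_h < lower_bound:
            break
        scale_id += 1
        members = list(best_pair)
        remaining -= set(best_pair)
        grew = True
        while grew:
            grew = False
            best_item, best_H = None, -np.inf
            for cand in sorted(remaining):
                trial = members + [cand]
                if not scale_ok(trial):
                    continue
                h = mokken_coefficients(values[:, trial]).H
                if h > best_H:
                    best_item, best_H = cand, h
            if best_item is not None:
                members.append(best_item)
                remaining.discard(best_item)
                grew = True
        partition[members] = scale_id
    return partition


# ---------------------------------------------------------------------------
# polychoric correlations
# ---------------------------------------------------------------------------


def _thresholds_from_marginal(x: np.ndarray, n_cat: int) -> np.ndarray:
    counts = np.bincount(x, minlength=n_cat).astype(float)
    cum = np.cumsum(counts)[:-1] / counts.sum()
    cum = np.clip(cum, 1e-6, 1 - 1e-6)
    return stats.norm.ppf(cum)


def _pair_polychoric(x: np.ndarray, y: np.ndarray) -> float:
    """Two-step ML: normal-quantile thresholds, then 1-D search for rho."""
    nx = int(x.max()) + 1
    ny = int(y.max()) + 1
    tx = _thresholds_from_marginal(x, nx)
    ty = _thresholds_from_marginal(y, ny)
    table = np.zeros((nx, ny))
    np.add.at(table, (x, y), 1.0)
    if np.any(table == 0):
        table = np.where(table == 0, 0.5, table)  # continuity correction
    table /= table.sum()
    ax = np.concatenate([[-np.inf], tx, [np.inf]])
    ay = np.concatenate([[-np.inf], ty, [np.inf]])

    gx, gy = np.meshgrid(ax, ay, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    finite = np.isfinite(pts).all(axis=1)

    def cell_probs(rho: float) -> np.ndarray:
        F = np.zeros(len(pts))
        F[(pts[:, 0] == np.inf) & (pts[:, 1] == np.inf)] = 1.0
        ix = (pts[:, 0] == np.inf) & np.isfinite(pts[:, 1])
        F[ix] = stats.norm.cdf(pts[ix, 1])
        iy = np.isfinite(pts[:, 0]) & (pts[:, 1] == np.inf)
        F[iy] = stats.norm.cdf(pts[iy, 0])
        if finite.any():
            mvn = stats.multivariate_normal(
                mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
            )
            F[finite] = mvn.cdf(pts[finite])
        Fg = F.reshape(nx + 1, ny + 1)
        p = Fg[1:, 1:] - Fg[:-1, 1:] - Fg[1:, :-1] + Fg[:-1, :-1]
        return np.clip(p, 1e-12, None)

    def nll(rho: float) -> float:
        return -float(np.sum(table * np.log(cell_probs(rho))))

    res = optimize.minimize_scalar(nll, bounds=(-0.999, 0.999), method="bounded")
    return float(res.x)


def polychoric_matrix(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=int)
    K = values.shape[1]
    for i in range(K):
        if len(np.unique(values[:, i])) < 2:
            raise ValueError(f"item {i} has fewer than 2 observed categories")
    R = np.eye(K)
    for i, j in itertools.combinations(range(K), 2):
        R[i, j] = R[j, i] = _pair_polychoric(values[:, i], values[:, j])
    return R


# ---------------------------------------------------------------------------
# one-factor ordinal CFA (ULS on the polychoric matrix)
# ---------------------------------------------------------------------------


def _smooth_psd(R: np.ndarray) -> np.ndarray:
    evals, evecs = np.linalg.eigh(R)
    if evals.min() >= 1e-8:
        return R
    evals = np.clip(evals, 1e-8, None)
    S = evecs @ np.diag(evals) @ evecs.T
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


def cfa_onefactor_fit(
    polychoric: np.ndarray,
    n: int,
    correlated_pairs: list[tuple[int, int]] | None = None,
    residual_flag: float = 0.1,
) -> OrdinalFactorFit:
    """One-factor model by unweighted least squares on a correlation matrix.

    Optionally frees residual correlations for `correlated_pairs`.  Fit
    indices are computed from the ULS discrepancy scaled by (n - 1); they
    preserve the fit/misfit decision logic, not any specific estimator's
    output.
    """
    S = _smooth_psd(np.asarray(polychoric, dtype=float))
    K = S.shape[0]
    pairs = list(correlated_pairs or [])
    iu = np.triu_indices(K, k=1)

    def implied(theta: np.ndarray) -> np.ndarray:
        lam = theta[:K]
        Sigma = np.outer(lam, lam)
        for k, (i, j) in enumerate(pairs):
            Sigma[i, j] = Sigma[j, i] = Sigma[i, j] + theta[K + k]
        np.fill_diagonal(Sigma, 1.0)
        return Sigma

    def discrepancy(theta: np.ndarray) -> float:
        d = (S - implied(theta))[iu]
        return float(np.sum(d * d))

    x0 = np.concatenate([np.full(K, 0.7), np.zeros(len(pairs))])
    res = optimize.minimize(discrepancy, x0, method="L-BFGS-B")
    if not res.success and res.fun > 1e-6:
        raise RuntimeError(f"one-factor ULS did not converge: {res.message}")
    theta = res.x
    Sigma = implied(theta)
    resid = S - Sigma

    F = discrepancy(theta)
    df = K * (K - 1) // 2 - K - len(pairs)
    chi2 = (n - 1) * F
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else float("nan")
    rmsea = (
        float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1)))) if df > 0 else 0.0
    )
    srmr = float(np.sqrt(np.mean(resid[iu] ** 2)))
    # baseline: independence model (zero off-diagonal correlations)
    F0 = float(np.sum(S[iu] ** 2))
    chi2_0 = (n - 1) * F0
    df0 = K * (K - 1) // 2
    cfi = float(
        1.0 - max(chi2 - df, 0.0) / max(chi2_0 - df0, chi2 - df, 1e-12)
    )
    tli = (
        float((chi2_0 / df0 - chi2 / df) / (chi2_0 / df0 - 1.0))
        if df > 0
        else float("nan")
    )
    flagged = [
        (int(i), int(j))
        for i, j in zip(*iu)
        if abs(resid[i, j]) > residual_flag and (i, j) not in pairs
    ]
    return OrdinalFactorFit(
        polychoric=S,
        loadings=theta[:K],
        chi2=chi2,
        df=df,
        p=p,
        rmsea=rmsea,
        srmr=srmr,
        cfi=cfi,
        tli=tli,
        flagged_pairs=flagged,
        residuals=resid,
        converged=bool(res.success),
    )
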