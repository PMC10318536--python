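"""Partial credit model: probabilities, CML item estimation, person measures.

Parameterization
----------------
Item ``i`` has ordered categories ``0..m_i``.  With ability ``theta``,
item location ``delta_i`` and centered thresholds ``tau_{i,1..m_i}``
(sum zero), the cumulative category parameter is

    beta_{i,0} = 0,   beta_{i,x} = sum_{k<=x} (delta_i + tau_{i,k})

and  P(X_i = x | theta) = exp(x*theta - beta_{i,x}) / sum_h exp(h*theta - beta_{i,h}).

Item parameters are estimated by conditional maximum likelihood: the
conditional likelihood given each person's total score is expressed
through elementary symmetric functions (polynomial convolution of the
per-item weights exp(-beta)), and maximized by Newton iteration with an
analytic gradient and Hessian.  The single flat direction of the
conditional likelihood (beta_{i,x} -> beta_{i,x} + c*x) is pinned by a
quadratic penalty on sum_i delta_i, which selects the sum-zero-location
solution without altering fitted probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

GRAD_TOL = 1e-6
MAX_NEWTON_ITER = 200
EXTREME_ADJ = 0.3  # raw-score adjustment for extreme totals
THETA_BRACKET = 30.0


class ConvergenceError(RuntimeError):
    pass


@dataclass
class ItemParameters:
    """Per-item locations and centered thresholds (logits)."""

    delta: np.ndarray  # (K,)
    tau: list[np.ndarray]  # tau[i] has length m_i, sums to 0
    score_maps: list[np.ndarray] | None = None  # original -> collapsed category

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        self.tau = [np.asarray(t, dtype=float) for t in self.tau]
        if len(self.tau) != self.delta.shape[0]:
            raise ValueError("delta and tau sizes disagree")

    @property
    def n_items(self) -> int:
        return self.delta.shape[0]

    @property
    def item_max(self) -> np.ndarray:
        return np.array([len(t) for t in self.tau])

    @property
    def max_total(self) -> int:
        return int(self.item_max.sum())

    def beta(self) -> list[np.ndarray]:
        """Cumulative category parameters, beta[i][x] for x = 0..m_i."""
        out = []
        for d, t in zip(self.delta, self.tau):
            out.append(np.concatenate([[0.0], np.cumsum(d + t)]))
        return out

    def adjacent_thresholds(self) -> list[np.ndarray]:
        """Adjacent-category (Rasch-Andrich) thresholds delta_i + tau_ik."""
        return [d + t for d, t in zip(self.delta, self.tau)]

    @classmethod
    def from_beta(cls, beta: list[np.ndarray], **kw) -> "ItemParameters":
        delta = np.array([b[-1] / (len(b) - 1) for b in beta])
        tau = [np.diff(b) - d for b, d in zip(beta, delta)]
        return cls(delta=delta, tau=tau, **kw)


@dataclass
class PersonEstimate:
    theta: float
    se: float
    raw: int
    extreme: bool


def pcm_category_probs(theta: float, delta: float, tau: np.ndarray) -> np.ndarray:
    """Category probabilities 0..m for a single item at a single ability."""
    tau = np.asarray(tau, dtype=float)
    beta = np.concatenate([[0.0], np.cumsum(delta + tau)])
    m = len(tau)
    logits = np.arange(m + 1) * theta - beta
    logits -= logits.max()
    p = np.exp(logits)
    return p / p.sum()


def _prob_table(theta: np.ndarray, params: ItemParameters) -> list[np.ndarray]:
    """probs[i] has shape (len(theta), m_i + 1)."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    out = []
    for b in params.beta():
        h = np.arange(len(b))
        logits = theta[:, None] * h[None, :] - b[None, :]
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        out.append(p / p.sum(axis=1, keepdims=True))
    return out


def expected_and_variance(
    theta: np.ndarray, params: ItemParameters
) -> tuple[np.ndarray, np.ndarray]:
    """Model expectation and variance of each item score, shape (n, K)."""
    probs = _prob_table(theta, params)
    n = np.atleast_1d(theta).shape[0]
    K = params.n_items
    E = np.empty((n, K))
    V = np.empty((n, K))
    for i, p in enumerate(probs):
        h = np.arange(p.shape[1])
        E[:, i] = p @ h
        V[:, i] = p @ h**2 - E[:, i] ** 2
    return E, V


# ---------------------------------------------------------------------------
# elementary symmetric functions
# ---------------------------------------------------------------------------


def _esf(eps_list: list[np.ndarray]) -> np.ndarray:
    """Coefficient r of prod_i (sum_h eps[i][h] z^h)."""
    g = np.array([1.0])
    for e in eps_list:
        g = np.convolve(g, e)
    return g


class _CMLWorkspace:
    """Caches ESF prefix/suffix products for gradient/Hessian evaluation."""

    def __init__(self, beta: list[np.ndarray]):
        self.beta = beta
        self.K = len(beta)
        # per-item scaling keeps the convolution in a safe float range;
        # all probability ratios are scale-invariant
        self.shift = [b.min() for b in beta]
        self.eps = [np.exp(-(b - s)) for b, s in zip(beta, self.shift)]
        self.log_scale = -float(np.sum(self.shift))
        pre: list[np.ndarray] = [np.array([1.0])]
        for e in self.eps[:-1]:
            pre.append(np.convolve(pre[-1], e))
        suf: list[np.ndarray] = [np.array([1.0])]
        for e in reversed(self.eps[1:]):
            suf.append(np.convolve(suf[-1], e))
        suf.reverse()
        self.prefix = pre  # prefix[i] = conv of items < i
        self.suffix = suf  # suffix[i] = conv of items > i
        self.gamma = np.convolve(self.prefix[-1], self.eps[-1])
        self.gamma_wo = [
            np.convolve(self.prefix[i], self.suffix[i]) for i in range(self.K)
        ]

    def log_gamma(self, r: np.ndarray) -> np.ndarray:
        return np.log(self.gamma[r]) + self.log_scale

    def cond_prob(self, i: int, r: np.ndarray) -> np.ndarray:
        """pi[v, h] = P(X_i = h | total = r_v), vectorized over totals."""
        m = len(self.eps[i]) - 1
        gw = self.gamma_wo[i]
        out = np.zeros((len(r), m + 1))
        for h in range(m + 1):
            idx = r - h
            ok = (idx >= 0) & (idx < len(gw))
            out[ok, h] = self.eps[i][h] * gw[idx[ok]] / self.gamma[r[ok]]
        return out

    def gamma_wo_pair(self, i: int, j: int) -> np.ndarray:
        """ESF of all items except i and j (i < j)."""
        g = self.prefix[i]
        for k in range(i + 1, j):
            g = np.convolve(g, self.eps[k])
        return np.convolve(g, self.suffix[j])


def _collapse_matrix(values: np.ndarray, item_max: np.ndarray):
    """Merge unobserved (null) categories; returns collapsed data + maps."""
    K = values.shape[1]
    new = np.empty_like(values)
    maps = []
    collapsed_any = False
    for i in range(K):
        observed = np.zeros(item_max[i] + 1, dtype=bool)
        observed[values[:, i]] = True
        # map each original category to its rank among observed ones;
        # unobserved categories inherit the rank of the next lower observed
        ranks = np.cumsum(observed) - 1
        ranks = np.maximum(ranks, 0)
        maps.append(ranks)
        new[:, i] = ranks[values[:, i]]
        if not observed.all():
            collapsed_any = True
    if collapsed_any:
        warnings.warn(
            "null item categories collapsed before CML estimation; "
            "score maps recorded on the returned ItemParameters",
            stacklevel=3,
        )
    new_max = np.array([m.max() for m in maps])
    return new, new_max, (maps if collapsed_any else None)


def estimate_item_parameters(
    values: np.ndarray,
    item_max: np.ndarray | None = None,
    penalty_weight: float = 1.0,
) -> ItemParameters:
    """Conditional ML estimation of PCM item parameters.

    Persons with extreme totals (0 or the maximum) carry no conditional
    information and are ignored.  Null categories are collapsed with a
    warning (`score_maps` records the original -> collapsed mapping).
    """
    values = np.asarray(values, dtype=int)
    if item_max is None:
        item_max = values.max(axis=0)
    item_max = np.asarray(item_max, dtype=int)
    if np.any(
        np.array([len(np.unique(values[:, i])) for i in range(values.shape[1])]) < 2
    ):
        raise ValueError("every item needs at least 2 observed categories")

    values, item_max, score_maps = _collapse_matrix(values, item_max)
    K = values.shape[1]
    max_total = int(item_max.sum())
    totals = values.sum(axis=1)
    inner = (totals > 0) & (totals < max_total)
    X = values[inner]
    if X.shape[0] < K:
        raise ValueError("too few non-extreme persons for estimation")
    r_obs = X.sum(axis=1)
    N_r = np.bincount(r_obs, minlength=max_total + 1).astype(float)
    used_r = np.nonzero(N_r)[0]

    # category counts n[i][h]
    counts = [
        np.bincount(X[:, i], minlength=item_max[i] + 1).astype(float) for i in range(K)
    ]
    sizes = item_max.tolist()
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    P = offsets[-1]
    mvec = item_max.astype(float)

    # flat parameter vector: beta_{i,1..m_i}
    def unflatten(b: np.ndarray) -> list[np.ndarray]:
        return [
            np.concatenate([[0.0], b[offsets[i] : offsets[i + 1]]]) for i in range(K)
        ]

    def objective(bflat: np.ndarray):
        beta = unflatten(bflat)
        ws = _CMLWorkspace(beta)
        f = 0.0
        for i in range(K):
            f += float(counts[i][1:] @ beta[i][1:])
        f += float(N_r[used_r] @ ws.log_gamma(used_r))
        s = float(np.sum([b[-1] / m for b, m in zip(beta, mvec)]))
        f += 0.5 * penalty_weight * s * s
        return f, ws, s

    def gradient(ws: _CMLWorkspace, s: float) -> np.ndarray:
        g = np.empty(P)
        for i in range(K):
            pi = ws.cond_prob(i, used_r)  # (R, m_i+1)
            expected = N_r[used_r] @ pi  # per category
            g[offsets[i] : offsets[i + 1]] = counts[i][1:] - expected[1:]
        # penalty term: d s / d beta_{i,m_i} = 1/m_i
        for i in range(K):
            g[offsets[i + 1] - 1] += penalty_weight * s / mvec[i]
        return g

    def hessian(ws: _CMLWorkspace) -> np.ndarray:
        H = np.zeros((P, P))
        pis = [ws.cond_prob(i, used_r) for i in range(K)]
        w = N_r[used_r]
        for i in range(K):
            pi = pis[i][:, 1:]  # (R, m_i)
            blk = -np.einsum("r,rh,rg->hg", w, pi, pi)
            blk[np.diag_indices_from(blk)] += w @ pi
            H[offsets[i] : offsets[i + 1], offsets[i] : offsets[i + 1]] = blk
        for i in range(K):
            for j in range(i + 1, K):
                gw = ws.gamma_wo_pair(i, j)
                mi, mj = sizes[i], sizes[j]
                pij = np.zeros((len(used_r), mi, mj))
                for h in range(1, mi + 1):
                    for gcat in range(1, mj + 1):
                        idx = used_r - h - gcat
                        ok = (idx >= 0) & (idx < len(gw))
                        pij[ok, h - 1, gcat - 1] = (
                            ws.eps[i][h]
                            * ws.eps[j][gcat]
                            * gw[idx[ok]]
                            / ws.gamma[used_r[ok]]
                        )
                cross = np.einsum("r,rhg->hg", w, pij) - np.einsum(
                    "r,rh,rg->hg", w, pis[i][:, 1:], pis[j][:, 1:]
                )
                H[offsets[i] : offsets[i + 1], offsets[j] : offsets[j + 1]] = cross
                H[offsets[j] : offsets[j + 1], offsets[i] : offsets[i + 1]] = cross.T
        a = np.zeros(P)
        for i in range(K):
            a[offsets[i + 1] - 1] = 1.0 / mvec[i]
        return H + penalty_weight * np.outer(a, a)

    # initial values from overall category frequencies
    b0 = np.empty(P)
    for i in range(K):
        freq = counts[i] + 0.5
        b0[offsets[i] : offsets[i + 1]] = np.log(freq[0]) - np.log(freq[1:])

    b = b0
    f, ws, s = objective(b)
    for _ in range(MAX_NEWTON_ITER):
        g = gradient(ws, s)
        if np.max(np.abs(g)) < GRAD_TOL:
            break
        H = hessian(ws)
        try:
            step = np.linalg.solve(H, -g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, -g, rcond=None)[0]
        # step-halving on objective increase
        lam = 1.0
        for _ in range(40):
            f_new, ws_new, s_new = objective(b + lam * step)
            if f_new <= f + 1e-12:
                break
            lam *= 0.5
        else:
            raise ConvergenceError("step halving failed in CML Newton")
        b = b + lam * step
        f, ws, s = f_new, ws_new, s_new
    else:
        raise ConvergenceError(
            f"CML did not reach gradient tolerance {GRAD_TOL} "
            f"in {MAX_NEWTON_ITER} iterations (|g|={np.max(np.abs(g)):.2e})"
        )

    params = ItemParameters.from_beta(unflatten(b), score_maps=score_maps)
    # exact re-centering along the flat direction
    c = params.delta.mean()
    params.delta = params.delta - c
    return params


def apply_score_maps(values: np.ndarray, params: ItemParameters) -> np.ndarray:
    """Re-map raw categories through the parameters' collapse maps.

    Categories beyond the calibrated range (possible when anchoring a new
    sample) are clipped to the highest calibrated category.
    """
    values = np.asarray(values, dtype=int)
    if params.score_maps is None:
        return values
    cols = []
    for i, m in enumerate(params.score_maps):
        idx = np.clip(values[:, i], 0, len(m) - 1)
        cols.append(m[idx])
    return np.column_stack(cols)


def conditional_loglik(values: np.ndarray, params: ItemParameters) -> float:
    """Conditional log-likelihood of non-extreme response rows.

    If the parameters were estimated after null-category collapsing,
    `score_maps` is applied to the data first so category indices match.
    """
    values = apply_score_maps(values, params)
    beta = params.beta()
    totals = values.sum(axis=1)
    inner = (totals > 0) & (totals < params.max_total)
    X = values[inner]
    ws = _CMLWorkspace(beta)
    ll = 0.0
    for i in range(params.n_items):
        ll -= float(np.sum(beta[i][X[:, i]]))
    ll -= float(np.sum(ws.log_gamma(X.sum(axis=1))))
    return ll


# ---------------------------------------------------------------------------
# person measures
# ---------------------------------------------------------------------------


def _solve_theta(target: float, params: ItemParameters) -> tuple[float, float]:
    """Solve sum_i E[X_i|theta] = target; returns (theta, se)."""

    def score_gap(th: float) -> float:
        E, _ = expected_and_variance(np.array([th]), params)
        return float(E.sum()) - target

    theta = brentq(score_gap, -THETA_BRACKET, THETA_BRACKET, xtol=1e-10)
    _, V = expected_and_variance(np.array([theta]), params)
    info = float(V.sum())
    return theta, 1.0 / np.sqrt(info)


def theta_for_raw(raw: float, params: ItemParameters) -> tuple[float, float]:
    """Ability and SE for a raw total under complete data (no adjustment)."""
    return _solve_theta(raw, params)


def estimate_person_measures(
    values: np.ndarray, params: ItemParameters
) -> list[PersonEstimate]:
    """Per-person ML ability given fixed item parameters.

    Extreme raw totals are shifted inward by 0.3 score points before
    solving and flagged.  Under complete data the estimate depends on the
    data only through the raw total, so estimates are cached per total.
    """
    values = np.asarray(values, dtype=int)
    totals = values.sum(axis=1)
    max_total = params.max_total
    cache: dict[int, tuple[float, float]] = {}
    out = []
    for r in totals:
        r = int(r)
        if r not in cache:
            extreme = r in (0, max_total)
            target = float(np.clip(r, EXTREME_ADJ, max_total - EXTREME_ADJ))
            cache[r] = _solve_theta(target, params)
        theta, se = cache[r]
        out.append(
            PersonEstimate(theta=theta, se=se, raw=r, extreme=r in (0, max_total))
        )
    return out


def _info_and_dinfo(theta: float, params: ItemParameters) -> tuple[float, float]:
    """Test information and its theta-derivative at a single ability."""
    probs = _prob_table(np.array([theta]), params)
    info = 0.0
    dinfo = 0.0
    for p in probs:
        h = np.arange(p.shape[1])
        p = p[0]
        m1 = p @ h
        m2 = p @ h**2
        m3 = p @ h**3
        info += m2 - m1**2
        dinfo += m3 - 3 * m2 * m1 + 2 * m1**3  # dV/dtheta = 3rd central moment
    return float(info), float(dinfo)


def wle_for_raw(raw: float, params: ItemParameters) -> tuple[float, float]:
    """Warm's weighted-likelihood ability for a raw total (complete data).

    Solves sum(x - E) + I'(theta)/(2 I(theta)) = 0; finite at extreme
    scores, with smaller bias than plain ML on short item subsets.
    SE = 1/sqrt(I) at the solution.
    """

    def f(th: float) -> float:
        E, _ = expected_and_variance(np.array([th]), params)
        info, dinfo = _info_and_dinfo(th, params)
        return (raw - float(E.sum())) + dinfo / (2.0 * info)

    theta = brentq(f, -THETA_BRACKET, THETA_BRACKET, xtol=1e-10)
    info, _ = _info_and_dinfo(theta, params)
    return theta, 1.0 / np.sqrt(info)


def theta_array(persons: list[PersonEstimate]) -> np.ndarray:
    return np.array([p.theta for p in persons])


def se_array(persons: list[PersonEstimate]) -> np.ndarray:
    return np.array([p.se for p in persons])


# ---------------------------------------------------------------------------
# raw-score to measure conversion
# ---------------------------------------------------------------------------


def score_conversion_table(
    params: ItemParameters, rescale: tuple[float, float] = (0.0, 100.0)
):
    """Raw total -> (theta, SE, 95% CI, rescaled 0-100) under complete data."""
    import pandas as pd

    max_total = params.max_total
    rows = []
    for r in range(max_total + 1):
        target = float(np.clip(r, EXTREME_ADJ, max_total - EXTREME_ADJ))
        theta, se = _solve_theta(target, params)
        rows.append((r, theta, se))
    t0 = rows[0][1]
    t1 = rows[-1][1]
    lo, hi = rescale
    scale = (hi - lo) / (t1 - t0)
    table = pd.DataFrame(rows, columns=["raw", "theta", "se"])
    table["ci_low"] = table.theta - 1.96 * table.se
    table["ci_high"] = table.theta + 1.96 * table.se
    table["scaled"] = lo + (table.theta - t0) * scale
    table["scaled_se"] = table.se * scale
    return table
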