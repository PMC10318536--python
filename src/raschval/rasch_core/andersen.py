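"""Conditional total fit statistic for super-item (testlet) solutions.

The unconditional item-trait chi-square is unreliable for samples of a
few hundred or more, so the final testlet solution is also checked with
a conditional statistic that never references estimated abilities:
under the PCM the distribution of each item score given the person's
TOTAL score is fully determined by the item parameters (through the
elementary symmetric functions), so observed category patterns can be
compared with their exact conditional expectations.

Persons are grouped into class intervals by total score.  For interval
``c`` let ``D_c`` collect the summed category-bin indicator deviations
``1[x_vi in bin] - P(X_i in bin | r_v)`` over the first K-1 items (the
K-th item is redundant: given the total, its scores are determined by
the others).  Distribution-level indicators -- rather than item scores
-- are essential, because a two-super-item PCM is rich enough to
reproduce almost any conditional score mean per total, leaving score
sums without power.  Raw super-item categories are too sparse for
chi-square asymptotics, so adjacent categories are merged into a few
pooled-quantile bins (for the statistic only; estimation always uses
the full categories).

Three estimation modes control the covariance of ``D``:

* ``"split"`` (default): item parameters come from one random half of
  the persons and the deviations from the other, so parameter noise
  only ADDS variance: V = S + C I^+ C'.  This avoids the conservative
  shrinkage that plugging in same-sample CML estimates produces when
  the parameter count is an appreciable fraction of n.
* ``"full"``: same-sample CML estimates with the first-order
  score-equation adjustment V = S - C I^+ C'.
* ``"anchored"``: externally fixed parameters, V = S.

chi2 = D' V^+ D with df = rank(V).

A group-refit Andersen likelihood-ratio test was considered and
rejected: with two testlets the category supports of low- and
high-total intervals are nearly disjoint, so interval-specific CML
estimates do not exist without category merging so aggressive that the
comparison loses meaning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .pcm import (
    ItemParameters,
    _CMLWorkspace,
    apply_score_maps,
    estimate_item_parameters,
)


@dataclass
class ConditionalFit:
    statistic: float
    df: int
    p: float
    n_groups: int


def _pair_prob(ws: _CMLWorkspace, i: int, j: int, r: np.ndarray) -> np.ndarray:
    """pi2[v, h, g] = P(X_i = h, X_j = g | total = r_v), i < j."""
    gw = ws.gamma_wo_pair(i, j)
    mi = len(ws.eps[i]) - 1
    mj = len(ws.eps[j]) - 1
    out = np.zeros((len(r), mi + 1, mj + 1))
    for h in range(mi + 1):
        for g in range(mj + 1):
            idx = r - h - g
            ok = (idx >= 0) & (idx < len(gw))
            out[ok, h, g] = (
                ws.eps[i][h] * ws.eps[j][g] * gw[idx[ok]] / ws.gamma[r[ok]]
            )
    return out


def _conditional_cov(params: ItemParameters, ru: np.ndarray):
    """Cov(1[X_i=h], 1[X_j=g] | r) over free categories, per unique total."""
    K = params.n_items
    sizes = params.item_max.tolist()
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    P = int(offsets[-1])
    ws = _CMLWorkspace(params.beta())
    pis = [ws.cond_prob(i, ru) for i in range(K)]
    covII = np.zeros((len(ru), P, P))
    for i in range(K):
        sl = slice(offsets[i], offsets[i + 1])
        p = pis[i][:, 1:]
        blk = -np.einsum("rh,rg->rhg", p, p)
        bi = np.arange(sizes[i])
        blk[:, bi, bi] += p
        covII[:, sl, sl] = blk
    for i in range(K):
        for j in range(i + 1, K):
            p2 = _pair_prob(ws, i, j, ru)
            cross = p2[:, 1:, 1:] - np.einsum(
                "rh,rg->rhg", pis[i][:, 1:], pis[j][:, 1:]
            )
            covII[:, offsets[i]:offsets[i + 1], offsets[j]:offsets[j + 1]] = cross
            covII[:, offsets[j]:offsets[j + 1], offsets[i]:offsets[i + 1]] = (
                cross.transpose(0, 2, 1)
            )
    return covII, pis, offsets, P


def _interval_labels(r: np.ndarray, n_groups: int,
                     group_labels: np.ndarray | None) -> np.ndarray:
    if group_labels is not None:
        _, labels = np.unique(np.asarray(group_labels), return_inverse=True)
    else:
        qs = np.unique(np.quantile(r, np.linspace(0, 1, n_groups + 1)[1:-1]))
        labels = np.searchsorted(qs, r, side="right")
        _, labels = np.unique(labels, return_inverse=True)
    while True:
        uniq, counts = np.unique(labels, return_counts=True)
        if len(uniq) <= 2 or counts.min() >= 10:
            break
        warnings.warn("merging a small total-score interval", stacklevel=3)
        k = uniq[np.argmin(counts)]
        tgt = k - 1 if k > 0 else uniq[1]
        labels[labels == k] = tgt
        _, labels = np.unique(labels, return_inverse=True)
    return labels


def conditional_total_chi2(
    values: np.ndarray,
    n_groups: int = 5,
    params: ItemParameters | None = None,
    group_labels: np.ndarray | None = None,
    estimation: str | None = None,
    min_expected: float = 8.0,
    split_seed: int = 0,
) -> ConditionalFit:
    """Conditional item-trait chi-square over total-score class intervals."""
    values = np.asarray(values, dtype=int)
    if values.shape[1] < 2:
        raise ValueError("need at least two (super-)items")
    if estimation is None:
        estimation = "anchored" if params is not None else "split"
    if estimation not in ("split", "full", "anchored"):
        raise ValueError(f"unknown estimation mode {estimation!r}")

    n = values.shape[0]
    if estimation == "split" and params is None:
        rng = np.random.default_rng(split_seed)
        perm = rng.permutation(n)
        half = n // 2
        train, evaluate = perm[:half], perm[half:]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            params = estimate_item_parameters(values[train])
        train_values = apply_score_maps(values[train], params)
        eval_values = apply_score_maps(values[evaluate], params)
        if group_labels is not None:
            group_labels = np.asarray(group_labels)[evaluate]
    else:
        if params is None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                params = estimate_item_parameters(values)
            if estimation == "anchored":
                estimation = "full"
        train_values = None
        eval_values = apply_score_maps(values, params)

    totals = eval_values.sum(axis=1)
    inner = (totals > 0) & (totals < params.max_total)
    X = eval_values[inner]
    r_all = X.sum(axis=1)
    if group_labels is not None:
        group_labels = np.asarray(group_labels)[inner]
    labels = _interval_labels(r_all, n_groups, group_labels)
    C = int(labels.max()) + 1
    if C < 2:
        raise ValueError("cannot form two total-score class intervals")

    K = params.n_items
    sizes = params.item_max.tolist()
    ru, r_inv = np.unique(r_all, return_inverse=True)
    covII, pis, offsets, P = _conditional_cov(params, ru)

    # information matrix from the sample that produced the estimates
    if estimation == "split":
        tt = train_values.sum(axis=1)
        t_in = tt[(tt > 0) & (tt < params.max_total)]
        tu, t_counts = np.unique(t_in, return_counts=True)
        covII_t, _, _, _ = _conditional_cov(params, tu)
        info = np.einsum("r,rpq->pq", t_counts.astype(float), covII_t)
    else:
        n_per_r = np.bincount(r_inv, minlength=len(ru)).astype(float)
        info = np.einsum("r,rpq->pq", n_per_r, covII)

    ind = np.zeros((X.shape[0], P))
    expected = np.zeros((X.shape[0], P))
    rows_idx = np.arange(X.shape[0])
    for i in range(K):
        hs = X[:, i]
        nz = hs >= 1
        ind[rows_idx[nz], offsets[i] + hs[nz] - 1] = 1.0
        expected[:, offsets[i]:offsets[i + 1]] = pis[i][r_inv, 1:]

    # interval-specific bin maps: merge adjacent categories of each of
    # the first K-1 items until every bin has expected count >= 5 within
    # the interval; the first bin is the dropped reference
    def interval_bin_rows(sel) -> np.ndarray:
        rows = []
        w = np.bincount(r_inv[sel], minlength=len(ru)).astype(float)
        for i in range(K - 1):
            e_cat = np.concatenate(
                [[float(w @ pis[i][:, 0])], w @ pis[i][:, 1:]]
            )
            bin_of = np.empty(sizes[i] + 1, dtype=int)
            b, acc = 0, 0.0
            for h in range(sizes[i] + 1):
                bin_of[h] = b
                acc += e_cat[h]
                if acc >= min_expected:
                    b += 1
                    acc = 0.0
            if acc > 0 and b > 0:
                bin_of[bin_of == b] = b - 1
            for bb in range(1, bin_of.max() + 1):
                row = np.zeros(P)
                for h in range(1, sizes[i] + 1):
                    if bin_of[h] == bb:
                        row[offsets[i] + h - 1] = 1.0
                rows.append(row)
        return np.array(rows) if rows else np.zeros((0, P))

    D_parts, S_blocks, C_parts = [], [], []
    for c in range(C):
        sel = labels == c
        Lc = interval_bin_rows(sel)
        if Lc.shape[0] == 0:
            continue
        w = np.bincount(r_inv[sel], minlength=len(ru)).astype(float)
        Sigma_c = np.einsum("r,rpq->pq", w, covII)
        D_parts.append(Lc @ (ind[sel] - expected[sel]).sum(axis=0))
        S_blocks.append(Lc @ Sigma_c @ Lc.T)
        C_parts.append(Lc @ Sigma_c)
    if not D_parts:
        raise ValueError("no usable category bins; data too degenerate")
    D = np.concatenate(D_parts)
    dims = [len(d) for d in D_parts]
    S = np.zeros((len(D), len(D)))
    pos = 0
    for blk, k in zip(S_blocks, dims):
        S[pos:pos + k, pos:pos + k] = blk
        pos += k
    Cmat = np.vstack(C_parts)

    if estimation == "split":
        V = S + Cmat @ np.linalg.pinv(info, rcond=1e-10) @ Cmat.T
    elif estimation == "full":
        V = S - Cmat @ np.linalg.pinv(info, rcond=1e-10) @ Cmat.T
    else:
        V = S

    evals, evecs = np.linalg.eigh(V)
    tol = max(evals.max(), 1.0) * 1e-8
    keep = evals > tol
    df = int(keep.sum())
    if df == 0:
        return ConditionalFit(statistic=0.0, df=0, p=1.0, n_groups=C)
    y = evecs[:, keep].T @ D
    chi2 = float(np.sum(y**2 / evals[keep]))
    return ConditionalFit(
        statistic=chi2, df=df, p=float(stats.chi2.sf(chi2, df)), n_groups=C
    )
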