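"""Testlet (super-item) construction and subscale unidimensionality indices.

Locally dependent items are summed into polytomous super-items, which
absorbs their shared variance while preserving every person's total
score.  After re-fitting the PCM on the super-items, three subscale
indices are derived from the two per-testlet person-estimate series:

* ``r``  -- disattenuated latent correlation between the subscales,
  C / sqrt(T1 * T2) with C = cov(t1, t2) and T_k = var(t_k) - mean SE_k^2,
  capped at 1;
* ``c``  -- unique-variance indicator, mean over subscales of
  (T_k - C) / var(t_k) (low values support unidimensionality);
* ``A``  -- common non-error variance, 2C / (var(t1) + var(t2)).

The exact decomposition behind the published c and A is not fully
specified by its source; the formulas above are documented surrogates
built from the same observed/true/error variance components and are not
meant to reproduce published values digit-for-digit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pcm import (
    EXTREME_ADJ,
    ItemParameters,
    _solve_theta,
    estimate_item_parameters,
)

#: default two-cluster partition (0-based item indices):
#: items 1-6 and 8-11 form one testlet; items 7, 12, 13, 14 the other.
DEFAULT_TESTLETS: tuple[tuple[int, ...], ...] = (
    (0, 1, 2, 3, 4, 5, 7, 8, 9, 10),
    (6, 11, 12, 13),
)


@dataclass
class TestletSpec:
    groups: tuple[tuple[int, ...], ...] = DEFAULT_TESTLETS

    def validate(self, n_items: int) -> None:
        flat = [i for g in self.groups for i in g]
        if sorted(flat) != list(range(n_items)):
            raise ValueError(
                "testlet partition must cover every item exactly once"
            )


@dataclass
class SubscaleIndices:
    c: float
    r: float
    A: float


def build_testlet_matrix(values: np.ndarray, spec: TestletSpec) -> np.ndarray:
    values = np.asarray(values, dtype=int)
    spec.validate(values.shape[1])
    return np.column_stack([values[:, list(g)].sum(axis=1) for g in spec.groups])


def testlet_item_max(item_max: np.ndarray, spec: TestletSpec) -> np.ndarray:
    return np.array([int(np.sum(item_max[list(g)])) for g in spec.groups])


def _single_item_estimates(scores: np.ndarray, delta: float, tau: np.ndarray):
    """Per-person ability and SE from one polytomous super-item."""
    params = ItemParameters(delta=np.array([delta]), tau=[np.asarray(tau)])
    m = len(tau)
    cache: dict[int, tuple[float, float]] = {}
    thetas = np.empty(len(scores))
    ses = np.empty(len(scores))
    for v, x in enumerate(scores):
        x = int(x)
        if x not in cache:
            target = float(np.clip(x, EXTREME_ADJ, m - EXTREME_ADJ))
            cache[x] = _solve_theta(target, params)
        thetas[v], ses[v] = cache[x]
    return thetas, ses


def subscale_indices(
    testlet_values: np.ndarray, params: ItemParameters
) -> SubscaleIndices:
    """Indices from the two testlet person-estimate series (see module doc)."""
    if params.n_items != 2:
        raise ValueError("subscale indices are defined for a two-testlet fit")
    series = []
    for k in range(2):
        t, se = _single_item_estimates(
            testlet_values[:, k], params.delta[k], params.tau[k]
        )
        series.append((t, se))
    (t1, s1), (t2, s2) = series
    V1, V2 = np.var(t1, ddof=1), np.var(t2, ddof=1)
    C = float(np.cov(t1, t2, ddof=1)[0, 1])
    T1 = V1 - float(np.mean(s1**2))
    T2 = V2 - float(np.mean(s2**2))
    if T1 <= 0 or T2 <= 0:
        r = float("nan")
    else:
        r = float(np.clip(C / np.sqrt(T1 * T2), -1.0, 1.0))
    c = float(np.mean([(T1 - C) / V1, (T2 - C) / V2]))
    A = float(2.0 * C / (V1 + V2))
    return SubscaleIndices(c=c, r=r, A=A)


def build_testlets(
    values: np.ndarray, spec: TestletSpec | None = None
) -> tuple[np.ndarray, ItemParameters, SubscaleIndices]:
    """Sum item groups into super-items, re-fit the PCM, derive indices."""
    spec = spec or TestletSpec()
    tl = build_testlet_matrix(values, spec)
    params = estimate_item_parameters(tl)
    idx = subscale_indices(tl, params)
    return tl, params, idx
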