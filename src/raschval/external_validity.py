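"""Convergent and discriminant validity.

Rank correlations against clinical anchors, two-group Mann-Whitney and
k-group Kruskal-Wallis comparisons with Bonferroni-corrected post-hocs,
the effect-size conversion chain r = |z|/sqrt(N), d = 2r/sqrt(1 - r^2)
(and eta-squared = (H - k + 1)/(n - k) for k groups), and normality
assessment of the measure distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

CORRELATION_BANDS = (
    (0.80, "very strong"),
    (0.50, "strong"),
    (0.30, "moderate"),
    (0.10, "weak"),
    (0.00, "negligible"),
)


def interpret_correlation(rho: float) -> str:
    a = abs(rho)
    for cut, label in CORRELATION_BANDS:
        if a >= cut:
            return label
    return "negligible"


def d_from_r(r: float) -> float:
    """Cohen's d from a point-biserial-style r: d = 2r / sqrt(1 - r^2)."""
    return 2.0 * r / np.sqrt(1.0 - r**2)


def d_from_eta2(eta2: float) -> float:
    return 2.0 * np.sqrt(eta2 / (1.0 - eta2))


def mannwhitney_d(z: float, n_total: int) -> float:
    """Effect-size chain from the normal-approximation z of a U test."""
    r = abs(z) / np.sqrt(n_total)
    return d_from_r(r)


def kruskal_eta2(H: float, k: int, n: int, variant: str = "adjusted") -> float:
    """eta^2 from a Kruskal-Wallis H; 'adjusted' = (H - k + 1)/(n - k)."""
    if variant == "adjusted":
        return max((H - k + 1) / (n - k), 0.0)
    if variant == "simple":
        return max(H / (n - 1), 0.0)
    raise ValueError(f"unknown eta2 variant {variant!r}")


@dataclass
class SpearmanResult:
    rho: float
    p: float
    n: int
    label: str


def spearman_assoc(x: np.ndarray, y: np.ndarray) -> SpearmanResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 5:
        raise ValueError("need at least 5 paired values")
    if x.std() == 0 or y.std() == 0:
        warnings.warn("constant series; correlation undefined", stacklevel=2)
        return SpearmanResult(float("nan"), float("nan"), len(x), "undefined")
    res = stats.spearmanr(x, y)
    return SpearmanResult(
        rho=float(res.statistic),
        p=float(res.pvalue),
        n=len(x),
        label=interpret_correlation(res.statistic),
    )


@dataclass
class GroupComparison:
    grouping: str
    k: int
    n_per_group: list[int]
    medians: list[float]
    statistic: float
    z: float | None
    p: float
    effect_r: float | None
    eta2: float | None
    cohens_d: float
    posthoc: list[dict] = field(default_factory=list)


def group_compare(
    measures: np.ndarray,
    groups: np.ndarray,
    grouping: str = "",
    eta2_variant: str = "adjusted",
) -> GroupComparison:
    """Mann-Whitney (k=2) or Kruskal-Wallis (k>=3) with d conversion."""
    measures = np.asarray(measures, dtype=float)
    groups = np.asarray(groups)
    ok = ~np.isnan(measures)
    measures, groups = measures[ok], groups[ok]
    levels = [l for l in pd_unique(groups)]
    samples = [measures[groups == l] for l in levels]
    if len(levels) < 2 or any(len(s) == 0 for s in samples):
        raise ValueError("need >= 2 non-empty groups")
    for l, s in zip(levels, samples):
        if len(s) < 2:
            warnings.warn(f"group {l!r} has < 2 members", stacklevel=2)
    n = len(measures)
    medians = [float(np.median(s)) for s in samples]
    ns = [len(s) for s in samples]
    if len(levels) == 2:
        a, b = samples
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        U = float(res.statistic)
        # tie-corrected normal approximation z
        mu = len(a) * len(b) / 2.0
        _, counts = np.unique(measures, return_counts=True)
        tie = np.sum(counts**3 - counts)
        sigma2 = (
            len(a) * len(b) / 12.0 * ((n + 1) - tie / (n * (n - 1.0)))
        )
        z = (U - mu) / np.sqrt(sigma2)
        r = abs(z) / np.sqrt(n)
        return GroupComparison(
            grouping=grouping,
            k=2,
            n_per_group=ns,
            medians=medians,
            statistic=U,
            z=float(z),
            p=float(res.pvalue),
            effect_r=float(r),
            eta2=None,
            cohens_d=float(d_from_r(r)),
        )
    H, p = stats.kruskal(*samples)
    k = len(levels)
    eta2 = kruskal_eta2(float(H), k, n, variant=eta2_variant)
    n_pairs = k * (k - 1) // 2
    posthoc = []
    for i in range(k):
        for j in range(i + 1, k):
            sub = group_compare(
                np.concatenate([samples[i], samples[j]]),
                np.concatenate(
                    [np.zeros(len(samples[i])), np.ones(len(samples[j]))]
                ),
                grouping=f"{levels[i]} vs {levels[j]}",
            )
            posthoc.append(
                {
                    "pair": (levels[i], levels[j]),
                    "U": sub.statistic,
                    "z": sub.z,
                    "p_raw": sub.p,
                    "p_bonferroni": min(sub.p * n_pairs, 1.0),
                    "d": sub.cohens_d,
                }
            )
    return GroupComparison(
        grouping=grouping,
        k=k,
        n_per_group=ns,
        medians=medians,
        statistic=float(H),
        z=None,
        p=float(p),
        effect_r=None,
        eta2=float(eta2),
        cohens_d=float(d_from_eta2(eta2)),
        posthoc=posthoc,
    )


def pd_unique(values: np.ndarray) -> list:
    """Order-preserving unique (keeps the caller's group ordering)."""
    seen: dict = {}
    for v in values:
        if v not in seen:
            seen[v] = None
    return list(seen)


@dataclass
class NormalityReport:
    skewness: float
    kurtosis: float  # Pearson scale: normal = 3
    ks_stat: float
    ks_p: float
    shapiro_stat: float
    shapiro_p: float
    n: int


def normality_check(measures: np.ndarray) -> NormalityReport:
    x = np.asarray(measures, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 8:
        raise ValueError("need at least 8 values")
    if x.std() == 0:
        raise ValueError("constant series")
    ks = stats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # shapiro warns for n > 5000
        sw = stats.shapiro(x)
    return NormalityReport(
        skewness=float(stats.skew(x)),
        kurtosis=float(stats.kurtosis(x, fisher=False)),
        ks_stat=float(ks.statistic),
        ks_p=float(ks.pvalue),
        shapiro_stat=float(sw.statistic),
        shapiro_p=float(sw.pvalue),
        n=len(x),
    )


# standard clinical groupings used by the discriminant-validity stage
def edss_three_groups(edss: np.ndarray) -> np.ndarray:
    e = np.asarray(edss, dtype=float)
    out = np.full(e.shape, None, dtype=object)
    out[e <= 3.5] = "EDSS 0-3.5"
    out[(e >= 4.0) & (e <= 5.5)] = "EDSS 4-5.5"
    out[e >= 6.0] = "EDSS >=6"
    return out


def abc_faller_groups(abc: np.ndarray) -> np.ndarray:
    a = np.asarray(abc, dtype=float)
    out = np.full(a.shape, None, dtype=object)
    out[a < 40] = "ABC <40 (fallers)"
    out[a >= 40] = "ABC >=40 (non-fallers)"
    return out


def abc_functioning_groups(abc: np.ndarray) -> np.ndarray:
    a = np.asarray(abc, dtype=float)
    out = np.full(a.shape, None, dtype=object)
    out[a < 50] = "ABC <50 (low)"
    out[(a >= 50) & (a <= 80)] = "ABC 50-80 (moderate)"
    out[a > 80] = "ABC >80 (high)"
    return out


def falls_groups(falls: np.ndarray, cut: int = 1) -> np.ndarray:
    f = np.asarray(falls, dtype=float)
    out = np.full(f.shape, None, dtype=object)
    out[f < cut] = f"falls <{cut}"
    out[f >= cut] = f"falls >={cut}"
    return out
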