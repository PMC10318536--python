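"""Time-dependency-avoiding subsample construction and balance checks.

Patients contribute one to three repeated observations; a Rasch
calibration sample must contain at most one observation per patient.
The splitter routes single-observation patients evenly to samples A and
B, one random observation of each two-observation patient to A and the
other to B, and for three-observation patients one random observation to
each of A and B with the leftover segregated into C.  A and B are then
halved into (A1, A2) and (B1, B2); C is flagged excluded when smaller
than the minimum calibration size.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_types import AssessmentRecord

MIN_SAMPLE_SIZE = 250

SUBSAMPLE_LABELS = ("A1", "A2", "B1", "B2", "C")


@dataclass
class SubsampleSplit:
    assignment: dict[tuple[str, int], str]  # (patient_id, obs_index) -> label
    seed: int
    c_excluded: bool

    def members(self, label: str) -> list[tuple[str, int]]:
        return [k for k, v in self.assignment.items() if v == label]

    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {l: 0 for l in SUBSAMPLE_LABELS}
        for v in self.assignment.values():
            out[v] += 1
        return out


def split_time_independent(
    records: list[AssessmentRecord], seed: int, min_size: int = MIN_SAMPLE_SIZE
) -> SubsampleSplit:
    rng = np.random.default_rng(seed)
    by_patient: dict[str, list[int]] = defaultdict(list)
    for r in records:
        by_patient[r.patient_id].append(r.obs_index)
    for pid, obs in by_patient.items():
        if len(obs) > 3:
            raise ValueError(f"patient {pid} has more than 3 observations")
        if len(set(obs)) != len(obs):
            raise ValueError(f"patient {pid} has duplicate observation indices")

    singles = sorted(pid for pid, o in by_patient.items() if len(o) == 1)
    doubles = sorted(pid for pid, o in by_patient.items() if len(o) == 2)
    triples = sorted(pid for pid, o in by_patient.items() if len(o) == 3)

    A: list[tuple[str, int]] = []
    B: list[tuple[str, int]] = []
    C: list[tuple[str, int]] = []

    # singles: forced even split (n//2 to A, remainder to B)
    order = rng.permutation(len(singles))
    half = len(singles) // 2
    for pos, idx in enumerate(order):
        pid = singles[idx]
        (A if pos < half else B).append((pid, by_patient[pid][0]))

    for pid in doubles:
        o = list(by_patient[pid])
        rng.shuffle(o)
        A.append((pid, o[0]))
        B.append((pid, o[1]))

    for pid in triples:
        o = list(by_patient[pid])
        rng.shuffle(o)
        A.append((pid, o[0]))
        B.append((pid, o[1]))
        C.append((pid, o[2]))

    assignment: dict[tuple[str, int], str] = {}

    def halve(sample: list[tuple[str, int]], l1: str, l2: str) -> None:
        order = rng.permutation(len(sample))
        cut = (len(sample) + 1) // 2
        for pos, idx in enumerate(order):
            assignment[sample[idx]] = l1 if pos < cut else l2

    halve(A, "A1", "A2")
    halve(B, "B1", "B2")
    for key in C:
        assignment[key] = "C"

    c_excluded = len(C) < min_size
    if C and c_excluded:
        warnings.warn(
            f"sample C (n={len(C)}) below minimum size {min_size}; "
            "flagged excluded from analysis",
            stacklevel=2,
        )
    return SubsampleSplit(assignment=assignment, seed=seed, c_excluded=c_excluded)


def subsample_records(
    records: list[AssessmentRecord], split: SubsampleSplit, label: str
) -> list[AssessmentRecord]:
    keys = set(split.members(label))
    return [r for r in records if (r.patient_id, r.obs_index) in keys]


def select_one_per_subject(
    records: list[AssessmentRecord], seed: int
) -> list[AssessmentRecord]:
    """One randomly chosen observation per patient (external validity input)."""
    rng = np.random.default_rng(seed)
    by_patient: dict[str, list[AssessmentRecord]] = defaultdict(list)
    for r in records:
        by_patient[r.patient_id].append(r)
    out = []
    for pid in sorted(by_patient):
        obs = by_patient[pid]
        out.append(obs[int(rng.integers(len(obs)))])
    return out


@dataclass
class BalanceRow:
    variable: str
    test: str
    statistic: float
    df: int
    p: float


def balance_check(
    subsamples: dict[str, pd.DataFrame],
    categorical: tuple[str, ...] = ("gender", "course"),
    continuous: tuple[str, ...] = ("age", "duration", "total"),
) -> pd.DataFrame:
    """Chi-square (categorical) / Kruskal-Wallis (continuous) comparisons."""
    if len(subsamples) < 2:
        raise ValueError("need at least two subsamples to compare")
    rows: list[BalanceRow] = []
    for var in categorical:
        tables = []
        for df in subsamples.values():
            if var in df.columns and df[var].notna().any():
                tables.append(df[var].dropna().value_counts())
        if len(tables) < 2:
            warnings.warn(f"variable {var!r} absent; skipped", stacklevel=2)
            continue
        cont = pd.concat(tables, axis=1).fillna(0.0).to_numpy()
        if cont.shape[0] < 2:
            stat, p, dof = 0.0, 1.0, 0
        else:
            stat, p, dof, _ = stats.chi2_contingency(cont)
        rows.append(BalanceRow(var, "chi2", float(stat), int(dof), float(p)))
    for var in continuous:
        groups = [
            df[var].dropna().to_numpy()
            for df in subsamples.values()
            if var in df.columns and df[var].notna().any()
        ]
        if len(groups) < 2:
            warnings.warn(f"variable {var!r} absent; skipped", stacklevel=2)
            continue
        if all(np.array_equal(g, groups[0]) for g in groups[1:]):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.kruskal(*groups)
        rows.append(BalanceRow(var, "kruskal", float(stat), len(groups) - 1, float(p)))
    return pd.DataFrame([r.__dict__ for r in rows])


def select_validation_sample(totals_by_label: dict[str, np.ndarray]) -> str:
    """Label with the widest observed total-score range; ties -> label order."""
    if not totals_by_label:
        raise ValueError("no subsamples given")
    best_label, best_range = None, -1
    for label in sorted(totals_by_label):
        t = np.asarray(totals_by_label[label])
        rng_ = int(t.max() - t.min())
        if rng_ > best_range:
            best_label, best_range = label, rng_
    return best_label
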