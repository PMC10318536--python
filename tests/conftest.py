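"""Shared fixtures.

Heavy simulation studies (calibration/power loops) are session-scoped so
the unit suite and the acceptance suite reuse the same computations.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import raschval.rasch_core as rc
from raschval import synthetic_data as sd
from raschval.cli_report import PipelineConfig, _factor_frame
from raschval.io_types import to_response_matrix
from raschval.rasch_core.pcm import apply_score_maps


def simulate_matrix(n_patients, seed, single_obs=True, **kw):
    """Response matrix + metadata from the synthetic generator."""
    if single_obs:
        kw.setdefault("obs_per_patient_probs", (1.0, 0.0, 0.0))
    cfg = sd.SimulationConfig(n_patients=n_patients, seed=seed, **kw)
    rm = to_response_matrix(sd.simulate_dataset(cfg))
    return rm.values, rm.meta, cfg


def fit_battery(values, n_class_intervals=None):
    """CML fit + person measures + fit report + residual structure."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        params = rc.estimate_item_parameters(values)
        values = apply_score_maps(values, params)
        persons = rc.estimate_person_measures(values, params)
        report = rc.fit_statistics(values, params, persons, n_class_intervals)
        resid = rc.residual_structure(values, params, persons)
    return values, params, persons, report, resid


@pytest.fixture(scope="session")
def small_fit():
    """A single well-specified n=300 sample with its full battery."""
    X, meta, cfg = simulate_matrix(300, seed=12345)
    Xc, params, persons, report, resid = fit_battery(X)
    return {
        "values": Xc, "meta": meta, "config": cfg, "params": params,
        "persons": persons, "report": report, "resid": resid,
    }


@pytest.fixture(scope="session")
def calibration_runs():
    """20 replicates of the full battery on correctly specified data
    (n = 288 persons, one observation each, 5 class intervals)."""
    out = []
    for seed in range(20):
        X, _, _ = simulate_matrix(288, seed=200 + seed)
        _, params, persons, report, resid = fit_battery(X, n_class_intervals=5)
        out.append({"report": report, "resid": resid, "params": params})
    return out


@pytest.fixture(scope="session")
def pst_runs():
    """10 replicates of the unidimensionality t-test at n = 500."""
    out = []
    for seed in range(10):
        X, _, _ = simulate_matrix(500, seed=300 + seed)
        _, params, persons, report, resid = fit_battery(X)
        out.append(resid)
    return out


@pytest.fixture(scope="session")
def ld_runs():
    """10 replicates with strong within-testlet dependence (sd = 1.0)."""
    out = []
    for seed in range(10):
        X, _, _ = simulate_matrix(500, seed=400 + seed, testlet_sd=1.0)
        _, params, persons, report, resid = fit_battery(X)
        out.append(resid)
    return out


@pytest.fixture(scope="session")
def dif_power_runs():
    """10 replicates with 0.5-logit uniform DIF on item 5 at n = 1000."""
    out = []
    for seed in range(10):
        X, meta, _ = simulate_matrix(
            1000, seed=500 + seed,
            dif=sd.DIFSpec(item=5, factor="gender", level="female", shift=0.5),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            params = rc.estimate_item_parameters(X)
            Xc = apply_score_maps(X, params)
            persons = rc.estimate_person_measures(Xc, params)
            rep = rc.dif_analysis(Xc, params, persons, meta[["gender"]])
        out.append(rep)
    return out


@pytest.fixture(scope="session")
def dif_null_runs():
    """10 replicates without DIF, four person factors, n = 500."""
    cfg0 = PipelineConfig()
    out = []
    for seed in range(10):
        X, meta, _ = simulate_matrix(500, seed=600 + seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            params = rc.estimate_item_parameters(X)
            Xc = apply_score_maps(X, params)
            persons = rc.estimate_person_measures(Xc, params)
            factors = _factor_frame(meta, cfg0.dif_factors)
            rep = rc.dif_analysis(Xc, params, persons, factors)
        out.append(rep)
    return out


@pytest.fixture(scope="session")
def recovery_fit():
    """Parameter recovery data: n = 2000, no testlet effect, known truth."""
    X, _, cfg = simulate_matrix(2000, seed=777)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        params = rc.estimate_item_parameters(X)
    return cfg.item_parameters(), params, X


@pytest.fixture(scope="session")
def conditional_chi2_runs():
    """20 replicates of the conditional fit statistic on data simulated
    from a fitted two-testlet PCM (parametric bootstrap: summing raw
    items does not itself produce a PCM super-item, so calibration must
    be judged against the fitted model's own law)."""
    from raschval.rasch_core.pcm import _prob_table

    X, _, _ = simulate_matrix(340, seed=100)
    tl = rc.build_testlet_matrix(X, rc.TestletSpec())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        params = rc.estimate_item_parameters(tl)
        tlc = apply_score_maps(tl, params)
        thetas = rc.theta_array(rc.estimate_person_measures(tlc, params))
    out = []
    for seed in range(20):
        rng = np.random.default_rng(3000 + seed)
        probs = _prob_table(thetas, params)
        Xb = np.zeros((len(thetas), 2), dtype=int)
        for i, p in enumerate(probs):
            Xb[:, i] = (rng.random(len(thetas))[:, None] > p.cumsum(axis=1)).sum(
                axis=1
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out.append(rc.conditional_total_chi2(Xb))
    return out
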