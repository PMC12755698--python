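"""Shared fixtures: small synthetic studies reused across test modules."""

import numpy as np
import pandas as pd
import pytest

import heatsynergy as hs


@pytest.fixture(scope="session")
def small_study():
    """A small end-to-end synthetic study (~500 matched sets), built once.

    Returns a dict with the exposure series, events, cases, untrimmed
    matched-set table, trim threshold and trimmed analysis table.
    """
    dgp = hs.ExposureDGP(n_areas=10)
    hazard = hs.HazardDGP()
    exposures = hs.generate_exposures(dgp, seed=101)
    events = hs.generate_events(exposures, hazard, n_persons=3500, seed=102)
    cases = hs.select_cases(events)
    sets, droplog = hs.build_matched_sets(cases, exposures)
    threshold = hs.compute_trim_threshold(sets["pm25_w"], 0.95)
    analysis, trim_ledger = hs.apply_trim(sets, threshold)
    return {
        "dgp": dgp,
        "hazard": hazard,
        "exposures": exposures,
        "events": events,
        "cases": cases,
        "sets": sets,
        "droplog": droplog,
        "threshold": threshold,
        "analysis": analysis,
        "trim_ledger": trim_ledger,
    }


@pytest.fixture(scope="session")
def random_strata():
    """200 random 3–5-row strata with case rows drawn from the true
    conditional model (softmax over the stratum), plus the truth."""
    rng = np.random.default_rng(7)
    beta = np.array([0.8, -0.5])
    rows, ys, gids = [], [], []
    for s in range(200):
        m = rng.integers(3, 6)
        X = rng.standard_normal((m, 2))
        prob = np.exp(X @ beta)
        prob /= prob.sum()
        case = rng.choice(m, p=prob)
        rows.append(X)
        ys.extend(1 * (np.arange(m) == case))
        gids.extend([s] * m)
    return {
        "X": np.vstack(rows),
        "y": np.array(ys),
        "groups": np.array(gids),
        "beta": beta,
    }


@pytest.fixture()
def tiny_exposures():
    """One area, 30 contiguous days, deterministic values."""
    dates = pd.date_range("2016-06-01", periods=30, freq="D")
    rng = np.random.default_rng(3)
    return pd.DataFrame(
        {
            "area_id": "A000",
            "date": dates,
            "tmax": 25 + 5 * rng.random(30),
            "pm25": np.exp(2.0 + 0.5 * rng.standard_normal(30)),
        }
    )
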