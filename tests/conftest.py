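"""Shared fixtures: small hand-built datasets and a fitted study-design dataset."""
import numpy as np
import pytest
from hypothesis import settings

import coxband as cb

settings.register_profile("suite", deadline=None, max_examples=25,
                          derandomize=True)
settings.load_profile("suite")


def make_sample(times, status, covariates, entry=None):
    """Small-sample constructor: one row per subject."""
    times = np.asarray(times, dtype=float)
    n = times.size
    entry = np.zeros(n) if entry is None else np.asarray(entry, dtype=float)
    return cb.SurvivalSample(np.arange(n), entry, times,
                             np.asarray(status, dtype=int),
                             np.asarray(covariates, dtype=float))


def random_sample(rng, n=20, p=1, tie_prob=0.0):
    """Random small survival dataset (optionally with tied event times)."""
    X = rng.normal(0, 1, (n, p))
    T = rng.exponential(1.0, n) / np.exp(np.clip(X @ np.full(p, 0.5), -30, 30))
    C = rng.exponential(1.5, n)
    time = np.minimum(T, C)
    if tie_prob > 0:
        time = np.ceil(time / 0.25) * 0.25  # grid times force ties
    status = (T <= C).astype(int)
    if status.sum() == 0:
        status[np.argmin(time)] = 1
    return cb.SurvivalSample(np.arange(n), np.zeros(n), time, status, X)


@pytest.fixture(scope="session")
def design_data():
    """One n=200 dataset from the simulation design, with its fit."""
    sc = cb.SimulationScenario(n=200)
    data = cb.generate_dataset(sc, np.random.default_rng(1234))
    fit = cb.fit_beta(data)
    return data, fit


@pytest.fixture(scope="session")
def design_ensemble(design_data):
    """A B=500 estimating-equation ensemble on the design dataset."""
    data, fit = design_data
    ens = cb.run_ensemble(data, fit, 500, cb.MultiplierSpec("normal", 99),
                          approach="score", increments="dN")
    return data, fit, ens


@pytest.fixture()
def hand2():
    """Two subjects, zero covariates: events at t=1 and t=2."""
    return make_sample([1.0, 2.0], [1, 1], [[0.0], [0.0]])
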