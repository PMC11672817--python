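"""Shared fixtures and independent oracles for the test suite."""

import sys
from functools import lru_cache

import numpy as np
import pandas as pd
import pytest

import daysopen as d


# ---------------------------------------------------------------- oracles

def oracle_A(sire, dam):
    """Dense numerator relationship matrix via memoized pairwise recursion.

    Independent of the package's iterative tabular loop: computes a(i, j)
    top-down from the classic recurrences.
    """
    sire = np.asarray(sire)
    dam = np.asarray(dam)
    n = len(sire) - 1
    sys.setrecursionlimit(max(10000, 50 * n))

    @lru_cache(maxsize=None)
    def a(i, j):
        if i == 0 or j == 0:
            return 0.0
        if i == j:
            return 1.0 + 0.5 * a(sire[i], dam[i])
        hi, lo = (i, j) if i > j else (j, i)
        return 0.5 * (a(sire[hi], lo) + a(dam[hi], lo))

    A = np.empty((n, n))
    for i in range(1, n + 1):
        for j in range(1, i + 1):
            A[i - 1, j - 1] = A[j - 1, i - 1] = a(i, j)
    return A


def random_pedigree_triples(rng, n, p_founder=0.25):
    """Random acyclic pedigree: parents always have smaller ids."""
    triples = []
    for i in range(1, n + 1):
        if i <= 2 or rng.random() < p_founder:
            triples.append((i, 0, 0))
        else:
            s = int(rng.integers(1, i))
            dm = int(rng.integers(1, i))
            if dm == s:
                dm = 0
            triples.append((i, s, dm))
    return triples


def mc_se(x):
    """Monte-Carlo SE of a chain mean (Geyer initial-positive-sequence)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    xc = x - x.mean()
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(xc, m)
    acov = np.fft.irfft(f * np.conj(f), m)[:n].real / n
    s = -acov[0]
    k = 0
    while k + 1 < min(n, 5000):
        pair = acov[k] + acov[k + 1]
        if pair <= 0:
            break
        s += 2 * pair
        k += 2
    return np.sqrt(max(s, acov[0]) / n)


def gibbs_vs_mme_z(seed, n_founders, n_iter=50_000):
    """Standardized deviations of fixed-variance Gibbs means from BLUP.

    Each z is a pivotal N(0,1) statistic when the sampler is correct.
    """
    cfg = d.SimulationConfig(seed=seed, n_founders=n_founders, n_generations=3)
    ped, rec, _ = d.simulate_dataset(cfg)
    edited, _ = d.edit_records(rec)
    design = d.build_design(edited, ped)
    vc = d.VarianceComponents(437.64, 705.76, 11932.0)
    sol = d.solve_mme(design, vc)
    chain = d.gibbs_gaussian(
        design,
        d.ChainConfig(n_iter=n_iter, burn_in=2000, thin=1, seed=seed),
        fixed_variances=vc,
        store_effect_draws=True,
    )
    draws = chain.extras["effect_draws"]
    se = np.array([mc_se(draws[:, j]) for j in range(draws.shape[1])])
    return np.abs(draws.mean(axis=0) - sol.stacked) / np.maximum(se, 1e-12)


@pytest.fixture(scope="session")
def make_random_pedigree():
    def _make(seed, n):
        rng = np.random.default_rng(seed)
        return d.from_triples(random_pedigree_triples(rng, n))
    return _make


# ------------------------------------------------------- simulated datasets

@pytest.fixture(scope="session")
def small_sim():
    """Small but structured dataset: ~600 animals, ~300 records."""
    cfg = d.SimulationConfig(seed=42, n_founders=200, n_generations=3)
    ped, records, truth = d.simulate_dataset(cfg)
    edited, report = d.edit_records(records)
    return {"config": cfg, "ped": ped, "records": records,
            "truth": truth, "edited": edited, "report": report}


@pytest.fixture(scope="session")
def tiny_sim():
    """Very small dataset for fast end-to-end fits."""
    cfg = d.SimulationConfig(seed=7, n_founders=120, n_generations=3)
    ped, records, truth = d.simulate_dataset(cfg)
    edited, _ = d.edit_records(records)
    return {"config": cfg, "ped": ped, "records": records,
            "truth": truth, "edited": edited}


@pytest.fixture
def short_chain():
    return d.ChainConfig(n_iter=3000, burn_in=800, thin=5, seed=123)


def uncensor(records: pd.DataFrame) -> pd.DataFrame:
    """Force every record to be uncensored (conception observed)."""
    out = records.copy()
    out["censored"] = False
    out["conception_date"] = out["calving_date"] + pd.to_timedelta(out["do"], unit="D")
    return out
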