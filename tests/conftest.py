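"""Shared fixtures and independent oracles.

The oracles here (dense tabular relationship matrix, brute-force checks)
are deliberately written from first principles so they stay independent of
the package's sparse/recursive implementations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest


def tabular_A(sire, dam):
    """Dense numerator relationship matrix by the recursive tabular method.

    ``sire``/``dam`` are positional indices with -1 unknown, parents first.
    """
    n = len(sire)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
        for j in range(i):
            a = 0.0
            if s >= 0:
                a += 0.5 * A[j, s]
            if d >= 0:
                a += 0.5 * A[j, d]
            A[i, j] = A[j, i] = a
    return A


def random_pedigree_frame(rng, n, n_founders=None, p_missing=0.15):
    """Random valid pedigree DataFrame (ids 1..n, parents precede)."""
    n_founders = n_founders or max(3, n // 4)
    sire = np.full(n, -1)
    dam = np.full(n, -1)
    for i in range(n_founders, n):
        if rng.random() > p_missing:
            sire[i] = int(rng.integers(0, i))
        if rng.random() > p_missing:
            dam[i] = int(rng.integers(0, i))
        if sire[i] == dam[i]:
            dam[i] = -1
    return pd.DataFrame({
        "animal": np.arange(1, n + 1),
        "sire": np.where(sire >= 0, sire + 1, 0),
        "dam": np.where(dam >= 0, dam + 1, 0),
    }), sire, dam


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def trio_pedigree():
    return pd.DataFrame({"animal": [1, 2, 3], "sire": [0, 0, 1],
                         "dam": [0, 0, 2]})


@pytest.fixture(scope="session")
def small_herd():
    from plevaluate import simdata
    cfg = simdata.SimConfig(n_founders_per_breed=30, n_generations=3, seed=3,
                            start_year=1995, data_end_year=2020,
                            genotyping_fraction=0.5, n_snps=120)
    return simdata.generate(cfg)


@pytest.fixture(scope="session")
def recovery_herd():
    """Mid-sized Gaussian herd for sampler checks (~420 cows)."""
    from plevaluate import relmat, simdata
    cfg = simdata.SimConfig(n_founders_per_breed=150, n_generations=3,
                            seed=11, start_year=1995, data_end_year=2020)
    ped = simdata.simulate_pedigree(cfg)
    cows = ped[(ped["sex"] == "F") & (ped["generation"] > 0)]["animal"]
    cg = simdata.make_cg_map(ped, cows, 36)
    rec, truth = simdata.simulate_rep_phenotypes(ped, cg, seed=5)
    _, ainv, codes = relmat.compute_inbreeding_and_A_inverse(ped)
    return {"pedigree": ped, "records": rec, "truth": truth,
            "a_inv": ainv, "codes": codes}
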