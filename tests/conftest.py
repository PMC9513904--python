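"""Shared fixtures: hand-built micro pedigrees, a pure-genomic dataset where
GBLUP and SNP-BLUP are exactly equivalent, and simulated populations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ipacc.genomic import AlleleFrequencySet, GenotypeMatrix
from ipacc.pedigree import Pedigree
from ipacc.simulate import SimulationConfig, simulate


@pytest.fixture
def trio_ped() -> Pedigree:
    """Two founders and their offspring."""
    return Pedigree([("1", "0", "0"), ("2", "0", "0"), ("3", "1", "2")])


@pytest.fixture
def micro4_ped() -> Pedigree:
    """Founders 1, 2; 3 = 1 x 2; 4 = 1 x 3 (parent-offspring mating)."""
    return Pedigree([("1", "0", "0"), ("2", "0", "0"), ("3", "1", "2"), ("4", "1", "3")])


def random_pedigree(n: int, seed: int, n_founders: int = 10) -> Pedigree:
    """Random valid pedigree: parents drawn from earlier animals or unknown."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(1, n + 1):
        if i <= n_founders:
            records.append((str(i), "0", "0"))
            continue
        s, d = rng.choice(i - 1, size=2, replace=False) + 1
        if rng.random() < 0.1:
            s = 0
        if rng.random() < 0.1:
            d = 0
        records.append((str(i), str(s), str(d)))
    return Pedigree(records)


@pytest.fixture(scope="session")
def pure_genomic():
    """Founders-only pedigree, every animal genotyped, training phenotyped.

    Centered with the base (founder) allele frequencies so Z has full row
    rank and G0 = ZZ'/k is invertible: the setting where the unblended
    ssGBLUP collapses to GBLUP and is exactly equivalent to SNP-BLUP.
    """
    rng = np.random.default_rng(42)
    n_tr, n_val, m = 120, 30, 400
    n = n_tr + n_val
    ids = [str(i + 1) for i in range(n)]
    ped = Pedigree([(a, "0", "0") for a in ids])
    p0 = rng.uniform(0.1, 0.9, m)
    M = rng.binomial(2, p0, size=(n, m)).astype(np.int8)
    gm = GenotypeMatrix(M, ids)
    freqs = AlleleFrequencySet(p0, float(2 * np.sum(p0 * (1 - p0))))
    sigma2_u, sigma2_e = 0.4, 0.6
    a_true = rng.normal(0, np.sqrt(sigma2_u / freqs.k), m)
    u = (M - 2 * p0) @ a_true
    y = u + rng.normal(0, np.sqrt(sigma2_e), n)
    phen = pd.DataFrame(
        {"animal": ids[:n_tr], "cg": ["c%d" % (i % 3) for i in range(n_tr)], "value": y[:n_tr]}
    )
    return {
        "ped": ped,
        "gm": gm,
        "freqs": freqs,
        "phen": phen,
        "ids": ids,
        "n_tr": n_tr,
        "sigma2_u": sigma2_u,
        "sigma2_e": sigma2_e,
        "u_true": u,
    }


SMALL_CFG = dict(
    n_founders=60,
    generation_sizes=(150, 150, 150, 120),
    m=300,
    genotyping_prob=(0.5, 0.85, 0.95, 0.95, 0.45),
)


@pytest.fixture(scope="session")
def small_sim():
    """Small simulated population (~630 animals) for fast end-to-end tests."""
    return simulate(SimulationConfig(seed=7, **SMALL_CFG))


@pytest.fixture(scope="session")
def standard_benchmark():
    """The standard synthetic benchmark used by the acceptance checks."""
    return simulate(SimulationConfig(seed=1))
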