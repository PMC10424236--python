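"""Shared fixtures.

The expensive fixture is the two-charged-bead umbrella run: two isolated
-2 e beads interacting by the bare CG Coulomb term, sampled over the
full 2-7 nm window ladder.  For two isolated particles the distance-
resolved free energy has the closed form U(r) - 2 kT ln r + const, so
this run is the end-to-end oracle shared by the WHAM and acceptance
tests.  It is session-scoped and computed once.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

import dnapmf
from dnapmf.config import preset
from dnapmf.pipeline import sample_all_windows
from dnapmf.constants import kT
from dnapmf.simulate import UmbrellaWindow, WindowRecord


TWO_BEAD_SEED = 20_240_901


def harmonic_windows(a=100.0, k=400.0, centers=np.arange(-1.0, 1.01, 0.1),
                     n=20_000, seed=0):
    """Exact Gaussian umbrella samples over U(x) = a x^2 / 2, shifted to
    positive x by +5 so the reaction coordinate stays physical.

    With bias k (x - c)^2 / 2 the biased density is Gaussian with mean
    k c / (a + k) and variance kT / (a + k), so the windows can be drawn
    exactly — an oracle fully independent of the Monte Carlo sampler.
    """
    rng = np.random.default_rng(seed)
    kt = kT(300.0)
    records = []
    for c in centers:
        mean = k * c / (a + k)
        sd = math.sqrt(kt / (a + k))
        x = rng.normal(mean, sd, n)
        records.append(WindowRecord(UmbrellaWindow(5.0 + c, k), 5.0 + x))
    return records


def two_bead_config():
    cfg = preset("two-bead-oracle")
    cfg.sampling.seed = TWO_BEAD_SEED
    return cfg.validate()


def two_bead_expected_pmf(r, reference_r, ff):
    """Closed-form expectation: pair energy plus the radial-measure term.

    The distance-coordinate profile of two isolated particles is
    ``U(r) - 2 kT ln(r / r_ref)`` referenced to zero at ``r_ref``; no
    radial-entropy correction is applied by the WHAM layer, so the
    measure term is part of the expected result.
    """
    r = np.asarray(r, dtype=float)
    u = np.array([dnapmf.simulate.coulomb_pair_energy(x, -2.0, -2.0, ff)
                  for x in r])
    u_ref = dnapmf.simulate.coulomb_pair_energy(reference_r, -2.0, -2.0, ff)
    return u - u_ref - 2.0 * ff.kT * np.log(r / reference_r)


@pytest.fixture(scope="session")
def two_bead_records():
    cfg = two_bead_config()
    return cfg, sample_all_windows(cfg)


@pytest.fixture(scope="session")
def l24na_state():
    """Assembled L24Na box: 24-bp rod pair, 295 Na+, 203 Cl-, 15 nm box."""
    box = dnapmf.SimulationBox(15.0)
    mol = dnapmf.build_linear_duplex_model(24)
    inv = dnapmf.compose_ion_inventory(2 * mol.total_charge, 1, 0.1, box)
    return dnapmf.place_pair_and_ions(mol, mol, inv, box, 2.0, seed=7)
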