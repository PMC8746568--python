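"""Shared fixtures: the packaged adduct-ion table, rule closures, and an
independent brute-force formula-enumeration oracle built on a dense numpy
grid over the full element lattice."""

from __future__ import annotations

import numpy as np
import pytest

from dissmet.annotate import ClosureIndex
from dissmet.chem import Formula
from dissmet.inference import default_rules, rule_closure
from dissmet.simulate import load_table1_fixture

PARENT = Formula.parse("C34H42O19")


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def rules():
    return default_rules()


@pytest.fixture(scope="session")
def closure8(rules):
    return rule_closure(PARENT, rules, 8)


@pytest.fixture(scope="session")
def closure_index(closure8):
    return ClosureIndex(closure8)


class BruteForceEnumerator:
    """Independent oracle: dense masses over the full bounded C/H/N/O/S grid.

    Deliberately implemented as array arithmetic over every lattice point
    (no pruning, no search) so it shares no code path with the package's
    enumerator.
    """

    M = {"C": 12.0, "H": 1.0078250319, "N": 14.0030740052,
         "O": 15.9949146221, "S": 31.97207069}

    def __init__(self, c=50, h=100, n=5, o=50, s=5):
        C = np.arange(c + 1)
        H = np.arange(h + 1)
        N = np.arange(n + 1)
        O = np.arange(o + 1)
        S = np.arange(s + 1)
        self.shape = (len(C), len(H), len(N), len(O), len(S))
        self.masses = (
            self.M["C"] * C[:, None, None, None, None]
            + self.M["H"] * H[None, :, None, None, None]
            + self.M["N"] * N[None, None, :, None, None]
            + self.M["O"] * O[None, None, None, :, None]
            + self.M["S"] * S[None, None, None, None, :]
        )
        self.rdb = (
            C[:, None, None, None, None].astype(float)
            + 1.0
            - H[None, :, None, None, None] / 2.0
            + N[None, None, :, None, None] / 2.0
            + 0.0 * O[None, None, None, :, None]
            + 0.0 * S[None, None, None, None, :]
        )

    def enumerate(self, target, tol_ppm=5.0, rdb_min=0.0, rdb_max=15.0):
        """Set of (C, H, N, O, S) tuples with mass within tolerance."""
        window = target * tol_ppm * 1e-6
        mask = (np.abs(self.masses - target) <= window) & \
               (self.rdb >= rdb_min) & (self.rdb <= rdb_max)
        return {tuple(int(v) for v in idx) for idx in np.argwhere(mask)}


@pytest.fixture(scope="session")
def brute():
    return BruteForceEnumerator()


@pytest.fixture(scope="session")
def random_masses():
    rng = np.random.default_rng(20211225)
    return [float(m) for m in rng.uniform(50.0, 800.0, size=50)]
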