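"""Shared fixtures: molecule sets, MOL blocks, synthetic tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from qsartox.graph import parse_smiles
from qsartox.synthetic import SyntheticSpec, generate_table
from qsartox.table import DescriptorTable

# 15 small molecules covering chains, branches, rings, aromatics and the
# functional groups the group-count rules target
MOLECULES = {
    "ethane": "CC",
    "propane": "CCC",
    "n-butane": "CCCC",
    "isobutane": "CC(C)C",
    "n-pentane": "CCCCC",
    "neopentane": "CC(C)(C)C",
    "cyclopropane": "C1CC1",
    "cyclohexane": "C1CCCCC1",
    "benzene": "c1ccccc1",
    "toluene": "Cc1ccccc1",
    "phenol": "Oc1ccccc1",
    "aniline": "Nc1ccccc1",
    "benzonitrile": "N#Cc1ccccc1",
    "4-nitroaniline": "Nc1ccc(cc1)[N+](=O)[O-]",
    "2,4,6-trichlorophenol": "Oc1c(Cl)cc(Cl)cc1Cl",
}

ETHANE_MOL = """ethane
  test

  2  1  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.5000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0  0  0  0
M  END
"""

BENZENE_MOL = """benzene
  test

  6  6  0  0  0  0  0  0  0  0999 V2000
    1.2124    0.7000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.2124   -0.7000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000   -1.4000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.2124   -0.7000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.2124    0.7000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    1.4000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  2  0  0  0  0
  2  3  1  0  0  0  0
  3  4  2  0  0  0  0
  4  5  1  0  0  0  0
  5  6  2  0  0  0  0
  6  1  1  0  0  0  0
M  END
"""

PHENOL_MOL = """phenol
  test

  7  7  0  0  0  0  0  0  0  0999 V2000
    1.2124    0.7000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.2124   -0.7000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000   -1.4000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.2124   -0.7000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -1.2124    0.7000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    1.4000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.0000    2.8000    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  2  0  0  0  0
  2  3  1  0  0  0  0
  3  4  2  0  0  0  0
  4  5  1  0  0  0  0
  5  6  2  0  0  0  0
  6  1  1  0  0  0  0
  6  7  1  0  0  0  0
M  END
"""

BAD_BOND_MOL = """broken
  test

  2  1  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    1.5000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
  0  2  1  0  0  0  0
M  END
"""

SALT_MOL = """salt
  test

  2  0  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
M  END
"""


@pytest.fixture(scope="session")
def molecules():
    return {name: parse_smiles(smi) for name, smi in MOLECULES.items()}


@pytest.fixture(scope="session")
def planted_table():
    """n=500 table: 3 informative, 3 exact duplicates, 14 noise columns."""
    spec = SyntheticSpec(
        n=500,
        n_informative=3,
        n_redundant=3,
        n_noise=14,
        coefficients=(1.0, 0.8, 0.6),
        sigma_redundant=0.0,
        sigma=0.3,
        seed=42,
    )
    table, truth = generate_table(spec)
    return table, truth


@pytest.fixture(scope="session")
def small_table():
    """Small regression table for CV/grid tests (fast to fit)."""
    rng = np.random.default_rng(11)
    n = 60
    X = rng.normal(size=(n, 4))
    y = X @ np.array([1.0, -0.5, 0.0, 0.0]) + 0.05 * rng.normal(size=n)
    return DescriptorTable(
        ids=[f"c{i}" for i in range(n)],
        X=pd.DataFrame(X, columns=["a", "b", "c", "d"]),
        y=pd.Series(y, name="logIGC50inv"),
    )


@pytest.fixture(scope="session", autouse=True)
def _warm_solver():
    """Compile the jitted SMO loop once so timings are stable."""
    from qsartox.svr import KernelSpec, train_svr

    rng = np.random.default_rng(0)
    X = rng.normal(size=(12, 2))
    y = rng.normal(size=12)
    train_svr(X, y, KernelSpec("linear"), C=1.0, epsilon=0.1)
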