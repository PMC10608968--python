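"""Shared fixtures and an independent residue-sum mass oracle.

The oracle duplicates the standard monoisotopic residue masses locally
so fragment/mass tests do not depend on the package's own table.
"""

from __future__ import annotations

import numpy as np
import pytest

from ranapep.chem import CTerminus, Peptide

ORACLE_MASSES = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "J": 113.08406, "N": 114.04293, "D": 115.02694,
    "Q": 128.05858, "K": 128.09496, "E": 129.04259, "M": 131.04049,
    "H": 137.05891, "F": 147.06841, "R": 156.10111, "Y": 163.06333,
    "W": 186.07931,
}
ORACLE_WATER = 18.010565
ORACLE_PROTON = 1.0072765
ORACLE_AMIDE = -0.98402
ORACLE_SS = -2.01565


def oracle_mass(seq: str, amide: bool = False, n_disulfides: int = 0) -> float:
    """Brute-force neutral monoisotopic mass from first principles."""
    return (sum(ORACLE_MASSES[c] for c in seq) + ORACLE_WATER
            + (ORACLE_AMIDE if amide else 0.0) + ORACLE_SS * n_disulfides)


def oracle_prefix(seq: str, i: int) -> float:
    return sum(ORACLE_MASSES[c] for c in seq[:i])


def oracle_suffix(seq: str, j: int) -> float:
    return sum(ORACLE_MASSES[c] for c in seq[len(seq) - j:])


@pytest.fixture(scope="session")
def bradykinin() -> Peptide:
    return Peptide("RPPGFSPFR", name="bradykinin")


@pytest.fixture(scope="session")
def temporin_a() -> Peptide:
    return Peptide("FLPLIGRVLSGIL", CTerminus.AMIDE, name="temporin A")


@pytest.fixture(scope="session")
def temporin_1da() -> Peptide:
    return Peptide("FLPLIAGLLGKLF", CTerminus.AMIDE, name="temporin 1Da")


@pytest.fixture(scope="session")
def brevinin_1da() -> Peptide:
    return Peptide("IIPLLLGKVVCAITKKC", disulfides=((11, 17),),
                   name="brevinin 1Da")


@pytest.fixture(scope="session")
def brevinin_1db() -> Peptide:
    return Peptide("FFPAFLKVAAKVVPSILCSITKKC", disulfides=((18, 24),),
                   name="brevinin 1Db")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20230716)
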