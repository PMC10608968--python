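"""Monoisotopic peptide mass arithmetic.

Ground truth for everything downstream: residue masses, terminal and
disulfide modifications, charge-state and isotopologue m/z, and ppm
errors.  All masses are monoisotopic and in daltons.

Conventions
-----------
* Residue positions are 1-based, matching the superscript notation used
  for frog peptides (e.g. ``Leu^6``).
* ``'J'`` is the Leu-or-Ile placeholder: it carries the shared Leu/Ile
  residue mass so a peptide's mass is computable before the isomer is
  resolved by EThcD w-ion evidence.
* C-terminal amidation replaces the free acid -OH with -NH2
  (delta -0.98402 Da); each intramolecular disulfide bond removes two
  hydrogens (delta -2.01565 Da).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from types import MappingProxyType
from typing import Iterable, Mapping, TextIO

__all__ = [
    "RESIDUE_MASSES",
    "WATER",
    "PROTON",
    "ISOTOPE_SPACING",
    "AMIDE_DELTA",
    "DISULFIDE_DELTA",
    "CTerminus",
    "MassDelta",
    "Peptide",
    "peptide_mono_mass",
    "ion_mz",
    "isotopologue_mz",
    "ppm_error",
    "read_peptide_table",
    "write_peptide_table",
    "read_peptide_fasta",
]

#: Monoisotopic residue (amino-acid minus water) masses, Da.
RESIDUE_MASSES: Mapping[str, float] = MappingProxyType({
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "J": 113.08406, "N": 114.04293, "D": 115.02694,
    "Q": 128.05858, "K": 128.09496, "E": 129.04259, "M": 131.04049,
    "H": 137.05891, "F": 147.06841, "R": 156.10111, "Y": 163.06333,
    "W": 186.07931,
})

WATER = 18.010565
PROTON = 1.0072765
ISOTOPE_SPACING = 1.0033548  # C13 - C12
AMIDE_DELTA = -0.98402       # -OH -> -NH2
DISULFIDE_DELTA = -2.01565   # loss of 2 H per S-S bond


class CTerminus(str, Enum):
    FREE_ACID = "free_acid"
    AMIDE = "amide"


class DeltaScope(str, Enum):
    PER_PEPTIDE = "per_peptide"
    PER_BOND = "per_bond"
    PER_ION = "per_ion"


@dataclass(frozen=True)
class MassDelta:
    """A named signed mass shift with the scope it applies at."""

    name: str
    delta: float
    scope: DeltaScope


#: Registry of the modification deltas the mass model uses.
MASS_DELTAS: Mapping[str, MassDelta] = MappingProxyType({
    "amide": MassDelta("amide", AMIDE_DELTA, DeltaScope.PER_PEPTIDE),
    "disulfide": MassDelta("disulfide", DISULFIDE_DELTA, DeltaScope.PER_BOND),
})


@dataclass(frozen=True)
class Peptide:
    """A peptide with terminal state, disulfide bonds and L/I ambiguity.

    Parameters
    ----------
    sequence:
        One-letter residue codes; ``'J'`` marks an unresolved Leu/Ile.
    c_terminus:
        Free acid (``-OH``) or amide (``-NH2``).
    disulfides:
        Intramolecular S-S bonds as 1-based ``(i, j)`` Cys position
        pairs with ``i < j``.
    name:
        Optional label carried through reports.
    """

    sequence: str
    c_terminus: CTerminus = CTerminus.FREE_ACID
    disulfides: tuple[tuple[int, int], ...] = ()
    name: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        for pos, code in enumerate(self.sequence, start=1):
            if code not in RESIDUE_MASSES:
                raise ValueError(
                    f"unknown residue code {code!r} at position {pos}"
                )
        object.__setattr__(self, "disulfides",
                           tuple(tuple(b) for b in self.disulfides))
        seen: set[int] = set()
        n = len(self.sequence)
        for i, j in self.disulfides:
            if not (1 <= i < j <= n):
                raise ValueError(f"disulfide ({i},{j}) out of range for length {n}")
            for p in (i, j):
                if self.sequence[p - 1] != "C":
                    raise ValueError(f"disulfide position {p} is not Cys")
                if p in seen:
                    raise ValueError(f"position {p} appears in two disulfide pairs")
                seen.add(p)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def ambiguous_positions(self) -> frozenset[int]:
        """1-based positions where 'J' stands for unresolved Leu/Ile."""
        return frozenset(i for i, c in enumerate(self.sequence, 1) if c == "J")

    @property
    def amidated(self) -> bool:
        return self.c_terminus is CTerminus.AMIDE

    def residue_mass(self, pos: int) -> float:
        return RESIDUE_MASSES[self.sequence[pos - 1]]


def peptide_mono_mass(p: Peptide) -> float:
    """Neutral monoisotopic mass of a peptide, Da.

    Sum of residue masses plus water, plus the amide delta when the
    C-terminus is amidated, minus 2.01565 Da per disulfide bond.
    """
    mass = sum(RESIDUE_MASSES[c] for c in p.sequence) + WATER
    if p.amidated:
        mass += AMIDE_DELTA
    mass += DISULFIDE_DELTA * len(p.disulfides)
    return mass


def ion_mz(mass: float, charge: int) -> float:
    """m/z of the ``charge``-fold protonated species of a neutral mass."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (mass + charge * PROTON) / charge


def isotopologue_mz(mass: float, charge: int, k: int = 0) -> float:
    """m/z of the k-th isotopologue (k extra neutrons) of a protonated ion.

    ``k=0`` is the monoisotopic peak; successive isotopologues are spaced
    by one C13-C12 mass difference divided by the charge.
    """
    if k < 0:
        raise ValueError(f"isotopologue index must be >= 0, got {k}")
    return ion_mz(mass, charge) + k * ISOTOPE_SPACING / charge


def ppm_error(experimental: float, theoretical: float) -> float:
    """Absolute relative mass deviation in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical mass must be positive")
    return abs(experimental - theoretical) / theoretical * 1e6


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties away from zero (report-formatting convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Tabular / FASTA-like peptide I/O

TABLE_COLUMNS = ("name", "sequence", "c_term", "disulfides", "exp_mass")


def _parse_disulfides(text: str) -> tuple[tuple[int, int], ...]:
    text = text.strip()
    if not text or text == "-":
        return ()
    bonds = []
    for part in text.split(";"):
        i, j = part.split("-")
        bonds.append((int(i), int(j)))
    return tuple(bonds)


def _format_disulfides(bonds: Iterable[tuple[int, int]]) -> str:
    return ";".join(f"{i}-{j}" for i, j in bonds) or "-"


def read_peptide_table(stream: TextIO | str) -> list[tuple[Peptide, float | None]]:
    """Read a tab-separated peptide table.

    Columns: name, sequence, c_term (``free_acid``/``amide``), disulfides
    (``i-j;k-l`` or ``-``), exp_mass (may be empty).  A header line is
    recognised and skipped.  Returns ``(Peptide, experimental_mass)``
    pairs; the mass is ``None`` when absent.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    out: list[tuple[Peptide, float | None]] = []
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0] == "name":  # header
            continue
        if len(fields) < 4:
            raise ValueError(f"line {lineno}: expected >=4 tab-separated fields")
        name, seq, c_term = fields[0], fields[1], fields[2]
        bonds = _parse_disulfides(fields[3])
        exp = float(fields[4]) if len(fields) > 4 and fields[4].strip() else None
        pep = Peptide(seq, CTerminus(c_term), bonds, name=name)
        out.append((pep, exp))
    return out


def write_peptide_table(entries: Iterable[tuple[Peptide, float | None]],
                        stream: TextIO) -> None:
    stream.write("\t".join(TABLE_COLUMNS) + "\n")
    for pep, exp in entries:
        stream.write("\t".join([
            pep.name, pep.sequence, pep.c_terminus.value,
            _format_disulfides(pep.disulfides),
            "" if exp is None else f"{exp:.3f}",
        ]) + "\n")


def read_peptide_fasta(stream: TextIO | str) -> list[Peptide]:
    """Read peptides from FASTA with ``[amide]`` / ``[ss=i-j]`` header tags.

    Example header: ``>brevinin_1Da [ss=11-17]``.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    peptides: list[Peptide] = []
    name, tags, chunks = None, "", []

    def flush() -> None:
        if name is None:
            return
        seq = "".join(chunks)
        amide = "[amide]" in tags
        bonds = []
        for token in tags.split():
            if token.startswith("[ss=") and token.endswith("]"):
                bonds.extend(_parse_disulfides(token[4:-1].replace(",", ";")))
        peptides.append(Peptide(seq, CTerminus.AMIDE if amide else
                                CTerminus.FREE_ACID, tuple(bonds), name=name))

    for line in stream:
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            header = line[1:].strip()
            parts = header.split(None, 1)
            name = parts[0]
            tags = parts[1] if len(parts) > 1 else ""
            chunks = []
        else:
            chunks.append(line)
    flush()
    return peptides
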