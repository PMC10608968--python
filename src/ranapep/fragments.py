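"""Fragment-ion prediction for CID/HCD/ETD/EThcD spectra.

Predicts backbone b/y (collisional) and c/z-dot (electron-transfer)
series, a-ions, secondary Lys-loss satellites of y-ions, and the
side-chain radical-loss w-ions that distinguish Leu from Ile, while
honouring the visibility constraint imposed by intact intramolecular
disulfide bonds (a single backbone cleavage inside an S-S loop cannot
separate the two pieces, so those ions are not observed unless the bond
is first opened, e.g. by ETD).

z ions are modelled as the radical z-dot species (y - NH2,
16.018724 Da); the even-electron z+1 form can be enabled per call.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Sequence

from .chem import (AMIDE_DELTA, DISULFIDE_DELTA, PROTON, RESIDUE_MASSES,
                   WATER, Peptide)

__all__ = [
    "CO", "NH3", "NH2", "LYS_RESIDUE", "W_LOSS",
    "Activation", "FragmentationMode", "FragmentIon",
    "CID", "HCD", "ETD", "ETHCD",
    "backbone_ions", "disulfide_visibility", "open_disulfide_ions",
    "satellite_losses", "w_ions",
]

CO = 27.994915    # b -> a
NH3 = 17.026549   # b -> c
NH2 = 16.018724   # y -> z-dot
H = 1.0078250
LYS_RESIDUE = 128.09496

#: side-chain radical losses from z-dot ions: isopropyl marks Leu,
#: ethyl marks Ile.
W_LOSS = {"L": 43.05478, "I": 29.03913}


class Activation(str, Enum):
    CID = "CID"
    HCD = "HCD"
    ETD = "ETD"
    ETHCD = "EThcD"


@dataclass(frozen=True)
class FragmentationMode:
    """Which ion series an activation method produces."""

    name: Activation
    series: frozenset[str]
    satellite_losses_enabled: bool = False
    w_ions_enabled: bool = False

    def __post_init__(self) -> None:
        allowed = {"a", "b", "y", "c", "z"}
        bad = self.series - allowed
        if bad:
            raise ValueError(f"unknown ion series: {sorted(bad)}")
        if self.w_ions_enabled and "z" not in self.series:
            raise ValueError("w ions require the z-dot series")


CID = FragmentationMode(Activation.CID, frozenset({"b", "y"}),
                        satellite_losses_enabled=True)
HCD = FragmentationMode(Activation.HCD, frozenset({"b", "y"}),
                        satellite_losses_enabled=True)
ETD = FragmentationMode(Activation.ETD, frozenset({"c", "z"}),
                        w_ions_enabled=True)
ETHCD = FragmentationMode(Activation.ETHCD, frozenset({"b", "y", "c", "z"}),
                          satellite_losses_enabled=True, w_ions_enabled=True)

MODES = {m.name.value: m for m in (CID, HCD, ETD, ETHCD)}

_PREFIX_SERIES = ("a", "b", "c")
_SUFFIX_SERIES = ("y", "z", "w")


@dataclass(frozen=True)
class FragmentIon:
    """A predicted fragment ion and its provenance.

    ``index`` is the 1-based cleavage ordinal counted from the series'
    own terminus (N for a/b/c, C for y/z/w).  ``visible`` is False when
    the cleavage lies inside an intact disulfide loop.  ``hypothesis``
    tags w-ions generated for an unresolved 'J' position with the
    Leu/Ile hypothesis they test.
    """

    series: str
    index: int
    charge: int
    mz: float
    visible: bool = True
    neutral_loss: str | None = None
    source_positions: tuple[int, int] = (0, 0)
    hypothesis: str | None = None

    @property
    def label(self) -> str:
        loss = f"-{self.neutral_loss}" if self.neutral_loss else ""
        chg = f"^{self.charge}+" if self.charge > 1 else ""
        hyp = f"({self.hypothesis})" if self.hypothesis else ""
        return f"{self.series}{self.index}{loss}{hyp}{chg}"

    @property
    def cleavage_site(self) -> int:
        """The backbone cleavage ordinal from the N-terminus."""
        start, end = self.source_positions
        if self.series in _PREFIX_SERIES:
            return end
        return start - 1


def _span_mass(p: Peptide, start: int, end: int) -> float:
    """Residue-sum mass of positions start..end (1-based, inclusive),
    including the delta of every disulfide bond fully inside the span."""
    mass = sum(p.residue_mass(i) for i in range(start, end + 1))
    for i, j in p.disulfides:
        if start <= i and j <= end:
            mass += DISULFIDE_DELTA
    return mass


def _site_in_intact_loop(p: Peptide, site: int) -> bool:
    return any(i <= site < j for i, j in p.disulfides)


def disulfide_visibility(p: Peptide, ion: FragmentIon) -> bool:
    """False when the ion's cleavage site lies strictly between the two
    Cys of an intact disulfide: the fragments remain tethered and the
    nominal ion cannot appear in the spectrum."""
    return not _site_in_intact_loop(p, ion.cleavage_site)


def _neutral_fragment_mass(p: Peptide, series: str, index: int) -> tuple[float, tuple[int, int]]:
    n = len(p)
    if series in _PREFIX_SERIES:
        span = (1, index)
        base = _span_mass(p, 1, index)
        if series == "b":
            neutral = base
        elif series == "a":
            neutral = base - CO
        else:  # c
            neutral = base + NH3
    else:
        span = (n - index + 1, n)
        base = _span_mass(p, *span) + WATER
        if p.amidated:
            base += AMIDE_DELTA
        if series == "y":
            neutral = base
        else:  # z-dot
            neutral = base - NH2
    return neutral, span


def backbone_ions(p: Peptide, mode: FragmentationMode,
                  max_charge: int = 1, z_plus_one: bool = False) -> list[FragmentIon]:
    """All backbone fragment ions of ``mode`` up to ``max_charge``.

    For a peptide of length n each enabled series contributes exactly
    n-1 indices per charge state.  Ions whose cleavage falls inside an
    intact disulfide loop are returned with ``visible=False``.

    ``z_plus_one`` additionally emits the even-electron z+1 (z')
    species one hydrogen above z-dot.
    """
    if max_charge < 1:
        raise ValueError("max_charge must be >= 1")
    n = len(p)
    ions: list[FragmentIon] = []
    for series in sorted(mode.series):
        for index in range(1, n):
            neutral, span = _neutral_fragment_mass(p, series, index)
            visible = not _site_in_intact_loop(
                p, index if series in _PREFIX_SERIES else n - index)
            for charge in range(1, max_charge + 1):
                mz = (neutral + charge * PROTON) / charge
                ions.append(FragmentIon(series, index, charge, mz,
                                        visible=visible, source_positions=span))
                if series == "z" and z_plus_one:
                    ions.append(FragmentIon("z", index, charge,
                                            mz + H / charge, visible=visible,
                                            neutral_loss="+H",
                                            source_positions=span))
    return ions


class HAdjust(str, Enum):
    NONE = "none"
    PLUS_H = "plus_H"
    MINUS_H = "minus_H"


def open_disulfide_ions(p: Peptide, mode: FragmentationMode,
                        bond: tuple[int, int] | None = None,
                        h_adjust: HAdjust | str = HAdjust.NONE,
                        max_charge: int = 1) -> list[FragmentIon]:
    """c/z-dot ions with one S-S bond treated as already cleaved.

    ETD preferentially cleaves disulfides; a follow-up activation of the
    ring-opened species then yields backbone ions inside the former
    loop.  This is what exposes the Rana-box interior (e.g. the TKKC
    stretch of brevinin 1Db).  The chosen bond (default: the first) is
    removed, ions are recomputed against the remaining bonds, and an
    optional one-hydrogen adjustment is applied to every fragment
    containing one of the opened Cys residues.
    """
    if mode.name not in (Activation.ETD, Activation.ETHCD):
        raise ValueError("disulfide opening requires ETD or EThcD")
    if not p.disulfides:
        raise ValueError("peptide has no disulfide bond to open")
    h_adjust = HAdjust(h_adjust)
    if bond is None:
        bond = p.disulfides[0]
    elif tuple(bond) not in p.disulfides:
        raise ValueError(f"no disulfide {bond} on this peptide")
    remaining = tuple(b for b in p.disulfides if b != tuple(bond))
    opened = Peptide(p.sequence, p.c_terminus, remaining, name=p.name)
    etd_only = FragmentationMode(mode.name, mode.series & {"c", "z"},
                                 w_ions_enabled=False)
    ions = backbone_ions(opened, etd_only, max_charge=max_charge)
    if h_adjust is HAdjust.NONE:
        return ions
    shift = H if h_adjust is HAdjust.PLUS_H else -H
    out = []
    for ion in ions:
        start, end = ion.source_positions
        if any(start <= c <= end for c in bond):
            ion = replace(ion, mz=ion.mz + shift / ion.charge)
        out.append(ion)
    return out


def satellite_losses(ions: Iterable[FragmentIon], p: Peptide) -> list[FragmentIon]:
    """Secondary-fragmentation Lys losses from y ions.

    After the primary y cleavage, Lys-containing y ions can lose K
    (128.09496 Da) and, when the fragment carries a Lys-Lys run, KK
    (256.18992 Da).  Returns only the new satellite ions.
    """
    out: list[FragmentIon] = []
    for ion in ions:
        if ion.series != "y" or ion.neutral_loss:
            continue
        start, end = ion.source_positions
        frag = p.sequence[start - 1:end]
        if "K" not in frag:
            continue
        out.append(replace(ion, mz=ion.mz - LYS_RESIDUE / ion.charge,
                           neutral_loss="K"))
        if "KK" in frag:
            out.append(replace(ion, mz=ion.mz - 2 * LYS_RESIDUE / ion.charge,
                               neutral_loss="KK"))
    return out


def w_ions(p: Peptide, z_ions: Iterable[FragmentIon]) -> list[FragmentIon]:
    """Side-chain radical-loss w ions from z-dot ions.

    A z-dot ion whose N-terminal residue is Leu loses the isopropyl
    radical (43.05478 Da); Ile loses ethyl (29.03913 Da).  An
    unresolved 'J' yields both candidate w ions, each tagged with the
    hypothesis it would confirm.  Other residues give no w ion.
    """
    out: list[FragmentIon] = []
    for ion in z_ions:
        if ion.series != "z" or ion.neutral_loss:
            continue
        first = p.sequence[ion.source_positions[0] - 1]
        if first == "J":
            candidates = [("L", "Leu"), ("I", "Ile")]
        elif first in W_LOSS:
            candidates = [(first, None)]
        else:
            continue
        for code, hyp in candidates:
            out.append(FragmentIon("w", ion.index, ion.charge,
                                   ion.mz - W_LOSS[code] / ion.charge,
                                   visible=ion.visible,
                                   source_positions=ion.source_positions,
                                   hypothesis=hyp))
    return out


def predict_ions(p: Peptide, mode: FragmentationMode,
                 max_charge: int = 1) -> list[FragmentIon]:
    """Backbone ions plus the satellite and w ions the mode enables."""
    ions = backbone_ions(p, mode, max_charge=max_charge)
    if mode.satellite_losses_enabled:
        ions.extend(satellite_losses(ions, p))
    if mode.w_ions_enabled:
        ions.extend(w_ions(p, [i for i in ions if i.series == "z"]))
    return ions
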