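"""Spectrum annotation: ion-peak matching, coverage, Leu/Ile calls.

Matching mirrors manual spectrum annotation practice: each predicted
ion is assigned independently to its nearest peak within a ppm
tolerance (a peak may therefore satisfy several ions), with ties broken
by smaller |ppm| and then higher intensity.  Cleavage-site coverage
counts a site as established when any visible backbone ion cut at that
site matched.  Leu/Ile discrimination evaluates, per unresolved 'J'
position, the two competing w-ion hypotheses (isopropyl loss = Leu,
ethyl loss = Ile) and calls the residue only when exactly one
hypothesis has peak support.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .chem import Peptide
from .fragments import (ETHCD, FragmentIon, FragmentationMode,
                        predict_ions, w_ions)

__all__ = ["Annotation", "CoverageReport", "IsomerCall", "match_peaks",
           "sequence_coverage", "leu_ile_discriminate", "DEFAULT_TOL_PPM"]

#: Orbitrap-class default matching tolerance, ppm.
DEFAULT_TOL_PPM = 10.0

_BACKBONE = {"a", "b", "c", "y", "z"}


@dataclass(frozen=True)
class Annotation:
    """A peak <-> predicted-ion match within tolerance."""

    peak_index: int
    ion: FragmentIon
    ppm_deviation: float


@dataclass(frozen=True)
class CoverageReport:
    """Per-cleavage-site fragment evidence for one peptide/spectrum pair."""

    spectrum_id: str
    length: int
    site_evidence: dict[int, tuple[str, ...]]   # site -> matched ion labels
    matched_ion_count: int
    precursor_ppm: float | None = None
    precursor_mismatch_da: float | None = None

    @property
    def covered_sites(self) -> frozenset[int]:
        return frozenset(s for s, ev in self.site_evidence.items() if ev)

    @property
    def covered_fraction(self) -> float:
        if self.length < 2:
            return 0.0
        return len(self.covered_sites) / (self.length - 1)


class Call(str, Enum):
    LEU = "Leu"
    ILE = "Ile"
    UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class IsomerCall:
    """Leu/Ile decision for one ambiguous sequence position."""

    position: int
    call: Call
    evidence: tuple[Annotation, ...] = ()


def match_peaks(s, ions: list[FragmentIon], tol_ppm: float = DEFAULT_TOL_PPM,
                visible_only: bool = True) -> list[Annotation]:
    """Match each predicted ion to its nearest peak within ``tol_ppm``.

    Returns one annotation per matched ion; unmatched ions are simply
    absent.  Every reported |ppm deviation| is <= ``tol_ppm``.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if not len(s) or not ions:
        return []
    mz = s.mz_array
    inten = s.intensity_array
    out: list[Annotation] = []
    for ion in ions:
        if visible_only and not ion.visible:
            continue
        lo = ion.mz * (1 - tol_ppm * 1e-6)
        hi = ion.mz * (1 + tol_ppm * 1e-6)
        i0 = int(np.searchsorted(mz, lo, side="left"))
        i1 = int(np.searchsorted(mz, hi, side="right"))
        if i0 == i1:
            continue
        cand = np.arange(i0, i1)
        ppm = (mz[cand] - ion.mz) / ion.mz * 1e6
        # smallest |ppm| first, higher intensity breaks exact ties
        order = sorted(range(len(cand)),
                       key=lambda k: (abs(ppm[k]), -inten[cand[k]]))
        best = order[0]
        out.append(Annotation(int(cand[best]), ion, float(ppm[best])))
    return out


def _site_of(ion: FragmentIon) -> int:
    return ion.cleavage_site


def sequence_coverage(p: Peptide, annotations: list[Annotation],
                      spectrum_id: str = "") -> CoverageReport:
    """Summarise which backbone cleavage sites the annotations establish."""
    n = len(p)
    evidence: dict[int, list[str]] = {site: [] for site in range(1, n)}
    matched = 0
    for ann in annotations:
        matched += 1
        ion = ann.ion
        if ion.series in _BACKBONE and ion.visible and not ion.neutral_loss:
            evidence[_site_of(ion)].append(ion.label)
    return CoverageReport(
        spectrum_id=spectrum_id, length=n,
        site_evidence={s: tuple(v) for s, v in evidence.items()},
        matched_ion_count=matched)


def leu_ile_discriminate(p: Peptide, s, tol_ppm: float = DEFAULT_TOL_PPM,
                         mode: FragmentationMode = ETHCD,
                         require_parent_z: bool = True,
                         exclusive_evidence: bool = True) -> list[IsomerCall]:
    """Call Leu vs Ile at every 'J' position from w-ion evidence.

    For each ambiguous position the two hypothesis w ions (z-dot minus
    isopropyl for Leu, minus ethyl for Ile) are matched against the
    spectrum.  Exactly one hypothesis matching yields a call; zero or
    both yield ``undetermined``.  By default a call also requires the
    parent z-dot ion itself to be matched, since the radical-loss
    evidence is chained to an observed z ion, and a peak that is
    already explained as a backbone or satellite ion of the candidate
    is not accepted as w evidence (``exclusive_evidence``) — an
    isobaric coincidence must not masquerade as a side-chain loss.
    The N-terminal residue has no covering z ion and always comes back
    undetermined.
    """
    if "z" not in mode.series or not mode.w_ions_enabled:
        raise ValueError("Leu/Ile discrimination requires a z-dot/w-capable "
                         "mode (ETD or EThcD)")
    positions = sorted(p.ambiguous_positions)
    if not positions:
        return []
    n = len(p)
    all_ions = predict_ions(p, mode)
    backbone = [i for i in all_ions if i.series != "w"]
    z_ions = [i for i in all_ions if i.series == "z"]
    hyp_ions = w_ions(p, z_ions)
    z_by_index = {i.index: i for i in z_ions if i.charge == 1}
    explained = ({ann.peak_index for ann in match_peaks(s, backbone, tol_ppm)}
                 if exclusive_evidence else set())
    w_matches = {ann.ion: ann
                 for ann in match_peaks(s, hyp_ions, tol_ppm)
                 if ann.peak_index not in explained}
    z_matches = {ann.ion.index for ann in match_peaks(s, z_ions, tol_ppm)}

    calls: list[IsomerCall] = []
    for pos in positions:
        j = n - pos + 1  # z index whose N-terminal residue is pos
        if j > n - 1:    # N-terminal residue: no z ion covers it
            calls.append(IsomerCall(pos, Call.UNDETERMINED))
            continue
        parent = z_by_index.get(j)
        if require_parent_z and (parent is None or j not in z_matches
                                 or not parent.visible):
            calls.append(IsomerCall(pos, Call.UNDETERMINED))
            continue
        hits = {}
        for ion, ann in w_matches.items():
            if ion.index == j and ion.hypothesis:
                hits[ion.hypothesis] = ann
        if len(hits) == 1:
            hyp, ann = next(iter(hits.items()))
            calls.append(IsomerCall(pos, Call(hyp), (ann,)))
        else:
            calls.append(IsomerCall(pos, Call.UNDETERMINED,
                                    tuple(hits.values())))
    return calls


def export_annotations(s, annotations: list[Annotation]) -> str:
    """Tab-separated annotated-peak table (mz, intensity, label, ppm)."""
    lines = ["peak_mz\tintensity\tion\tppm"]
    for ann in sorted(annotations, key=lambda a: a.peak_index):
        pk = s.peaks[ann.peak_index]
        lines.append(f"{pk.mz:.4f}\t{pk.intensity:.3g}\t"
                     f"{ann.ion.label}\t{ann.ppm_deviation:.1f}")
    return "\n".join(lines) + "\n"
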