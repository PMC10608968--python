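"""Study-level peptidome analyses.

Three pieces sit on top of the chemistry/fragmentation stack:

* a rule-based classifier assigning frog skin peptides to the families
  found in ranid secretions (brevinin 1/2, temporin, melittin-related
  peptide, bradykinin-related peptide);
* a targeted search that enumerates bradykinin variants (N-/C-
  extensions, proteolytic truncations, single-residue substitutions)
  and screens precursor masses or spectra for them;
* a report builder that recomputes theoretical masses and ppm errors
  for a peptide inventory and flags any disagreement with the supplied
  experimental or previously published values.

Bundled reference tables (loaded with :func:`load_reference_peptides`
and :func:`load_cloned_sequences`) hold the 28 secreted peptides and
the 20 cDNA-cloned transcriptome sequences of *Rana dalmatina*.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources

import pandas as pd

from .chem import (CTerminus, Peptide, peptide_mono_mass, ppm_error,
                   round_half_up)
from .fragments import HCD, backbone_ions
from .annotate import match_peaks

__all__ = ["Family", "FamilyCall", "classify_family", "VariantConfig",
           "TargetedHit", "targeted_variant_search", "PeptideRecord",
           "build_report", "load_reference_peptides", "load_cloned_sequences",
           "BRADYKININ", "THR6_BRADYKININ", "BRP_SEARCH_CONFIG"]

BRADYKININ = "RPPGFSPFR"
THR6_BRADYKININ = "RPPGFTPFR"


class Family(str, Enum):
    BREVININ1 = "brevinin1"
    BREVININ2 = "brevinin2"
    TEMPORIN = "temporin"
    MRP = "MRP"
    BRP = "BRP"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class FamilyCall:
    family: Family
    evidence: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.family is not Family.UNCLASSIFIED and not self.evidence:
            raise ValueError("a family call needs evidence")


def _longest_common_substring(a: str, b: str) -> str:
    best = ""
    for i in range(len(a)):
        for j in range(i + len(best) + 1, len(a) + 1):
            if a[i:j] in b:
                best = a[i:j]
            else:
                break
    return best


def _rana_box(p: Peptide) -> tuple[int, int] | None:
    """An annotated C-terminal disulfide loop with a 3-5 residue
    interior whose second Cys sits at (or one short of) the C-terminus."""
    n = len(p)
    for i, j in p.disulfides:
        if 3 <= j - i - 1 <= 5 and j >= n - 1:
            return (i, j)
    return None


# classification precedence: BRP -> Rana box -> temporin -> MRP.  The
# BRP rule runs first so short Cys-free bradykinin pieces are never
# read as temporins.
def classify_family(p: Peptide, brp_min_overlap: int = 5,
                    brevinin_length_cut: int = 26) -> FamilyCall:
    """Assign a peptide to a ranid skin-peptide family.

    Rules, in order: (1) BRP — an exact overlap of at least
    ``brp_min_overlap`` residues with the bradykinin or [Thr6]-
    bradykinin core; (2) a Rana box (C-terminal disulfide loop) —
    brevinin 1 up to ``brevinin_length_cut`` residues, brevinin 2
    beyond; (3) temporin — 10-14 residues, amidated, Cys-free; (4)
    melittin-related peptide — 20-26 residues, amidated, Cys-free.
    Anything else is unclassified.
    """
    seq, n = p.sequence, len(p)
    for core in (BRADYKININ, THR6_BRADYKININ):
        ov = _longest_common_substring(seq, core)
        if len(ov) >= brp_min_overlap:
            return FamilyCall(Family.BRP,
                              (f"core overlap {ov} with {core}",))
    box = _rana_box(p)
    if box is not None:
        fam = Family.BREVININ1 if n <= brevinin_length_cut else Family.BREVININ2
        return FamilyCall(fam, (f"Rana box Cys{box[0]}-Cys{box[1]}",
                                f"length {n}"))
    if "C" not in seq and p.amidated:
        if 10 <= n <= 14:
            return FamilyCall(Family.TEMPORIN,
                              (f"length {n}", "amidated", "Cys-free"))
        if 20 <= n <= 26:
            return FamilyCall(Family.MRP,
                              (f"length {n}", "amidated", "Cys-free"))
    return FamilyCall(Family.UNCLASSIFIED)


# ---------------------------------------------------------------------------
# Targeted bradykinin-variant search

@dataclass(frozen=True)
class VariantConfig:
    """Variant space around a core peptide.

    Extensions are given as residue strings; substitutions as 1-based
    ``(position, residue)`` pairs applied singly to the core.
    Truncations remove up to ``n_truncation_window`` leading and
    ``c_truncation_window`` trailing residues of each variant, subject
    to ``min_length``.
    """

    n_extensions: tuple[str, ...] = ()
    c_extensions: tuple[str, ...] = ()
    substitutions: tuple[tuple[int, str], ...] = ()
    n_truncation_window: int = 0
    c_truncation_window: int = 0
    min_length: int = 5


#: The published bradykinin-related-peptide search space: DV N-terminal
#: extension, I / IA C-terminal extensions, Ser6->Thr6 substitution,
#: and the proteolytic truncation windows the detected fragments span.
BRP_SEARCH_CONFIG = VariantConfig(
    n_extensions=("DV",),
    c_extensions=("I", "IA"),
    substitutions=((6, "T"),),
    n_truncation_window=4,
    c_truncation_window=2,
)


@dataclass(frozen=True)
class TargetedHit:
    sequence: str
    description: str
    theoretical_mass: float
    dataset_index: int
    matched_mass: float
    ppm: float
    diagnostic_ion_matches: int | None = None


def enumerate_variants(core: Peptide, cfg: VariantConfig) -> dict[str, str]:
    """All variant sequences (deduplicated) with a provenance string."""
    if not core.sequence:
        raise ValueError("core must be non-empty")
    bases = {core.sequence: "core"}
    for pos, res in cfg.substitutions:
        seq = core.sequence[:pos - 1] + res + core.sequence[pos:]
        bases.setdefault(seq, f"core {core.sequence[pos - 1]}{pos}->{res}")
    variants: dict[str, str] = {}
    for base, base_desc in bases.items():
        for n_ext in ("",) + tuple(cfg.n_extensions):
            for c_ext in ("",) + tuple(cfg.c_extensions):
                full = n_ext + base + c_ext
                desc = base_desc
                if n_ext:
                    desc += f" +N[{n_ext}]"
                if c_ext:
                    desc += f" +C[{c_ext}]"
                for start in range(0, cfg.n_truncation_window + 1):
                    for stop in range(0, cfg.c_truncation_window + 1):
                        sub = full[start:len(full) - stop]
                        if len(sub) < cfg.min_length:
                            continue
                        d = desc
                        if start or stop:
                            d += f" [{start + 1}-{len(full) - stop}]"
                        variants.setdefault(sub, d)
    if not variants:
        raise ValueError("variant set is empty")
    return variants


def targeted_variant_search(core: Peptide, cfg: VariantConfig,
                            dataset, tol_ppm: float = 10.0,
                            c_terminus: CTerminus = CTerminus.FREE_ACID) -> list[TargetedHit]:
    """Screen precursor masses (or spectra) for core variants.

    ``dataset`` entries are either neutral monoisotopic masses in Da or
    :class:`~ranapep.spectra.Spectrum` objects.  A mass entry hits when
    it matches a variant's theoretical mass within ``tol_ppm`` (0 means
    exact equality); for spectra, matched diagnostic singly charged
    b/y ions of the variant are additionally counted.
    """
    variants = enumerate_variants(core, cfg)
    peptides = {seq: Peptide(seq, c_terminus) for seq in variants}
    masses = {seq: peptide_mono_mass(pep) for seq, pep in peptides.items()}
    hits: list[TargetedHit] = []
    for idx, entry in enumerate(dataset):
        if hasattr(entry, "precursor_mz"):
            exp_mass = entry.precursor_neutral_mass
            spectrum = entry
        else:
            exp_mass, spectrum = float(entry), None
        if exp_mass is None:
            continue
        for seq, theor in masses.items():
            if tol_ppm == 0:
                ok = exp_mass == theor
            else:
                ok = ppm_error(exp_mass, theor) <= tol_ppm
            if not ok:
                continue
            diag = None
            if spectrum is not None:
                ions = backbone_ions(peptides[seq], HCD)
                diag = len(match_peaks(spectrum, ions, max(tol_ppm, 1e-6)))
            hits.append(TargetedHit(
                sequence=seq, description=variants[seq],
                theoretical_mass=round_half_up(theor, 3),
                dataset_index=idx, matched_mass=exp_mass,
                ppm=round_half_up(ppm_error(exp_mass, theor), 1)
                if theor else 0.0,
                diagnostic_ion_matches=diag))
    return hits


# ---------------------------------------------------------------------------
# Table-style report

@dataclass(frozen=True)
class PeptideRecord:
    """One inventory row: a peptide with its measured mass and any
    previously published theoretical mass / ppm values to check."""

    name: str
    peptide: Peptide
    experimental_mass: float | None = None
    published_theoretical_mass: float | None = None
    published_ppm: float | None = None
    novel: bool = False
    notes: str = ""


def build_report(records: list[PeptideRecord]) -> pd.DataFrame:
    """Recompute masses, ppm and family for an inventory of peptides.

    Theoretical masses are recomputed from sequence/terminus/disulfide
    state (rounded half-up to 3 decimals), ppm errors from the supplied
    experimental masses (1 decimal).  Where published values are given,
    disagreements beyond the printed precision are flagged rather than
    silently adopted.  Recomputation is idempotent: re-running on the
    report's own values changes nothing.
    """
    rows = []
    for rec in records:
        p = rec.peptide
        theor = peptide_mono_mass(p)
        theor_r = round_half_up(theor, 3)
        ppm_r = (round_half_up(ppm_error(rec.experimental_mass, theor_r), 1)
                 if rec.experimental_mass is not None else None)
        call = classify_family(p)
        suffix = "-NH2" if p.amidated else "-OH"
        mass_flag = (rec.published_theoretical_mass is not None
                     and abs(theor_r - rec.published_theoretical_mass) > 0.001)
        ppm_flag = (rec.published_ppm is not None and ppm_r is not None
                    and abs(ppm_r - rec.published_ppm) > 0.05)
        rows.append({
            "name": rec.name,
            "sequence": p.sequence + suffix,
            "length": len(p),
            "disulfides": ";".join(f"{i}-{j}" for i, j in p.disulfides),
            "exp_mass": rec.experimental_mass,
            "theor_mass": theor_r,
            "ppm": ppm_r,
            "family": call.family.value,
            "novel": rec.novel,
            "mass_mismatch": mass_flag,
            "ppm_mismatch": ppm_flag,
            "notes": rec.notes,
        })
    columns = ["name", "sequence", "length", "disulfides", "exp_mass",
               "theor_mass", "ppm", "family", "novel", "mass_mismatch",
               "ppm_mismatch", "notes"]
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# Bundled reference data

def _data_text(fname: str) -> str:
    return (resources.files("ranapep") / "data" / fname).read_text()


def load_reference_peptides() -> list[PeptideRecord]:
    """The 28 peptides identified in the secretion, with measured and
    published theoretical masses."""
    records = []
    for line in _data_text("secreted_peptides.tsv").splitlines():
        if not line.strip() or line.startswith("name\t") or line.startswith("#"):
            continue
        (name, seq, c_term, ss, exp, theor, ppm, novel) = line.split("\t")
        bonds = tuple(tuple(int(x) for x in b.split("-"))
                      for b in ss.split(";")) if ss != "-" else ()
        pep = Peptide(seq, CTerminus(c_term), bonds, name=name)
        records.append(PeptideRecord(
            name=name, peptide=pep, experimental_mass=float(exp),
            published_theoretical_mass=float(theor),
            published_ppm=float(ppm), novel=(novel == "1")))
    return records


def load_cloned_sequences() -> pd.DataFrame:
    """cDNA-cloned transcriptome sequences (code, sequence, group)."""
    from io import StringIO
    return pd.read_csv(StringIO(_data_text("cloned_transcriptome.tsv")),
                       sep="\t")
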