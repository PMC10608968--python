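"""Centroided spectra: MGF I/O and synthetic-spectrum simulation.

The simulator stands in for instrument data: it emits the ions a given
activation mode predicts for a peptide, with configurable peak dropout,
Gaussian ppm m/z jitter and uniform noise peaks, deterministically from
a seed.  MGF reading/writing is backed by :mod:`pyteomics.mgf`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
from pyteomics import mgf as _mgf

from .chem import PROTON, Peptide, ion_mz, peptide_mono_mass
from .fragments import FragmentationMode, predict_ions

__all__ = ["Peak", "Spectrum", "SimulationConfig", "simulate_spectrum",
           "read_mgf", "write_mgf", "MGFError"]


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float = 1.0

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("peak m/z must be positive")
        if self.intensity < 0:
            raise ValueError("peak intensity must be >= 0")


@dataclass
class Spectrum:
    """A centroided peak list with precursor information.

    Peaks are sorted by m/z on construction and exact-duplicate m/z
    values are merged (intensities summed).  ``precursor_charge`` is
    ``None`` when the source file did not state it.
    """

    peaks: list[Peak]
    precursor_mz: float
    precursor_charge: int | None = None
    title: str = ""
    mode: str = ""

    def __post_init__(self) -> None:
        merged: dict[float, float] = {}
        for pk in self.peaks:
            merged[pk.mz] = merged.get(pk.mz, 0.0) + pk.intensity
        self.peaks = [Peak(mz, inten) for mz, inten in sorted(merged.items())]
        if self.precursor_charge is not None and self.precursor_charge < 1:
            raise ValueError("precursor charge must be >= 1")

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])

    @property
    def intensity_array(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks])

    @property
    def precursor_neutral_mass(self) -> float | None:
        if self.precursor_charge is None:
            return None
        return (self.precursor_mz - PROTON) * self.precursor_charge

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass(frozen=True)
class SimulationConfig:
    """Noise model for synthetic spectra.

    dropout_prob:
        Probability each predicted ion is *not* observed.
    mz_jitter_ppm:
        Gaussian sigma of the relative m/z error, ppm.
    noise_peak_count:
        Number of uniform random noise peaks in [100, precursor m/z].
    intensity_model:
        ``uniform`` (all 1.0) or ``rank_decay`` (1/ion rank).
    """

    dropout_prob: float = 0.0
    mz_jitter_ppm: float = 0.0
    noise_peak_count: int = 0
    intensity_model: str = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout_prob must be in [0, 1]")
        if self.mz_jitter_ppm < 0:
            raise ValueError("mz_jitter_ppm must be >= 0")
        if self.noise_peak_count < 0:
            raise ValueError("noise_peak_count must be >= 0")
        if self.intensity_model not in ("uniform", "rank_decay"):
            raise ValueError("intensity_model must be uniform or rank_decay")


def simulate_spectrum(p: Peptide, mode: FragmentationMode,
                      cfg: SimulationConfig = SimulationConfig(),
                      precursor_charge: int = 2,
                      max_fragment_charge: int = 1) -> Spectrum:
    """Synthesize a centroided MS/MS spectrum for a peptide.

    Every *visible* ion the mode predicts (backbone series plus Lys-loss
    satellites and w-ions where enabled) is retained with probability
    ``1 - dropout_prob``, its m/z perturbed by Gaussian ppm jitter, and
    ``noise_peak_count`` uniform noise peaks are added below the
    precursor m/z.  Deterministic for a fixed config seed.
    """
    rng = np.random.default_rng(cfg.seed)
    ions = [i for i in predict_ions(p, mode, max_charge=max_fragment_charge)
            if i.visible]
    precursor_mz = ion_mz(peptide_mono_mass(p), precursor_charge)
    peaks: list[Peak] = []
    for rank, ion in enumerate(ions, start=1):
        if rng.random() < cfg.dropout_prob:
            continue
        mz = ion.mz
        if cfg.mz_jitter_ppm > 0:
            mz *= 1.0 + rng.normal(0.0, cfg.mz_jitter_ppm) * 1e-6
        inten = 1.0 if cfg.intensity_model == "uniform" else 1.0 / rank
        peaks.append(Peak(mz, inten))
    if cfg.noise_peak_count:
        lo, hi = 100.0, max(precursor_mz, 101.0)
        noise_int = min((pk.intensity for pk in peaks), default=1.0) * 0.5
        for mz in rng.uniform(lo, hi, size=cfg.noise_peak_count):
            peaks.append(Peak(float(mz), noise_int))
    return Spectrum(peaks, precursor_mz, precursor_charge,
                    title=p.name or p.sequence, mode=mode.name.value)


class MGFError(ValueError):
    """Malformed MGF input."""


def _find_bad_line(text: str) -> int | None:
    """Best-effort location of the first malformed line in an MGF body."""
    in_block = False
    for lineno, line in enumerate(text.splitlines(), 1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        if s.upper() == "BEGIN IONS":
            in_block = True
            continue
        if s.upper() == "END IONS":
            in_block = False
            continue
        if in_block and "=" not in s:
            try:
                parts = s.split()
                float(parts[0])
                if len(parts) > 1:
                    float(parts[1])
            except (ValueError, IndexError):
                return lineno
    return None


def read_mgf(source: IO[str] | str | Path) -> list[Spectrum]:
    """Read all spectra from an MGF stream, string or path.

    Recognised block fields: TITLE, PEPMASS (m/z with optional
    intensity), CHARGE ("2+").  A missing CHARGE leaves the charge
    unknown; peaks are sorted on load.  Malformed peak lines raise
    :class:`MGFError` naming the line number.
    """
    if isinstance(source, Path):
        text = source.read_text()
    elif isinstance(source, str) and "\n" not in source and Path(source).exists():
        text = Path(source).read_text()
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()
    spectra: list[Spectrum] = []
    try:
        with _mgf.read(io.StringIO(text), use_index=False) as reader:
            for entry in reader:
                params = entry["params"]
                pepmass = params.get("pepmass", (0.0,))
                charge_field = params.get("charge")
                charge = int(charge_field[0]) if charge_field else None
                peaks = [Peak(float(mz), float(inten))
                         for mz, inten in zip(entry["m/z array"],
                                              entry["intensity array"])]
                spectra.append(Spectrum(
                    peaks, float(pepmass[0]), charge,
                    title=str(params.get("title", "")),
                    mode=str(params.get("mode", ""))))
    except MGFError:
        raise
    except Exception as exc:
        lineno = _find_bad_line(text)
        where = f" at line {lineno}" if lineno is not None else ""
        raise MGFError(f"malformed MGF block{where}: {exc}") from exc
    return spectra


def write_mgf(spectra: Iterable[Spectrum], stream: IO[str] | str | Path) -> None:
    """Write spectra in Mascot generic format (round-trips with read_mgf)."""
    entries = []
    for s in spectra:
        params = {"title": s.title, "pepmass": round(s.precursor_mz, 4)}
        if s.precursor_charge is not None:
            params["charge"] = f"{s.precursor_charge}+"
        if s.mode:
            params["mode"] = s.mode
        entries.append({
            "params": params,
            "m/z array": np.round(s.mz_array, 4),
            "intensity array": np.round(s.intensity_array, 4),
        })
    if isinstance(stream, (str, Path)):
        with open(stream, "w") as fh:
            _mgf.write(entries, fh)
    else:
        _mgf.write(entries, stream)
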