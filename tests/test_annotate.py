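"""Peak matching, coverage accounting and Leu/Ile discrimination."""

import numpy as np
import pytest
from scipy.stats import norm

from ranapep.chem import CTerminus, Peptide, RESIDUE_MASSES
from ranapep.fragments import ETHCD, HCD, backbone_ions, predict_ions, w_ions
from ranapep.spectra import Peak, SimulationConfig, Spectrum, simulate_spectrum
from ranapep.annotate import (Call, leu_ile_discriminate, match_peaks,
                              sequence_coverage)


def jify(seq: str) -> str:
    return "".join("J" if c in "LI" else c for c in seq)


class TestMatchPeaks:
    def test_noiseless_simulation_matches_every_ion(self, bradykinin):
        sp = simulate_spectrum(bradykinin, HCD, SimulationConfig(seed=0))
        ions = backbone_ions(bradykinin, HCD)
        assert len(match_peaks(sp, ions, 10.0)) == len(ions) == 16

    def test_empty_spectrum_gives_no_annotations(self, bradykinin):
        empty = Spectrum([], 500.0, 2)
        assert match_peaks(empty, backbone_ions(bradykinin, HCD), 10.0) == []

    def test_every_annotation_within_tolerance(self, temporin_a):
        cfg = SimulationConfig(mz_jitter_ppm=8, noise_peak_count=30, seed=5)
        sp = simulate_spectrum(temporin_a, ETHCD, cfg)
        anns = match_peaks(sp, predict_ions(temporin_a, ETHCD), 10.0)
        assert anns and all(abs(a.ppm_deviation) <= 10.0 for a in anns)

    def test_matched_fraction_follows_gaussian_tail(self, bradykinin):
        """With sigma=20 ppm jitter and 5 ppm tolerance the matched
        fraction approaches P(|N(0,20)| < 5) ~= 0.197."""
        ions = backbone_ions(bradykinin, HCD)
        matched = total = 0
        for s in range(120):
            sp = simulate_spectrum(bradykinin, HCD,
                                   SimulationConfig(mz_jitter_ppm=20, seed=s))
            matched += len(match_peaks(sp, ions, 5.0))
            total += len(ions)
        expect = 2 * norm.cdf(5 / 20) - 1
        se = np.sqrt(expect * (1 - expect) / total)
        assert abs(matched / total - expect) < 4 * se

    def test_tie_resolved_to_smallest_ppm(self):
        ion = backbone_ions(Peptide("GG"), HCD)[0]  # b1
        near = ion.mz * (1 + 2e-6)
        far = ion.mz * (1 + 8e-6)
        sp = Spectrum([Peak(near, 1.0), Peak(far, 99.0)], 300.0, 1)
        (ann,) = match_peaks(sp, [ion], 10.0)
        assert sp.peaks[ann.peak_index].mz == pytest.approx(near)


class TestCoverage:
    def test_full_noiseless_ethcd_coverage(self, temporin_1da):
        sp = simulate_spectrum(temporin_1da, ETHCD, SimulationConfig(seed=0))
        anns = match_peaks(sp, predict_ions(temporin_1da, ETHCD), 10.0)
        assert sequence_coverage(temporin_1da, anns).covered_fraction == 1.0

    def test_single_ion_covers_one_site(self, bradykinin):
        b2 = [i for i in backbone_ions(bradykinin, HCD)
              if i.series == "b" and i.index == 2]
        sp = Spectrum([Peak(b2[0].mz)], 531.0, 2)
        rep = sequence_coverage(bradykinin, match_peaks(sp, b2, 10.0))
        n = len(bradykinin)
        assert rep.covered_fraction == pytest.approx(1 / (n - 1))
        assert rep.covered_sites == frozenset({2})

    def test_intact_disulfide_leaves_loop_uncovered(self, brevinin_1da):
        sp = simulate_spectrum(brevinin_1da, HCD, SimulationConfig(seed=0))
        anns = match_peaks(sp, predict_ions(brevinin_1da, HCD), 10.0)
        rep = sequence_coverage(brevinin_1da, anns)
        loop_sites = set(range(11, 17))       # between Cys11 and Cys17
        assert rep.covered_sites.isdisjoint(loop_sites)
        assert rep.covered_fraction == pytest.approx(
            (len(brevinin_1da) - 1 - len(loop_sites)) / (len(brevinin_1da) - 1))

    def test_adding_peaks_never_decreases_coverage(self, temporin_a, rng):
        ions = predict_ions(temporin_a, ETHCD)
        full = simulate_spectrum(temporin_a, ETHCD, SimulationConfig(seed=1))
        prev = -1.0
        for k in range(0, len(full.peaks) + 1, 5):
            sp = Spectrum(list(full.peaks[:k]), full.precursor_mz,
                          full.precursor_charge)
            frac = sequence_coverage(
                temporin_a, match_peaks(sp, ions, 10.0)).covered_fraction
            assert frac >= prev
            prev = frac


class TestLeuIle:
    def test_all_six_isomers_called_on_clean_spectrum(self, temporin_1da):
        sp = simulate_spectrum(temporin_1da, ETHCD, SimulationConfig(seed=3))
        cand = Peptide(jify(temporin_1da.sequence), CTerminus.AMIDE)
        calls = {c.position: c.call.value
                 for c in leu_ile_discriminate(cand, sp, 10.0)}
        truth = {i: ("Leu" if c == "L" else "Ile")
                 for i, c in enumerate(temporin_1da.sequence, 1) if c in "LI"}
        assert calls == truth
        assert len(calls) == 6

    def test_missing_w_ion_yields_undetermined(self, temporin_1da):
        sp = simulate_spectrum(temporin_1da, ETHCD, SimulationConfig(seed=3))
        cand = Peptide(jify(temporin_1da.sequence), CTerminus.AMIDE)
        # remove the w evidence for position 4 (z index n-4+1 = 10)
        z10 = next(i for i in backbone_ions(temporin_1da, ETHCD)
                   if i.series == "z" and i.index == 10)
        w10 = w_ions(temporin_1da, [z10])[0]
        peaks = [p for p in sp.peaks if abs(p.mz - w10.mz) > 0.01]
        sp2 = Spectrum(peaks, sp.precursor_mz, sp.precursor_charge)
        calls = {c.position: c.call for c in leu_ile_discriminate(cand, sp2, 10.0)}
        assert calls[4] is Call.UNDETERMINED
        assert calls[2] is not Call.UNDETERMINED

    def test_conflicting_hypotheses_yield_undetermined(self, temporin_1da):
        sp = simulate_spectrum(temporin_1da, ETHCD, SimulationConfig(seed=3))
        cand = Peptide(jify(temporin_1da.sequence), CTerminus.AMIDE)
        # inject the opposing (Ile) w peak for position 4: conflict
        z10 = next(i for i in backbone_ions(temporin_1da, ETHCD)
                   if i.series == "z" and i.index == 10)
        w_alt = z10.mz - 29.03913
        sp2 = Spectrum(list(sp.peaks) + [Peak(w_alt)], sp.precursor_mz,
                       sp.precursor_charge)
        calls = {c.position: c.call for c in leu_ile_discriminate(cand, sp2, 10.0)}
        assert calls[4] is Call.UNDETERMINED

    def test_collision_mode_rejected(self, temporin_1da):
        sp = simulate_spectrum(temporin_1da, HCD, SimulationConfig(seed=3))
        with pytest.raises(ValueError):
            leu_ile_discriminate(temporin_1da, sp, 10.0, mode=HCD)

    def test_never_wrong_under_dropout(self, rng):
        """With 30% peak dropout the caller abstains rather than errs."""
        aa = sorted(set(RESIDUE_MASSES) - {"J"})
        for _ in range(30):
            n = int(rng.integers(8, 21))
            while True:
                seq = "".join(rng.choice(aa, size=n))
                if sum(c in "LI" for c in seq[1:]) >= 2:
                    break
            p = Peptide(seq, CTerminus.AMIDE)
            sp = simulate_spectrum(
                p, ETHCD, SimulationConfig(dropout_prob=0.3,
                                           seed=int(rng.integers(2**31))))
            cand = Peptide(jify(seq), CTerminus.AMIDE)
            for c in leu_ile_discriminate(cand, sp, 10.0):
                if c.call is Call.UNDETERMINED or seq[c.position - 1] not in "LI":
                    continue
                truth = "Leu" if seq[c.position - 1] == "L" else "Ile"
                assert c.call.value == truth, (seq, c.position)
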