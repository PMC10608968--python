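"""Fragment-ion prediction vs an independent residue-sum oracle."""

import pytest
from hypothesis import given, settings, strategies as st

from ranapep.chem import CTerminus, Peptide, peptide_mono_mass
from ranapep.fragments import (CID, ETD, ETHCD, HCD, CO, NH2, NH3,
                               FragmentationMode, Activation, backbone_ions,
                               disulfide_visibility, open_disulfide_ions,
                               predict_ions, satellite_losses, w_ions)

from conftest import (ORACLE_AMIDE, ORACLE_PROTON, ORACLE_WATER,
                      oracle_prefix, oracle_suffix)

FREE_AA = st.sampled_from("GASPVTCLNDQKEMHFRYW")
SEQ = st.text(alphabet=FREE_AA, min_size=2, max_size=30)


def oracle_ion_mz(seq, series, index, amide=False):
    """Singly charged fragment m/z from first-principles residue sums."""
    if series in ("a", "b", "c"):
        base = oracle_prefix(seq, index)
        shift = {"a": -27.994915, "b": 0.0, "c": 17.026549}[series]
        return base + shift + ORACLE_PROTON
    base = oracle_suffix(seq, index) + ORACLE_WATER + (ORACLE_AMIDE if amide else 0)
    shift = {"y": 0.0, "z": -16.018724}[series]
    return base + shift + ORACLE_PROTON


def ion_map(p, mode, max_charge=1, **kw):
    return {(i.series, i.index, i.charge): i
            for i in backbone_ions(p, mode, max_charge, **kw)}


class TestBackboneIons:
    def test_bradykinin_hcd_examples(self, bradykinin):
        ions = ion_map(bradykinin, HCD)
        assert ions[("b", 2, 1)].mz == pytest.approx(254.161, abs=1e-3)
        assert ions[("y", 1, 1)].mz == pytest.approx(175.119, abs=1e-3)

    def test_bradykinin_etd_examples(self, bradykinin):
        ions = ion_map(bradykinin, ETD)
        assert ions[("c", 2, 1)].mz == pytest.approx(271.188, abs=1e-3)
        assert ions[("z", 1, 1)].mz == pytest.approx(159.100, abs=1e-3)

    @pytest.mark.parametrize("mode,n_series", [(HCD, 2), (ETD, 2), (ETHCD, 4)])
    def test_ion_counts(self, mode, n_series, temporin_a):
        n = len(temporin_a)
        ions = backbone_ions(temporin_a, mode, max_charge=2)
        assert len(ions) == n_series * (n - 1) * 2

    def test_series_offsets_constant(self, temporin_a):
        ions = ion_map(temporin_a, ETHCD)
        for i in range(1, len(temporin_a)):
            assert ions[("c", i, 1)].mz - ions[("b", i, 1)].mz == \
                pytest.approx(NH3, abs=1e-9)
            assert ions[("y", i, 1)].mz - ions[("z", i, 1)].mz == \
                pytest.approx(NH2, abs=1e-9)

    def test_b_y_complementarity(self, bradykinin):
        n = len(bradykinin)
        total = peptide_mono_mass(bradykinin)
        ions = ion_map(bradykinin, HCD)
        for i in range(1, n):
            s = ions[("b", i, 1)].mz + ions[("y", n - i, 1)].mz
            assert s == pytest.approx(total + 2 * 1.0072765, abs=1e-9)

    @settings(derandomize=True, max_examples=60)
    @given(SEQ, st.booleans())
    def test_oracle_equivalence_random_peptides(self, seq, amide):
        """Every predicted singly charged ion equals the brute-force sum."""
        p = Peptide(seq, CTerminus.AMIDE if amide else CTerminus.FREE_ACID)
        for ion in backbone_ions(p, ETHCD):
            assert ion.mz == pytest.approx(
                oracle_ion_mz(seq, ion.series, ion.index, amide), abs=1e-9)

    def test_mode_invariants(self):
        with pytest.raises(ValueError):
            FragmentationMode(Activation.HCD, frozenset({"b", "y"}),
                              w_ions_enabled=True)


class TestDisulfideVisibility:
    def test_loop_internal_y_invisible(self, brevinin_1da):
        ions = ion_map(brevinin_1da, HCD)
        assert not ions[("y", 3, 1)].visible       # cleavage 14/15 inside loop
        assert disulfide_visibility(brevinin_1da, ions[("y", 3, 1)]) is False

    def test_outside_loop_visible(self, brevinin_1da):
        ions = ion_map(brevinin_1da, HCD)
        assert ions[("b", 9, 1)].visible

    def test_linear_peptide_all_visible(self, temporin_a):
        assert all(i.visible for i in backbone_ions(temporin_a, ETHCD))


class TestOpenDisulfide:
    def test_rana_box_c_ions_become_visible(self, brevinin_1db):
        opened = open_disulfide_ions(brevinin_1db, ETHCD)
        vis = {i.index for i in opened if i.series == "c" and i.visible}
        assert {19, 20, 21, 22, 23} <= vis

    def test_no_h_adjust_matches_linear_values(self, brevinin_1db):
        linear = Peptide(brevinin_1db.sequence)
        lin = {(i.series, i.index): i.mz for i in backbone_ions(linear, ETD)}
        for ion in open_disulfide_ions(brevinin_1db, ETHCD):
            # single bond opened, none remain: equals the linear value
            assert ion.mz == pytest.approx(lin[(ion.series, ion.index)],
                                           abs=1e-9)

    def test_h_adjust_shifts_loop_fragments(self, brevinin_1db):
        none = {(i.series, i.index): i.mz
                for i in open_disulfide_ions(brevinin_1db, ETHCD, h_adjust="none")}
        plus = {(i.series, i.index): i.mz
                for i in open_disulfide_ions(brevinin_1db, ETHCD, h_adjust="plus_H")}
        # c24 span contains Cys18: shifted; c10 does not: unshifted
        assert plus[("c", 23)] - none[("c", 23)] == pytest.approx(1.0078250)
        assert plus[("c", 10)] == none[("c", 10)]

    def test_linear_peptide_rejected(self, temporin_a):
        with pytest.raises(ValueError, match="no disulfide"):
            open_disulfide_ions(temporin_a, ETHCD)

    def test_requires_etd_based_mode(self, brevinin_1da):
        with pytest.raises(ValueError, match="ETD"):
            open_disulfide_ions(brevinin_1da, HCD)


class TestSatelliteLosses:
    def test_lys_and_dilys_losses_present(self, brevinin_1db):
        ions = backbone_ions(brevinin_1db, HCD)
        sats = {i.label for i in satellite_losses(ions, brevinin_1db)}
        assert "y11-K" in sats and "y11-KK" in sats

    def test_no_lysine_no_satellites(self, bradykinin):
        ions = backbone_ions(bradykinin, HCD)
        assert satellite_losses(ions, bradykinin) == []

    def test_loss_gap_is_lysine_residue_mass(self, brevinin_1db):
        ions = ion_map(brevinin_1db, HCD)
        sats = {(i.index, i.neutral_loss): i.mz
                for i in satellite_losses(list(ions.values()), brevinin_1db)}
        assert ions[("y", 11, 1)].mz - sats[(11, "K")] == \
            pytest.approx(128.09496, abs=1e-9)


class TestWIons:
    @pytest.mark.parametrize("seq,w_mz", [("GIK", 215.139), ("GLK", 201.123)])
    def test_radical_loss_values(self, seq, w_mz):
        p = Peptide(seq)
        z = [i for i in backbone_ions(p, ETD) if i.series == "z"]
        w = {i.index: i.mz for i in w_ions(p, z)}
        assert w[2] == pytest.approx(w_mz, abs=1e-3)

    def test_unbranched_residue_gives_no_w(self):
        p = Peptide("AGK")
        z = [i for i in backbone_ions(p, ETD) if i.series == "z"]
        assert all(i.index != 3 for i in w_ions(p, z))
        # z2 starts at Gly: no w ion at all here
        assert w_ions(p, [i for i in z if i.index == 2]) == []

    def test_j_yields_both_hypotheses_separated_by_ch2(self):
        p = Peptide("GJK")
        z = [i for i in backbone_ions(p, ETD) if i.series == "z"]
        w = {i.hypothesis: i.mz for i in w_ions(p, z) if i.index == 2}
        assert set(w) == {"Leu", "Ile"}
        assert w["Ile"] - w["Leu"] == pytest.approx(14.01565, abs=1e-9)


class TestPredictIons:
    def test_ethcd_includes_satellites_and_w(self, temporin_1da):
        series = {i.series for i in predict_ions(temporin_1da, ETHCD)}
        assert {"b", "y", "c", "z", "w"} <= series
        losses = {i.neutral_loss for i in predict_ions(temporin_1da, ETHCD)}
        assert "K" in losses  # Lys satellite present
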