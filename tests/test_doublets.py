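"""Doublet matching, rank / second-peptide filters, target selection and the
full trigger decision."""

import numpy as np
import pytest

from xltrigger import (
    PrecursorInfo,
    SyntheticScenario,
    TriggerConfig,
    apply_rank_filter,
    apply_second_peptide_filter,
    decide,
    generate,
    match_doublets,
    second_peptide_mass,
    select_targets,
)
from xltrigger.chem import PROTON_MASS
from xltrigger.deconvolution import DeconvolutedPeak, assign_intensity_ranks
from xltrigger.fragments import peptide_neutral_mass

from conftest import make_spectrum


def dpeak(mono_mz, charge, intensity=100.0, rank=0):
    return DeconvolutedPeak(
        mono_mz=mono_mz,
        charge=charge,
        summed_intensity=intensity,
        max_member_intensity=intensity,
        member_indices=(),
        rank=rank,
    )


def brute_force_matches(peaks, xl, tol_ppm):
    """Independent all-pairs matcher: every ordered peak pair against every
    active doublet pair and the tolerance."""
    out = []
    for light in peaks:
        if light.charge < 1:
            continue
        for heavy in peaks:
            if heavy.charge != light.charge or heavy is light:
                continue
            for pair in xl.doublet_pairs:
                theo = light.mono_mz + pair.delta_mass / light.charge
                if abs(heavy.mono_mz - theo) <= theo * tol_ppm * 1e-6:
                    out.append((light.mono_mz, heavy.mono_mz, light.charge, pair.light.label))
    return sorted(out)


def as_tuples(matches):
    return sorted(
        (m.light_peak.mono_mz, m.heavy_peak.mono_mz, m.charge, m.pair.light.label)
        for m in matches
    )


class TestMatchDoublets:
    def test_z1_pair_at_sulfur_delta(self, xl):
        delta = xl.doublet_pairs[0].delta_mass
        peaks = [dpeak(500.0, 1), dpeak(500.0 + delta, 1)]
        (m,) = match_doublets(peaks, xl, 5.0)
        assert m.charge == 1
        assert abs(m.observed_delta_ppm) < 1e-6

    def test_charge_mismatch_is_rejected(self, xl):
        delta = xl.doublet_pairs[0].delta_mass
        peaks = [dpeak(500.0, 1), dpeak(500.0 + delta / 2, 2)]
        assert match_doublets(peaks, xl, 5.0) == []

    def test_z2_delta_is_divided_by_charge(self, xl):
        delta = xl.doublet_pairs[0].delta_mass
        peaks = [dpeak(400.0, 2), dpeak(400.0 + delta / 2, 2)]
        (m,) = match_doublets(peaks, xl, 5.0)
        assert m.charge == 2

    def test_tolerance_gate(self, xl):
        delta = xl.doublet_pairs[0].delta_mass
        theo = 500.0 + delta
        peaks = [dpeak(500.0, 1), dpeak(theo * (1 + 10e-6), 1)]
        assert match_doublets(peaks, xl, 5.0) == []
        assert len(match_doublets(peaks, xl, 12.0)) == 1

    def test_brute_force_equivalence_random(self, xl, rng):
        delta = xl.doublet_pairs[0].delta_mass
        for _ in range(100):
            n = int(rng.integers(2, 31))
            peaks = []
            for _ in range(n):
                z = int(rng.integers(0, 4))  # include some charge-unknown
                mz = float(rng.uniform(150, 1500))
                if rng.random() < 0.3 and peaks:
                    # plant a partner near an existing peak to force matches
                    ref = peaks[int(rng.integers(0, len(peaks)))]
                    if ref.charge >= 1:
                        z = ref.charge
                        mz = (ref.mono_mz + delta / z) * (1 + float(rng.normal(0, 3e-6)))
                peaks.append(dpeak(mz, z))
            peaks = assign_intensity_ranks(peaks)
            tol = float(rng.choice([1.0, 5.0, 10.0]))
            assert as_tuples(match_doublets(peaks, xl, tol)) == brute_force_matches(peaks, xl, tol)


class TestRankFilter:
    def test_one_member_in_top_20_is_kept(self, xl):
        delta = xl.doublet_pairs[0].delta_mass
        peaks = [dpeak(500.0, 1, rank=3), dpeak(500.0 + delta, 1, rank=50)]
        (m,) = match_doublets(peaks, xl, 5.0)
        assert apply_rank_filter([m], 20) == [m]
        assert m.doublet_rank == 3

    def test_both_members_outside_cutoff_removed(self, xl):
        delta = xl.doublet_pairs[0].delta_mass
        peaks = [dpeak(500.0, 1, rank=25), dpeak(500.0 + delta, 1, rank=40)]
        matches = match_doublets(peaks, xl, 5.0)
        assert apply_rank_filter(matches, 20) == []
        assert apply_rank_filter(matches, 25) == matches  # boundary rank kept

    def test_vacuous_cutoff_is_identity(self, xl):
        delta = xl.doublet_pairs[0].delta_mass
        peaks = assign_intensity_ranks([dpeak(500.0, 1), dpeak(500.0 + delta, 1)])
        matches = match_doublets(peaks, xl, 5.0)
        assert apply_rank_filter(matches, 100) == matches

    def test_idempotent(self, xl):
        delta = xl.doublet_pairs[0].delta_mass
        peaks = [dpeak(500.0, 1, rank=10), dpeak(500.0 + delta, 1, rank=30)]
        matches = match_doublets(peaks, xl, 5.0)
        once = apply_rank_filter(matches, 20)
        assert apply_rank_filter(once, 20) == once


class TestSecondPeptideFilter:
    def _match(self, xl, pep_mass, z=1):
        """A doublet whose light member is (pep + A stub) at charge z."""
        light_mz = (pep_mass + xl.stub("A").mass + z * PROTON_MASS) / z
        heavy_mz = light_mz + xl.doublet_pairs[0].delta_mass / z
        peaks = [dpeak(light_mz, z, rank=1), dpeak(heavy_mz, z, rank=2)]
        (m,) = match_doublets(peaks, xl, 5.0)
        return m

    def test_equals_partner_peptide_mass(self, xl):
        pep1, pep2 = 800.0, 700.0
        m = self._match(xl, pep1)
        prec_neutral = pep1 + pep2 + xl.full_mass
        precursor = PrecursorInfo((prec_neutral + 3 * PROTON_MASS) / 3, 3)
        assert second_peptide_mass(m, precursor, xl) == pytest.approx(pep2, abs=1e-6)

    def test_heavy_member_gives_same_value(self, xl):
        """Computing from the heavy member with its complementary stub gives
        the identical partner mass."""
        pep1, pep2 = 900.0, 650.0
        m = self._match(xl, pep1, z=2)
        prec_neutral = pep1 + pep2 + xl.full_mass
        precursor = PrecursorInfo((prec_neutral + 4 * PROTON_MASS) / 4, 4)
        via_light = second_peptide_mass(m, precursor, xl)
        pep_from_heavy = (m.heavy_peak.mono_mz - PROTON_MASS) * m.charge - m.pair.heavy.mass
        via_heavy = precursor.neutral_mass - pep_from_heavy - xl.full_mass
        assert via_light == pytest.approx(via_heavy, abs=1e-9)

    def test_linear_modified_leaves_nothing(self, xl):
        """A doublet covering the whole precursor leaves ~0 Da for a second
        peptide and must be filtered."""
        pep = 900.0
        m = self._match(xl, pep)
        prec_neutral = pep + xl.full_mass  # precursor is one peptide + linker
        precursor = PrecursorInfo(prec_neutral + PROTON_MASS, 1)
        spm = second_peptide_mass(m, precursor, xl)
        assert abs(spm) < 1.0
        assert apply_second_peptide_filter([m], precursor, xl, 500.0) == []

    @pytest.mark.parametrize("extra,kept", [(499.9, False), (500.1, True)])
    def test_near_boundary(self, xl, extra, kept):
        pep = 800.0
        m = self._match(xl, pep)
        prec_neutral = pep + xl.full_mass + extra
        precursor = PrecursorInfo(prec_neutral + PROTON_MASS, 1)
        out = apply_second_peptide_filter([m], precursor, xl, 500.0)
        assert bool(out) is kept
        if out:
            assert out[0].second_peptide_mass == pytest.approx(extra, abs=1e-6)

    def test_exact_boundary_is_kept(self, xl):
        """A remaining mass exactly at the minimum passes (>= convention)."""
        m = self._match(xl, 800.0)
        precursor = PrecursorInfo(800.0 + xl.full_mass + 500.0 + PROTON_MASS, 1)
        boundary = second_peptide_mass(m, precursor, xl)
        assert apply_second_peptide_filter([m], precursor, xl, boundary)
        assert not apply_second_peptide_filter(
            [m], precursor, xl, np.nextafter(boundary, np.inf)
        )

    def test_unknown_precursor_charge_kept_flagged(self, xl):
        m = self._match(xl, 800.0)
        precursor = PrecursorInfo(700.0, 0)
        (kept,) = apply_second_peptide_filter([m], precursor, xl, 500.0)
        assert kept.second_peptide_mass is None
        assert kept.second_peptide_unfiltered

    def test_empty_list(self, xl):
        assert apply_second_peptide_filter([], PrecursorInfo(500.0, 2), xl, 500.0) == []

    def test_idempotent(self, xl):
        m = self._match(xl, 800.0)
        precursor = PrecursorInfo((800.0 + 700.0 + xl.full_mass + 2 * PROTON_MASS) / 2, 2)
        once = apply_second_peptide_filter([m], precursor, xl, 500.0)
        twice = apply_second_peptide_filter(once, precursor, xl, 500.0)
        assert [m.second_peptide_mass for m in twice] == [m.second_peptide_mass for m in once]


def test_filter_monotonicity(xl, rng):
    """Surviving-match count never decreases when the rank cutoff or the
    tolerance grows, or the second-peptide minimum mass shrinks."""
    delta = xl.doublet_pairs[0].delta_mass
    peaks = []
    for _ in range(40):
        z = int(rng.integers(1, 3))
        mz = float(rng.uniform(200, 1200))
        peaks.append(dpeak(mz, z, intensity=float(rng.uniform(1, 100))))
        if rng.random() < 0.5:
            peaks.append(
                dpeak((mz + delta / z) * (1 + float(rng.normal(0, 4e-6))), z,
                      intensity=float(rng.uniform(1, 100)))
            )
    peaks = assign_intensity_ranks(peaks)
    precursor = PrecursorInfo(1200.0, 3)

    counts_tol = [len(match_doublets(peaks, xl, t)) for t in (1, 2.5, 5, 10, 20)]
    assert counts_tol == sorted(counts_tol)

    matches = match_doublets(peaks, xl, 10.0)
    counts_rank = [len(apply_rank_filter(matches, c)) for c in (1, 5, 10, 20, 50, 100)]
    assert counts_rank == sorted(counts_rank)

    counts_mass = [
        len(apply_second_peptide_filter(matches, precursor, xl, mm))
        for mm in (2000.0, 1000.0, 500.0, 100.0, 1.0)
    ]
    assert counts_mass == sorted(counts_mass)


class TestSelectTargets:
    def _doublet(self, xl, light_mz, z=1, rank_l=1, rank_h=2, intensity=100.0):
        delta = xl.doublet_pairs[0].delta_mass
        peaks = [
            dpeak(light_mz, z, intensity=intensity, rank=rank_l),
            dpeak(light_mz + delta / z, z, intensity=intensity, rank=rank_h),
        ]
        (m,) = match_doublets(peaks, xl, 5.0)
        return m

    def test_one_doublet_two_targets(self, xl):
        m = self._doublet(xl, 500.0)
        d = select_targets([m], cap=4, scan_id="s")
        assert d.trigger
        assert len(d.targets) == 2
        assert {t.mz for t in d.targets} == {m.light_peak.mono_mz, m.heavy_peak.mono_mz}

    def test_cap_and_order(self, xl):
        m1 = self._doublet(xl, 400.0, rank_l=1, rank_h=5)
        m2 = self._doublet(xl, 600.0, rank_l=2, rank_h=6)
        m3 = self._doublet(xl, 800.0, rank_l=3, rank_h=7)
        d = select_targets([m1, m2, m3], cap=4)
        assert len(d.targets) == 4
        # ordered by doublet rank: both m1 members, then both m2 members
        assert [t.source for t in d.targets] == [m1, m1, m2, m2]

    def test_no_doublets_no_trigger(self, xl):
        d = select_targets([], cap=4)
        assert not d.trigger
        assert d.targets == ()

    def test_deduplication_by_mz_and_charge(self, xl):
        m = self._doublet(xl, 500.0)
        d = select_targets([m, m], cap=4)
        assert len(d.targets) == 2


class TestDecide:
    def test_crosslinked_triggers_both_peptides(self, xl):
        spectra, truth = generate(SyntheticScenario(n_scans=5, class_mix=(1.0, 0, 0), seed=21), xl)
        for s, rec in zip(spectra, truth.itertuples()):
            d = decide(s, xl)
            assert d.trigger
            mzs = [t.mz for t in d.targets]
            for planted in (rec.p1_light_mz, rec.p1_heavy_mz, rec.p2_light_mz, rec.p2_heavy_mz):
                assert any(abs(t - planted) <= planted * 1e-6 for t in mzs)

    def test_linear_never_triggers(self, xl):
        spectra, _ = generate(SyntheticScenario(n_scans=5, class_mix=(0, 1.0, 0), seed=22), xl)
        assert all(not decide(s, xl).trigger for s in spectra)

    def test_linear_modified_never_triggers(self, xl):
        """Doublet present but the precursor holds one peptide only: the
        second-peptide-mass filter must veto the trigger."""
        spectra, truth = generate(SyntheticScenario(n_scans=5, class_mix=(0, 0, 1.0), seed=23), xl)
        for s, rec in zip(spectra, truth.itertuples()):
            d = decide(s, xl)
            assert not d.trigger
            # ... even though the doublet itself is found before step 4
            from xltrigger.deconvolution import deconvolute

            matches = apply_rank_filter(match_doublets(deconvolute(s), xl, 5.0), 20)
            assert matches

    def test_ms3_spectrum_rejected(self, xl):
        s = make_spectrum([(500.0, 1.0)], ms_level=3)
        with pytest.raises(ValueError):
            decide(s, xl)

    def test_unknown_precursor_charge_is_conservative(self, xl):
        """Without a precursor mass, steps 1-3 run and the decision is
        emitted unfiltered (a linker-modified linear peptide then triggers)."""
        spectra, _ = generate(SyntheticScenario(n_scans=2, class_mix=(0, 0, 1.0), seed=24), xl)
        s = spectra[0]
        s_unknown = make_spectrum(
            [(p.mz, p.intensity) for p in s.peaks],
            precursor_mz=s.precursor.mz,
            precursor_charge=0,
            scan_id=s.scan_id,
        )
        d = decide(s_unknown, xl)
        assert not d.second_peptide_filter_applied
        assert d.trigger


def test_trigger_config_validation():
    with pytest.raises(ValueError):
        TriggerConfig(ms2_tol_ppm=-1)
    with pytest.raises(ValueError):
        TriggerConfig(cap=0)
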