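"""Label mass arithmetic, triplet detection, and labeling QC checks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from silacq import synthetic_data as sd
from silacq.silac_labels import (
    HEAVY,
    LIGHT,
    MEDIUM,
    InvalidSequenceError,
    PeakList,
    PeptideSpec,
    UndefinedEfficiencyError,
    channel_mass_shift,
    check_arg_pro_conversion,
    detect_triplets,
    expected_mz_spacing,
    incorporation_efficiency,
)

SEQS = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30)


class TestChannelMassShift:
    @pytest.mark.parametrize(
        "seq,label,expected",
        [
            ("GVVDSEDLPLNISR", MEDIUM, 6.020129),   # 1 Arg, 13C6
            ("GVVDSEDLPLNISR", HEAVY, 10.008269),   # 1 Arg, 13C6 15N4
            ("VNQIGSVTESLQACK", MEDIUM, 4.025107),  # 1 Lys, 2H4
            ("VNQIGSVTESLQACK", HEAVY, 8.014199),   # 1 Lys, 13C6 15N2
            ("GVVDSEDLPLNISR", LIGHT, 0.0),
            ("AEDTAVYG", MEDIUM, 0.0),              # no K, no R
            ("AEDTAVYG", HEAVY, 0.0),
        ],
    )
    def test_known_shifts(self, seq, label, expected):
        assert channel_mass_shift(PeptideSpec(seq), label) == pytest.approx(
            expected, abs=1e-5
        )

    def test_rejects_invalid_residues(self):
        with pytest.raises(InvalidSequenceError):
            PeptideSpec("PEPTIDEZ1")

    @given(a=SEQS, b=SEQS)
    @settings(max_examples=200, deadline=None)
    def test_additive_over_concatenation(self, a, b):
        for label in (MEDIUM, HEAVY):
            assert channel_mass_shift(PeptideSpec(a + b), label) == pytest.approx(
                channel_mass_shift(PeptideSpec(a), label)
                + channel_mass_shift(PeptideSpec(b), label)
            )


class TestExpectedSpacing:
    def test_doubly_charged_lys_peptide(self):
        spec = PeptideSpec("VNQIGSVTESLQACK", charge=2)
        assert expected_mz_spacing(spec, (LIGHT, MEDIUM)) == pytest.approx(
            2.012554, abs=1e-5
        )

    def test_singly_charged_arg_peptide(self):
        spec = PeptideSpec("GVVDSEDLPLNISR", charge=1)
        assert expected_mz_spacing(spec, (LIGHT, HEAVY)) == pytest.approx(
            10.008269, abs=1e-5
        )

    def test_same_channel_is_zero(self):
        spec = PeptideSpec("GGPEVQQVPAGER", charge=2)
        assert expected_mz_spacing(spec, (MEDIUM, MEDIUM)) == 0.0

    @given(st.integers(min_value=1, max_value=6))
    @settings(deadline=None)
    def test_spacing_halves_when_charge_doubles(self, z):
        s1 = PeptideSpec("GVVDSEDLPLNISR", charge=z)
        s2 = PeptideSpec("GVVDSEDLPLNISR", charge=2 * z)
        assert expected_mz_spacing(s2, (LIGHT, HEAVY)) == pytest.approx(
            expected_mz_spacing(s1, (LIGHT, HEAVY)) / 2
        )


class TestDetectTriplets:
    def test_planted_triplet_found(self):
        spec = PeptideSpec("GVVDSEDLPLNISR", charge=1)
        peaks, truth = sd.simulate_peaklist(spec, incorporation=0.5, seed=0)
        found = detect_triplets(peaks, spec, tolerance_ppm=10)
        assert len(found) == 1
        assert found[0].light_mz == pytest.approx(truth[0].light_mz, abs=1e-9)
        assert found[0].heavy_mz - found[0].light_mz == pytest.approx(
            10.008269, abs=1e-4
        )

    def test_lone_light_peak_yields_nothing(self):
        spec = PeptideSpec("GVVDSEDLPLNISR", charge=1)
        peaks = PeakList.from_pairs([(800.0, 1e5)])
        assert detect_triplets(peaks, spec) == []

    def test_offset_medium_peak_rejected_at_10ppm(self):
        spec = PeptideSpec("GVVDSEDLPLNISR", charge=1)
        peaks, _ = sd.simulate_peaklist(spec, incorporation=0.5, seed=0)
        mz = peaks.mz.copy()
        # displace the medium peak by 0.1 Da (~66 ppm at m/z ~1500)
        i_m = int(np.argmin(np.abs(mz - (peaks.mz[0] + 6.020129))))
        mz[i_m] += 0.1
        broken = PeakList(np.sort(mz), peaks.intensity)
        assert detect_triplets(broken, spec, tolerance_ppm=10) == []

    def test_empty_peaklist(self):
        spec = PeptideSpec("GVVDSEDLPLNISR")
        assert detect_triplets(PeakList(np.empty(0), np.empty(0)), spec) == []

    def test_recovery_rate_on_clean_spectra(self):
        """>=99% of planted triplets recovered at 10 ppm without noise."""
        spec = PeptideSpec("VNQIGSVTESLQACK", charge=2)
        hits = 0
        n = 100
        for seed in range(n):
            peaks, truth = sd.simulate_peaklist(spec, incorporation=0.5, seed=seed)
            found = detect_triplets(peaks, spec, tolerance_ppm=10)
            hits += any(
                abs(f.light_mz - truth[0].light_mz) < 1e-6 for f in found
            )
        assert hits / n >= 0.99

    def test_pure_noise_spectra_mostly_clean(self):
        """No triplets on pure-noise spectra in >=95% of seeds."""
        spec = PeptideSpec("VNQIGSVTESLQACK", charge=2)
        clean = 0
        n = 40
        for seed in range(n):
            rng = np.random.default_rng(seed)
            mz = np.sort(rng.uniform(300, 1800, 40))
            mz = mz[np.diff(mz, prepend=0) > 1e-6]
            peaks = PeakList(mz, rng.uniform(1e3, 1e5, mz.size))
            clean += len(detect_triplets(peaks, spec, tolerance_ppm=10)) == 0
        assert clean / n >= 0.95


class TestIncorporationEfficiency:
    @pytest.mark.parametrize(
        "light,labeled,expected",
        [(0.0, 5e4, 1.0), (3.3, 3.3, 0.5), (2.0, 98.0, 0.98)],
    )
    def test_examples(self, light, labeled, expected):
        assert incorporation_efficiency(light, labeled) == pytest.approx(expected)

    def test_both_zero_is_undefined(self):
        with pytest.raises(UndefinedEfficiencyError):
            incorporation_efficiency(0.0, 0.0)

    @given(
        light=st.floats(0.01, 1e6),
        labeled=st.floats(0.01, 1e6),
        scale=st.floats(1e-3, 1e3),
    )
    @settings(max_examples=100, deadline=None)
    def test_scale_invariant(self, light, labeled, scale):
        assert incorporation_efficiency(light, labeled) == pytest.approx(
            incorporation_efficiency(light * scale, labeled * scale)
        )


class TestArgProConversion:
    def test_planted_satellite_flagged(self):
        spec = PeptideSpec("GVVDSEDLPLNISR", charge=1)  # one Pro
        peaks, _ = sd.simulate_peaklist(spec, conversion_fraction=0.2, seed=1)
        flag, frac = check_arg_pro_conversion(peaks, spec, "medium")
        assert flag
        assert frac == pytest.approx(0.2, abs=1e-6)

    def test_clean_spectrum_not_flagged(self):
        spec = PeptideSpec("GVVDSEDLPLNISR", charge=1)
        peaks, _ = sd.simulate_peaklist(spec, seed=1)
        flag, frac = check_arg_pro_conversion(peaks, spec, "medium")
        assert not flag and frac == 0.0

    def test_proline_free_peptide_vacuously_clean(self):
        spec = PeptideSpec("VNQIGSVTESLQACK", charge=2)
        peaks, _ = sd.simulate_peaklist(spec, seed=1)
        assert check_arg_pro_conversion(peaks, spec, "heavy") == (False, 0.0)
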