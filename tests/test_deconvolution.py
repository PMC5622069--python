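import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from quatmass.deconvolution import (
    PROTON_MASS,
    ChargeEnvelope,
    OccupancyDistribution,
    assign_charges,
    copper_adduct_delta,
    detect_adduct_series,
    mass_width_from_peak_width,
    neutral_mass,
)
from quatmass.peaks import Peak, PeakList


def envelope_peaks(mass: float, charges, fwhm: float = 0.0, scale: float = 1.0) -> PeakList:
    """Forward electrospray model: one peak per charge state."""
    return PeakList(
        [Peak((mass + z * PROTON_MASS) / z, scale, fwhm) for z in charges]
    )


class TestAssignCharges:
    def test_three_peak_envelope_z10_to_12(self):
        peaks = envelope_peaks(100_000.0, [10, 11, 12])
        envs = assign_charges(peaks, 1, 20, tol_ppm=20)
        assert len(envs) == 1
        assert [z for _, z in envs[0].members] == [12, 11, 10]

    def test_published_intact_mass_envelope(self):
        # charge run synthesized from the 211,216 Da intact complex
        peaks = envelope_peaks(211_216.0, range(27, 32))
        envs = assign_charges(peaks, 20, 40, tol_ppm=20)
        assert len(envs) == 1
        assert sorted(z for _, z in envs[0].members) == list(range(27, 32))

    def test_half_integer_spacing_rejected(self):
        # spacing implies z = 10.5; no integer charge makes the masses agree
        p_lo = Peak(PROTON_MASS + 10.5 * 900.0, 1.0)
        p_hi = Peak(p_lo.mz + 900.0, 1.0)
        envs = assign_charges(PeakList([p_lo, p_hi]), 1, 50, tol_ppm=50)
        assert envs == []

    def test_single_peak_ambiguous(self):
        assert assign_charges(PeakList([Peak(5000.0, 1.0)]), 1, 50) == []

    def test_intensity_scaling_invariance(self):
        peaks = envelope_peaks(211_216.0, range(27, 32))
        scaled = PeakList([Peak(p.mz, p.intensity * 1e6, p.fwhm_mz) for p in peaks])
        a = assign_charges(peaks, 20, 40, 20)
        b = assign_charges(scaled, 20, 40, 20)
        assert [[z for _, z in e.members] for e in a] == [
            [z for _, z in e.members] for e in b
        ]


class TestNeutralMass:
    def test_exact_inversion(self):
        envs = assign_charges(envelope_peaks(100_000.0, [10, 11, 12]), 1, 20, 20)
        est = neutral_mass(envs[0])
        assert est.mass == pytest.approx(100_000.0, abs=0.1)
        assert est.n_peaks == 3

    def test_intact_complex_mass_and_width(self):
        # per-peak FWHM of 55 Th at z ~ 29 maps to ~1.6 kDa in mass
        envs = assign_charges(envelope_peaks(211_216.0, range(27, 32), fwhm=55.0), 20, 40, 20)
        est = neutral_mass(envs[0])
        assert est.mass == pytest.approx(211_216.0, abs=1.0)
        assert est.fwhm_mass == pytest.approx(55.0 * 29, abs=1e-9)
        assert 1500 < est.fwhm_mass < 1700

    def test_single_member_flagged(self):
        env = ChargeEnvelope([(Peak(10001.007276, 1.0), 10)])
        est = neutral_mass(env)
        assert est.sd == 0.0
        assert est.n_peaks == 1
        assert est.low_confidence


class TestMassWidth:
    @pytest.mark.parametrize(
        "fwhm,z,expected",
        [(55.0, 29, 1595.0), (0.0, 17, 0.0), (33.3, 1, 33.3)],
    )
    def test_values(self, fwhm, z, expected):
        assert mass_width_from_peak_width(fwhm, z) == pytest.approx(expected)

    def test_linear_in_both_arguments(self):
        assert mass_width_from_peak_width(10.0, 6) == pytest.approx(
            2 * mass_width_from_peak_width(5.0, 6)
        )
        assert mass_width_from_peak_width(10.0, 6) == pytest.approx(
            2 * mass_width_from_peak_width(10.0, 3)
        )

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            mass_width_from_peak_width(-1.0, 5)


@settings(deadline=None, max_examples=80, derandomize=True)
@given(
    mass=st.floats(min_value=10_000.0, max_value=1_000_000.0),
    z_start=st.integers(min_value=5, max_value=80),
    run=st.integers(min_value=2, max_value=8),
)
def test_forward_inverse_identity(mass, z_start, run):
    """Synthesize -> assign -> neutral_mass recovers the input mass."""
    charges = list(range(z_start, min(z_start + run, 99)))
    peaks = envelope_peaks(mass, charges)
    envs = assign_charges(peaks, 1, 100, tol_ppm=5)
    assert len(envs) == 1
    est = neutral_mass(envs[0])
    assert abs(est.mass - mass) <= 5e-6 * mass


class TestAdductSeries:
    def mk_series(self, base_mass: float, z: int, intensities: dict[int, float]) -> PeakList:
        delta = copper_adduct_delta(0)
        return PeakList(
            [
                Peak((base_mass + k * delta + z * PROTON_MASS) / z, inten)
                for k, inten in intensities.items()
            ]
        )

    def test_apo_only(self):
        peaks = self.mk_series(11_699.0, 5, {0: 3.0})
        dist = detect_adduct_series(peaks, 5, copper_adduct_delta(0), 3)
        assert dist.probs == {0: 1.0}

    def test_triangular_occupancy(self):
        # satellites at +63.546/5 = 12.7092 Th with 1:2:1 intensities
        peaks = self.mk_series(11_699.0, 5, {0: 1.0, 1: 2.0, 2: 1.0})
        dist = detect_adduct_series(peaks, 5, 63.546, 4)
        assert dist.probs == pytest.approx({0: 0.25, 1: 0.5, 2: 0.25})

    def test_dominant_single_copper(self):
        peaks = self.mk_series(12_112.0, 5, {0: 0.5, 1: 8.0, 2: 0.3})
        dist = detect_adduct_series(peaks, 5, 63.546, 3)
        assert dist.mode == 1

    def test_gap_in_series_scores_zero(self):
        peaks = self.mk_series(11_699.0, 5, {0: 1.0, 2: 1.0})
        dist = detect_adduct_series(peaks, 5, 63.546, 3)
        assert dist.probs[1] == 0.0
        assert dist.probs[0] == pytest.approx(0.5)

    def test_empty_list_raises(self):
        with pytest.raises(ValueError, match="anchor"):
            detect_adduct_series(PeakList([]), 5, 63.546, 2)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        intensities=st.lists(
            st.floats(min_value=0.01, max_value=100.0), min_size=1, max_size=5
        )
    )
    def test_normalization_property(self, intensities):
        peaks = self.mk_series(
            11_699.0, 5, {k: v for k, v in enumerate(intensities)}
        )
        dist = detect_adduct_series(peaks, 5, 63.546, len(intensities) - 1)
        assert sum(dist.probs.values()) == pytest.approx(1.0, abs=1e-9)


class TestOccupancyInvariants:
    def test_keys_must_be_contiguous(self):
        with pytest.raises(ValueError):
            OccupancyDistribution({0: 0.5, 2: 0.5})

    def test_must_sum_to_one(self):
        with pytest.raises(ValueError):
            OccupancyDistribution({0: 0.5, 1: 0.6})

    def test_displaced_proton_convention(self):
        assert copper_adduct_delta(0) == pytest.approx(63.546)
        assert copper_adduct_delta(2) == pytest.approx(61.530)
        with pytest.raises(ValueError):
            copper_adduct_delta(3)
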