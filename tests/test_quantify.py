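"""Calibration and quantification tests with hand-computed oracles."""

import numpy as np
import pytest

from nanotrace import (
    AcquisitionSettings,
    IonicCalibration,
    ParticleEvent,
    ParticlePopulation,
    TimeTrace,
    blank_subtract,
    concentrations,
    detection_limits,
    event_mass,
    fit_ionic_calibration,
    mass_equivalent_diameter,
    mass_to_counts,
    sphere_mass,
    transport_efficiency_frequency,
    transport_efficiency_mass,
)
from nanotrace.types import SampleResult, TransportEfficiency

GOLD_60NM_MASS = 2.185e-15  # g; (pi/6) * (60e-7 cm)^3 * 19.32 g/cm^3


def constant_trace(value, n=10, element="Au", day_id="d1"):
    s = AcquisitionSettings(dwell_time=1.0, acquisition_time=float(n), flow_rate=0.5)
    return TimeTrace(np.full(n, value), s, element=element, day_id=day_id)


def make_events(n, integral=100.0):
    return [
        ParticleEvent(start_dwell=3 * i, end_dwell=3 * i + 1, max_intensity=integral,
                      integral=integral, local_baseline=0.0, threshold=1)
        for i in range(n)
    ]


UNIT_SETTINGS = AcquisitionSettings(dwell_time=1.0, acquisition_time=60.0, flow_rate=60000.0)
# flow 60000 mL/min = 1 L/s, so eta * q * t_dwell = eta in consistent units


class TestIonicCalibration:
    def test_exact_line(self):
        pairs = [(0.0, constant_trace(0)), (20.0, constant_trace(40)),
                 (200.0, constant_trace(400))]
        calib = fit_ionic_calibration(pairs)
        assert calib.slope == pytest.approx(2.0)
        assert calib.intercept == pytest.approx(0.0, abs=1e-12)

    def test_duplicate_standards_pooled(self):
        pairs = [(c, constant_trace(int(2 * c))) for c in (0, 20, 200, 0, 20, 200)]
        calib = fit_ionic_calibration(pairs)
        assert calib.n_points == 6
        assert calib.slope == pytest.approx(2.0)

    def test_requires_three_distinct_concentrations_with_zero(self):
        with pytest.raises(ValueError):
            fit_ionic_calibration([(0.0, constant_trace(0)), (20.0, constant_trace(40))])
        with pytest.raises(ValueError):
            fit_ionic_calibration([(5.0, constant_trace(1))] * 3)
        with pytest.raises(ValueError, match="0 ug/L"):
            fit_ionic_calibration(
                [(10.0, constant_trace(20)), (20.0, constant_trace(40)),
                 (200.0, constant_trace(400))]
            )


class TestSphereArithmetic:
    def test_gold_60nm_mass(self):
        assert sphere_mass(60.0, 19.32) == pytest.approx(GOLD_60NM_MASS, rel=1e-3)

    def test_reference_number_concentration(self):
        # 1250 ng/L / 2.185e-15 g = 5.72e8 particles/L
        per_l = 1250e-9 / sphere_mass(60.0, 19.32)
        assert per_l == pytest.approx(5.72e8, rel=1e-3)

    def test_mass_equivalent_diameter_inverts_sphere_mass(self):
        assert mass_equivalent_diameter(GOLD_60NM_MASS, 19.32) == pytest.approx(60.0, rel=1e-3)

    def test_cube_root_scaling(self):
        d1 = mass_equivalent_diameter(1e-15, 10.0)
        assert mass_equivalent_diameter(8e-15, 10.0) == pytest.approx(2 * d1)

    def test_mass_fraction_scaling(self):
        d_full = mass_equivalent_diameter(1e-15, 10.0, 1.0)
        d_half = mass_equivalent_diameter(1e-15, 10.0, 0.5)
        assert d_half / d_full == pytest.approx(0.5 ** (-1 / 3))

    def test_non_positive_mass_rejected(self):
        with pytest.raises(ValueError):
            mass_equivalent_diameter(0.0, 10.0)


class TestTransportEfficiency:
    def test_frequency_identity(self):
        # 60 s at 1 mL/min delivers C_num * 1.0 particles; N_det == delivered -> eta 1
        s = AcquisitionSettings(dwell_time=1e-4, acquisition_time=60.0, flow_rate=1.0)
        pop = ParticlePopulation("Au", density=19.32, number_concentration=5.0)
        trace = TimeTrace(np.zeros(s.n_dwells, dtype=int), s, element="Au")
        eta = transport_efficiency_frequency(trace, pop, s, events=make_events(5))
        assert eta.eta == pytest.approx(1.0)
        assert eta.method == "frequency"

    def test_frequency_requires_particles(self):
        from nanotrace.quantify import NoParticlesError

        s = AcquisitionSettings(dwell_time=1e-4, acquisition_time=60.0, flow_rate=1.0)
        pop = ParticlePopulation("Au", density=19.32, number_concentration=5.0)
        trace = TimeTrace(np.zeros(s.n_dwells, dtype=int), s)
        with pytest.raises(NoParticlesError):
            transport_efficiency_frequency(trace, pop, s, events=[])

    def test_mass_method_identity_and_linearity(self):
        # median particle mass 1e-6 g = 1 ug; S_bar = 1 count; b = 1 -> eta = 1
        pop = ParticlePopulation(
            "X", density=6.0 / np.pi, median_diameter=1e5, number_concentration=1.0
        )
        assert pop.median_particle_mass == pytest.approx(1e-6)
        calib = IonicCalibration(slope=1.0, intercept=0.0)
        events = make_events(1, integral=1.0)
        eta = transport_efficiency_mass(events, pop, calib, UNIT_SETTINGS)
        assert eta.eta == pytest.approx(1.0)
        # doubling b doubles eta at fixed S_bar (capped at the physical bound 1)
        with pytest.raises(ValueError):
            transport_efficiency_mass(
                events, pop, IonicCalibration(slope=2.0, intercept=0.0), UNIT_SETTINGS
            )
        half = transport_efficiency_mass(
            make_events(1, integral=2.0), pop, calib, UNIT_SETTINGS
        )
        assert half.eta == pytest.approx(0.5)
        doubled = transport_efficiency_mass(
            make_events(1, integral=2.0),
            pop,
            IonicCalibration(slope=2.0, intercept=0.0),
            UNIT_SETTINGS,
        )
        assert doubled.eta == pytest.approx(2 * half.eta)


class TestEventMass:
    def test_round_trip_with_simulator_conversion(self, settings):
        calib = IonicCalibration(slope=10.0, intercept=0.0)
        s_counts = mass_to_counts(GOLD_60NM_MASS, 10.0, 0.05, settings)
        recovered = event_mass(s_counts, calib, 0.05, settings)
        assert recovered == pytest.approx(GOLD_60NM_MASS, rel=1e-12)

    def test_unit_identity(self):
        # S_p = b and eta*q*t_dwell = 1 (L units) -> m = 1 ug = 1e-6 g
        calib = IonicCalibration(slope=7.0, intercept=0.0)
        eta = TransportEfficiency(eta=1.0, method="frequency")
        assert event_mass(7.0, calib, eta, UNIT_SETTINGS) == pytest.approx(1e-6)

    def test_monotone_in_integral(self, settings):
        calib = IonicCalibration(slope=10.0, intercept=0.0)
        masses = [event_mass(s, calib, 0.05, settings) for s in (10.0, 20.0, 400.0)]
        assert masses[0] < masses[1] < masses[2]

    def test_requires_positive_slope(self, settings):
        with pytest.raises(ValueError):
            event_mass(10.0, IonicCalibration(slope=0.0, intercept=0.0), 0.05, settings)


class TestConcentrations:
    def test_zero_events(self, settings):
        res = concentrations([], 0.05, settings)
        assert res.number_concentration == 0.0
        assert res.mass_concentration == 0.0

    def test_closed_form_number_concentration(self, settings):
        # 18,750 events / (0.05 * 0.375 mL) = 1e6/mL = 1e9/L = 1e9 per g at 1 g/L
        res = concentrations(make_events(18750), 0.05, settings, dilution=1.0)
        assert res.number_concentration == pytest.approx(1e9)

    def test_dilution_linearity(self, settings):
        full = concentrations(make_events(100), 0.05, settings, dilution=1.0)
        half = concentrations(make_events(100), 0.05, settings, dilution=0.5)
        assert half.number_concentration == pytest.approx(2 * full.number_concentration)


class TestBlankSubtraction:
    def sample(self, num, mass=0.0, element="Au"):
        return SampleResult(element=element, sample_id="s", number_concentration=num,
                            mass_concentration=mass)

    def test_zero_blanks_unchanged(self):
        out = blank_subtract(self.sample(100.0), [self.sample(0.0)])
        assert out.number_concentration == 100.0
        assert not out.floored

    def test_mean_blank_subtracted(self):
        out = blank_subtract(self.sample(100.0), [self.sample(20.0), self.sample(40.0)])
        assert out.number_concentration == pytest.approx(70.0)
        assert out.raw_number_concentration == 100.0

    def test_floor_and_flag(self):
        out = blank_subtract(self.sample(10.0), [self.sample(30.0)])
        assert out.number_concentration == 0.0
        assert out.floored

    def test_no_matching_blank_errors(self):
        with pytest.raises(ValueError):
            blank_subtract(self.sample(10.0), [self.sample(1.0, element="Pb")])


class TestDetectionLimits:
    #: settings/calibration making 1 count == 1 fg of particle mass
    FG_SETTINGS = AcquisitionSettings(dwell_time=1.0, acquisition_time=60.0, flow_rate=60000.0)
    FG_CALIB = IonicCalibration(slope=1e9, intercept=0.0)

    def blanks(self, values, element="Au"):
        return [
            SampleResult(element=element, sample_id=f"b{i}", number_concentration=v,
                         mass_concentration=v)
            for i, v in enumerate(values)
        ]

    def limits(self, blanks_by_day, thresholds):
        days = list(blanks_by_day)
        return detection_limits(
            blanks_by_day, thresholds,
            {d: self.FG_CALIB for d in days}, {d: 1.0 for d in days},
            self.FG_SETTINGS, element="Au",
        )

    def test_identical_blanks_lod_equals_blank(self):
        lim = self.limits({"d1": self.blanks([5.0, 5.0, 5.0])}, {"d1": 1.0})
        assert lim.number_lod == pytest.approx(5.0)
        assert lim.number_loq == pytest.approx(5.0)

    def test_mass_per_particle_lod_is_max_across_days(self):
        lim = self.limits(
            {"d1": self.blanks([1.0, 2.0]), "d2": self.blanks([1.0, 2.0])},
            {"d1": 0.5, "d2": 0.8},
        )
        assert lim.mass_per_particle_lod == pytest.approx(0.8)

    def test_hand_computed_blank_statistics(self):
        # blanks 1..12: mean 6.5, sample SD 3.6056; LOQ = 6.5 + 36.056 = 42.556
        lim = self.limits({"d1": self.blanks(list(range(1, 13)))}, {"d1": 1.0})
        assert lim.number_lod == pytest.approx(6.5 + 3 * 3.605551, rel=1e-5)
        assert lim.number_loq == pytest.approx(6.5 + 10 * 3.605551, rel=1e-5)

    def test_day_pooling_identical_days(self):
        one = self.limits({"d1": self.blanks([1.0, 3.0, 5.0])}, {"d1": 2.0})
        two = self.limits(
            {"d1": self.blanks([1.0, 3.0, 5.0]), "d2": self.blanks([1.0, 3.0, 5.0])},
            {"d1": 2.0, "d2": 2.0},
        )
        assert two.number_lod == pytest.approx(one.number_lod)
        assert two.mass_per_particle_lod == pytest.approx(one.mass_per_particle_lod)

    def test_single_blank_day_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            lim = self.limits(
                {"d1": self.blanks([1.0, 3.0]), "d2": self.blanks([9.0])},
                {"d1": 1.0, "d2": 1.0},
            )
        assert lim.day_ids == ("d1",)
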