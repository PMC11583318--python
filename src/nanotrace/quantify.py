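"""Calibration and conversion of event integrals to masses and concentrations.

The chain is: fit an ionic response (counts/dwell per ug/L) from dissolved
standards; calibrate the transport efficiency eta with a reference nanoparticle
suspension of known size and concentration; convert each event integral S_p to
element mass per particle

    m_p = S_p * eta * q * t_dwell / b

(q the uptake in L/s, b the ionic slope; mass in grams after the ug -> g
conversion at this one boundary), and to a mass-equivalent spherical diameter
under an assumed compound density and element mass fraction. Event counts and
summed masses then give blank-corrected number and mass concentrations per
gram of wet tissue, with per-day blank-derived detection limits.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy import stats

from .detect import DEFAULT_FP_RATE, DEFAULT_GAP_MERGE, DEFAULT_WINDOW, detect_events, rolling_median_baseline
from .types import (
    AcquisitionSettings,
    DetectionLimits,
    IonicCalibration,
    ParticleEvent,
    ParticlePopulation,
    SampleResult,
    TimeTrace,
    TransportEfficiency,
)

__all__ = [
    "fit_ionic_calibration",
    "transport_efficiency_frequency",
    "transport_efficiency_mass",
    "event_mass",
    "mass_to_counts",
    "mass_equivalent_diameter",
    "concentrations",
    "blank_subtract",
    "detection_limits",
    "NoParticlesError",
]


class NoParticlesError(RuntimeError):
    """A reference acquisition contained no detectable particles."""


def mass_to_counts(
    mass_g: float,
    ionic_response: float,
    eta: float,
    settings: AcquisitionSettings,
) -> float:
    """Total counts produced by a particle of element mass ``mass_g`` grams.

    Inverse of :func:`event_mass`'s integral-to-mass conversion:
    ``S = m[ug] * b / (eta * q[L/s] * t_dwell)``.
    """
    return (mass_g * 1e6) * ionic_response / (eta * settings.flow_l_per_s * settings.dwell_time)


def event_mass(
    event: ParticleEvent | float,
    calib: IonicCalibration,
    eta: TransportEfficiency | float,
    settings: AcquisitionSettings,
) -> float:
    """Element mass per particle (g) from a baseline-corrected event integral."""
    if calib.slope <= 0:
        raise ValueError("calibration slope must be > 0")
    integral = event.integral if isinstance(event, ParticleEvent) else float(event)
    eta_val = eta.eta if isinstance(eta, TransportEfficiency) else float(eta)
    m_ug = integral * eta_val * settings.flow_l_per_s * settings.dwell_time / calib.slope
    return m_ug * 1e-6


def mass_equivalent_diameter(
    mass_g: float, density: float, element_mass_fraction: float = 1.0
) -> float:
    """Diameter (nm) of the sphere of the assumed compound holding this element mass.

    d = (6 (m/f) / (pi rho))^(1/3); a 2.185 fg Au mass at rho = 19.32 g/cm^3
    and f = 1 maps back to 60 nm.
    """
    if mass_g <= 0:
        raise ValueError("mass must be > 0")
    if density <= 0:
        raise ValueError("density must be > 0")
    if not 0 < element_mass_fraction <= 1:
        raise ValueError("element_mass_fraction must be in (0, 1]")
    compound_mass = mass_g / element_mass_fraction
    d_cm = (6.0 * compound_mass / (math.pi * density)) ** (1.0 / 3.0)
    return d_cm * 1e7


def fit_ionic_calibration(
    standard_traces: list[tuple[float, TimeTrace]],
) -> IonicCalibration:
    """OLS line of mean counts per dwell vs standard concentration (ug/L).

    Start-of-day and end-of-day standards at the same concentration are simply
    pooled: every (concentration, trace) pair contributes one point.
    """
    if len(standard_traces) < 3:
        raise ValueError("calibration requires >= 3 standard traces")
    concs = np.array([c for c, _ in standard_traces], dtype=float)
    if len(np.unique(concs)) < 3:
        raise ValueError("calibration requires >= 3 distinct concentrations")
    if not np.any(concs == 0):
        raise ValueError("calibration requires a 0 ug/L (blank) standard")
    means = np.array([float(np.mean(t.counts)) for _, t in standard_traces])
    fit = stats.linregress(concs, means)
    resid = means - (fit.intercept + fit.slope * concs)
    dof = max(len(concs) - 2, 1)
    first = standard_traces[0][1]
    return IonicCalibration(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        element=first.element,
        day_id=first.day_id,
        slope_se=float(fit.stderr),
        residual_se=float(np.sqrt(np.sum(resid**2) / dof)),
        n_points=len(concs),
    )


def _detect(trace: TimeTrace, window: int, fp_rate: float, gap_merge: int):
    baseline = rolling_median_baseline(trace, window=window)
    return detect_events(trace, baseline, fp_rate=fp_rate, gap_merge=gap_merge)


def transport_efficiency_frequency(
    reference_trace: TimeTrace,
    reference: ParticlePopulation,
    settings: AcquisitionSettings,
    window: int = DEFAULT_WINDOW,
    fp_rate: float = DEFAULT_FP_RATE,
    gap_merge: int = DEFAULT_GAP_MERGE,
    events: list[ParticleEvent] | None = None,
) -> TransportEfficiency:
    """Transport efficiency from the detected particle rate of a reference run.

    eta = N_detected / (C_num,ref * q * t_acq). For a monodisperse reference
    the number concentration is the mass concentration divided by the single
    particle mass (e.g. 1250 ng/L of 60 nm Au -> 5.72e8 particles/L).
    """
    if reference.number_concentration <= 0:
        raise ValueError("reference number concentration must be known and > 0")
    if events is None:
        events = _detect(reference_trace, window, fp_rate, gap_merge)
    n_detected = len(events)
    if n_detected == 0:
        raise NoParticlesError(
            "no particles detected in the reference acquisition; the "
            "transport-efficiency calibration is unusable"
        )
    delivered = (
        reference.number_concentration
        * settings.flow_rate
        * (settings.acquisition_time / 60.0)
    )
    return TransportEfficiency(
        eta=n_detected / delivered, method="frequency", day_id=reference_trace.day_id
    )


def transport_efficiency_mass(
    reference_events: list[ParticleEvent],
    reference: ParticlePopulation,
    calib: IonicCalibration,
    settings: AcquisitionSettings,
) -> TransportEfficiency:
    """Transport efficiency from the mean reference event integral.

    Solves m_ref = S_bar * eta * q * t_dwell / b for eta:
    eta = m_ref * b / (S_bar * q * t_dwell), with m_ref the known single
    particle element mass of the reference.
    """
    if not reference_events:
        raise NoParticlesError("no reference events; mass method unusable")
    s_bar = float(np.mean([e.integral for e in reference_events]))
    if s_bar <= 0:
        raise ValueError("mean reference integral must be > 0")
    m_ref_ug = reference.median_particle_mass * 1e6
    eta = m_ref_ug * calib.slope / (s_bar * settings.flow_l_per_s * settings.dwell_time)
    return TransportEfficiency(eta=eta, method="mass")


def concentrations(
    events: list[ParticleEvent],
    eta: TransportEfficiency | float,
    settings: AcquisitionSettings,
    dilution: float = 1.0,
    calib: IonicCalibration | None = None,
    element: str = "",
    sample_id: str = "",
    day_id: str = "",
) -> SampleResult:
    """Particle number and mass concentrations per gram of wet tissue.

    Number concentration per litre of digest is ``n / (eta * q * t_acq)``;
    division by the dilution (grams of tissue per litre, default 1 g/L)
    converts to a per-gram-tissue basis. The mass concentration (ng/g) uses
    the sum of per-event masses and therefore needs the ionic calibration.
    """
    if dilution <= 0:
        raise ValueError("dilution must be > 0")
    eta_val = eta.eta if isinstance(eta, TransportEfficiency) else float(eta)
    analyzed_ml = eta_val * settings.flow_rate * (settings.acquisition_time / 60.0)
    n = len(events)
    number_per_l = n / analyzed_ml * 1000.0  # mL -> L
    number_per_g = number_per_l / dilution
    if calib is not None and n > 0:
        total_mass_g = sum(event_mass(e, calib, eta_val, settings) for e in events)
        mass_per_l_ng = total_mass_g * 1e9 / (analyzed_ml / 1000.0)
        mass_per_g = mass_per_l_ng / dilution
    else:
        mass_per_g = 0.0
    return SampleResult(
        element=element,
        sample_id=sample_id,
        day_id=day_id,
        n_events=n,
        number_concentration=number_per_g,
        mass_concentration=mass_per_g,
        dilution=dilution,
    )


def blank_subtract(sample: SampleResult, blanks: list[SampleResult]) -> SampleResult:
    """Subtract the mean procedural-blank concentrations, flooring at zero.

    Blanks must match the sample's element. Pre-subtraction values are kept on
    the result; a blank mean exceeding the sample floors the result at 0 and
    sets ``floored``.
    """
    matching = [b for b in blanks if b.element == sample.element]
    if not matching:
        raise ValueError(f"no procedural blanks for element {sample.element!r}")
    blank_num = float(np.mean([b.number_concentration for b in matching]))
    blank_mass = float(np.mean([b.mass_concentration for b in matching]))
    num = sample.number_concentration - blank_num
    mass = sample.mass_concentration - blank_mass
    floored = num < 0 or mass < 0
    out = SampleResult(
        element=sample.element,
        sample_id=sample.sample_id,
        day_id=sample.day_id,
        n_events=sample.n_events,
        number_concentration=max(num, 0.0),
        mass_concentration=max(mass, 0.0),
        dilution=sample.dilution,
        raw_number_concentration=sample.number_concentration,
        raw_mass_concentration=sample.mass_concentration,
        blank_subtracted=True,
        floored=floored,
    )
    return out


def detection_limits(
    blank_results_by_day: dict[str, list[SampleResult]],
    thresholds_by_day: dict[str, float],
    calibrations_by_day: dict[str, IonicCalibration],
    etas_by_day: dict[str, TransportEfficiency | float],
    settings: AcquisitionSettings,
    element: str = "",
) -> DetectionLimits:
    """Blank-derived detection/quantification limits pooled across days.

    Per day, the concentration LOD is mean + 3 SD (LOQ: mean + 10 SD) of that
    day's procedural-blank concentrations; the final concentration limits are
    the means across days. The mass-per-particle LOD per day converts that
    day's intensity threshold to mass via the day's calibration, and the final
    value is the maximum across days (keeps false-negative rates comparable).
    Days with fewer than two blanks have no defined SD and are skipped with a
    warning.
    """
    if not blank_results_by_day:
        raise ValueError("at least one day of blanks is required")
    day_num_lod, day_num_loq, day_mass_lod, day_mass_loq = [], [], [], []
    day_mpp_lod, used_days = [], []
    for day, blanks in blank_results_by_day.items():
        if len(blanks) < 2:
            warnings.warn(
                f"day {day!r} has {len(blanks)} blank(s); SD undefined, day skipped",
                stacklevel=2,
            )
            continue
        nums = np.array([b.number_concentration for b in blanks], dtype=float)
        masses = np.array([b.mass_concentration for b in blanks], dtype=float)
        day_num_lod.append(nums.mean() + 3.0 * nums.std(ddof=1))
        day_num_loq.append(nums.mean() + 10.0 * nums.std(ddof=1))
        day_mass_lod.append(masses.mean() + 3.0 * masses.std(ddof=1))
        day_mass_loq.append(masses.mean() + 10.0 * masses.std(ddof=1))
        thr = thresholds_by_day[day]
        calib = calibrations_by_day[day]
        eta = etas_by_day[day]
        day_mpp_lod.append(event_mass(float(thr), calib, eta, settings) * 1e15)  # g -> fg
        used_days.append(day)
    if not used_days:
        raise ValueError("no day had >= 2 blanks; detection limits undefined")
    return DetectionLimits(
        element=element,
        mass_per_particle_lod=float(np.max(day_mpp_lod)),
        number_lod=float(np.mean(day_num_lod)),
        number_loq=float(np.mean(day_num_loq)),
        mass_lod=float(np.mean(day_mass_lod)),
        mass_loq=float(np.mean(day_mass_loq)),
        day_ids=tuple(used_days),
    )
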