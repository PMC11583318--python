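"""Synthetic raw traces, calibration standards, and survey datasets.

Everything downstream of the instrument is testable against these generators:
each one returns its ground truth (event list and masses, true transport
efficiency, true survey effects) alongside the synthetic data.

A raw trace is built as a per-dwell expected intensity — Poisson background
(optionally with a slow sinusoidal drift) plus the counts of each particle
transient spread over a few dwells with triangular weights — realized as one
Poisson draw per dwell. Particle arrivals form a homogeneous Poisson process
over the acquisition; coincident (overlapping) events are allowed and recorded
in the ground truth so the detector's merge behaviour can be probed.
"""

from __future__ import annotations

import numpy as np

from .quantify import mass_to_counts
from .types import (
    AcquisitionSettings,
    GroundTruth,
    NoiseModel,
    ParticlePopulation,
    SimulatedEvent,
    TimeTrace,
    sphere_mass,
)

__all__ = [
    "expected_event_count",
    "simulate_trace",
    "simulate_ionic_standard",
    "simulate_survey",
    "SURVEY_ELEMENTS",
]

#: elements surveyed by default (engineered or incidental particles exist for each)
SURVEY_ELEMENTS = ("Ag", "Al", "Ba", "Ce", "Cu", "Fe", "Mn", "Pb", "Si", "Ti", "Zr")


def _check_seed(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if not isinstance(seed, (int, np.integer)) or isinstance(seed, bool):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    return np.random.default_rng(int(seed))


def expected_event_count(
    settings: AcquisitionSettings,
    number_concentration: float,
    transport_efficiency: float,
) -> float:
    """Expected detected-particle count: C_num * q * t_acq * eta.

    ``number_concentration`` in particles/mL, ``flow_rate`` in mL/min; e.g.
    1e6 /mL * 0.5 mL/min * 0.75 min * 0.05 = 18,750 events in 45 s.
    """
    return (
        number_concentration
        * settings.flow_rate
        * (settings.acquisition_time / 60.0)
        * transport_efficiency
    )


def _triangular_weights(span: int) -> np.ndarray:
    """Symmetric triangular split of one particle's counts over ``span`` dwells."""
    j = np.arange(1, span + 1, dtype=float)
    w = np.minimum(j, span + 1 - j)
    return w / w.sum()


def _background(settings: AcquisitionSettings, noise: NoiseModel) -> np.ndarray:
    n = settings.n_dwells
    lam = np.full(n, float(noise.baseline_mean))
    if noise.drift_amplitude > 0:
        t = np.arange(n) * settings.dwell_time
        lam = lam + noise.drift_amplitude * np.sin(2 * np.pi * t / noise.drift_period)
    return np.clip(lam, 0.0, None)


def simulate_trace(
    settings: AcquisitionSettings,
    population: ParticlePopulation,
    noise: NoiseModel,
    transport_efficiency: float,
    ionic_response: float,
    seed: int | np.random.Generator,
    span_range: tuple[int, int] = (3, 7),
    n_events: int | None = None,
    deterministic: bool = False,
    element: str | None = None,
    sample_id: str = "",
    day_id: str = "",
) -> tuple[TimeTrace, GroundTruth]:
    """Simulate one acquisition of a particle suspension.

    Parameters
    ----------
    transport_efficiency : fraction of nebulized particles reaching the plasma,
        in (0, 1].
    ionic_response : detector sensitivity in counts/dwell per (ug/L), as fitted
        from dissolved standards; a particle of element mass ``m`` deposits
        ``m * b / (eta * q * t_dwell)`` total counts (consistent units).
    span_range : inclusive range of transient durations in dwells.
    n_events : force this exact event count instead of the Poisson draw
        (useful for constructing noiseless single-event fixtures).
    deterministic : write expected per-dwell intensities instead of Poisson
        realizations (exact, generally non-integer counts).

    Returns the trace and a :class:`GroundTruth` listing every injected event.
    """
    rng = _check_seed(seed)
    if not 0 < transport_efficiency <= 1:
        raise ValueError("transport_efficiency must be in (0, 1]")
    if ionic_response <= 0:
        raise ValueError("ionic_response must be > 0")
    lo, hi = span_range
    if not (1 <= lo <= hi):
        raise ValueError("span_range must satisfy 1 <= lo <= hi")
    n_dwells = settings.n_dwells

    mu = expected_event_count(settings, population.number_concentration, transport_efficiency)
    if mu > n_dwells:
        raise ValueError(
            f"impossible geometry: expected {mu:.0f} events exceeds the "
            f"{n_dwells} available dwells; dilute the population or shorten "
            "the acquisition"
        )
    n = int(n_events) if n_events is not None else int(rng.poisson(mu))

    lam = _background(settings, noise)
    events: list[SimulatedEvent] = []
    if n > 0:
        spans = rng.integers(lo, hi + 1, size=n)
        starts = rng.integers(0, np.maximum(n_dwells - spans, 1), size=n)
        sigma = np.log(population.geometric_sd)
        diam = population.median_diameter * np.exp(rng.normal(0.0, sigma, size=n))
        masses = sphere_mass(1.0, population.density, population.element_mass_fraction) * diam**3
        order = np.argsort(starts)
        for idx in order:
            start, span, mass = int(starts[idx]), int(spans[idx]), float(masses[idx])
            total_counts = mass_to_counts(
                mass, ionic_response, transport_efficiency, settings
            )
            w = _triangular_weights(span)
            lam[start : start + span] += total_counts * w
            events.append(SimulatedEvent(start_dwell=start, span=span, mass=mass))

    counts = lam if deterministic else rng.poisson(lam).astype(np.int64)
    trace = TimeTrace(
        counts=counts,
        settings=settings,
        element=element if element is not None else population.element,
        sample_id=sample_id,
        day_id=day_id,
    )
    truth = GroundTruth(
        events=events,
        true_number_concentration=population.number_concentration,
        true_transport_efficiency=transport_efficiency,
        true_ionic_response=ionic_response,
    )
    return trace, truth


def simulate_ionic_standard(
    settings: AcquisitionSettings,
    concentration: float,
    ionic_response: float,
    noise: NoiseModel,
    seed: int | np.random.Generator,
    element: str = "",
    sample_id: str = "",
    day_id: str = "",
) -> TimeTrace:
    """Simulate a dissolved calibration standard of the given concentration (ug/L).

    Mean counts per dwell are ``baseline_mean + ionic_response * concentration``,
    realized per dwell as a Poisson draw.
    """
    rng = _check_seed(seed)
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    lam = _background(settings, noise) + ionic_response * concentration
    counts = rng.poisson(lam).astype(np.int64)
    return TimeTrace(
        counts=counts, settings=settings, element=element,
        sample_id=sample_id or f"std-{concentration:g}", day_id=day_id,
    )


# -- survey generator ---------------------------------------------------------

#: class shares matching the surveyed coastline (47 farms, 18 anthropogenic,
#: 4 natural of 69 locations)
CLASS_SHARES = {"farm": 47 / 69, "anthropogenic": 18 / 69, "natural": 4 / 69}

_SEASON_OF_MONTH = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
}


def _assign_classes(n_locations: int, rng: np.random.Generator) -> np.ndarray:
    n_anthro = max(1, round(n_locations * CLASS_SHARES["anthropogenic"]))
    n_natural = max(1, round(n_locations * CLASS_SHARES["natural"]))
    n_farm = n_locations - n_anthro - n_natural
    if n_farm < 0:
        raise ValueError("n_locations too small to hold all three classes")
    classes = np.array(
        ["anthropogenic"] * n_anthro + ["natural"] * n_natural + ["farm"] * n_farm
    )
    rng.shuffle(classes)
    return classes


def _effect(effects, group: str, element: str) -> float:
    """Resolve a per-group effect that may be scalar or per-element."""
    if effects is None:
        return 1.0
    val = effects.get(group, 1.0)
    if isinstance(val, dict):
        return float(val.get(element, 1.0))
    return float(val)


def simulate_survey(
    n_locations: int = 69,
    elements: tuple[str, ...] = SURVEY_ELEMENTS,
    class_effects: dict | None = None,
    season_effects: dict | None = None,
    censoring_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
    n_parallels: int = 3,
    median_number_concentration: float | dict = 1e7,  # particles per g
    gsd_location: float = 3.0,
    gsd_parallel: float = 1.2,
    mean_particle_mass_ng: float | dict = 1e-6,  # ~1 fg per particle
    impact_gsd: float = 2.0,
):
    """Generate a multi-location survey with known effects and censoring.

    Per-location, per-element number concentrations are lognormal around an
    element median, multiplied by the location class effect and the season
    effect; each location carries ``n_parallels`` replicate preparations with
    their own (smaller) lognormal scatter. Mass concentrations follow as
    number concentration times a mean per-particle mass. The per-element LOD
    is placed at the ``censoring_rate`` quantile of the base (effect-free)
    location distribution, so that fraction of baseline locations is expected
    to fall below it; values below the LOD are flagged censored, not removed.

    ``class_effects`` / ``season_effects`` map a group name to a multiplier,
    either scalar or per-element, e.g. ``{"anthropogenic": {"Pb": 10.0}}``.
    Class effects act as a shared source: every location draws one impact
    intensity ``w ~ LN(0, ln(impact_gsd))`` and the applied multiplier is
    ``effect ** w``, so elements elevated by the same source co-vary within a
    location and impacted sites differ in degree, as real hotspots do.
    Season effects are applied as plain multipliers.

    Returns ``(SurveyTable, ground_truth_dict)``.
    """
    from .survey import SurveyTable  # local import: survey does not import simulate
    from scipy.stats import norm
    import pandas as pd

    rng = _check_seed(seed)
    if n_locations < 2:
        raise ValueError("n_locations must be >= 2")
    if not elements:
        raise ValueError("element list must not be empty")
    if not 0.0 <= censoring_rate <= 1.0:
        raise ValueError("censoring_rate must be in [0, 1]")

    elements = tuple(elements)
    medians = {
        el: (median_number_concentration[el]
             if isinstance(median_number_concentration, dict)
             else float(median_number_concentration))
        for el in elements
    }
    mpp = {
        el: (mean_particle_mass_ng[el]
             if isinstance(mean_particle_mass_ng, dict)
             else float(mean_particle_mass_ng))
        for el in elements
    }

    classes = _assign_classes(n_locations, rng)
    months = rng.integers(1, 13, size=n_locations)
    seasons = np.array([_SEASON_OF_MONTH[m] for m in months])
    shell = np.clip(rng.normal(4.0, 0.8, size=n_locations), 2.4, 7.4)

    sig_loc = np.log(gsd_location)
    sig_par = np.log(gsd_parallel)
    # one impact intensity per location, shared across all elements the
    # location's class elevates (graded hotspots, co-varying elements)
    impact = np.exp(rng.normal(0.0, np.log(max(impact_gsd, 1.0)), size=n_locations))
    locations = [f"L{i:03d}" for i in range(n_locations)]
    index = pd.MultiIndex.from_product(
        [locations, range(1, n_parallels + 1)], names=["location", "parallel"]
    )

    number = pd.DataFrame(index=index, columns=list(elements), dtype=float)
    mass = pd.DataFrame(index=index, columns=list(elements), dtype=float)
    for j, el in enumerate(elements):
        loc_factor = np.exp(rng.normal(0.0, sig_loc, size=n_locations))
        class_eff = np.array([_effect(class_effects, c, el) for c in classes])
        season_eff = np.array([_effect(season_effects, s, el) for s in seasons])
        eff = class_eff**impact * season_eff
        loc_mean = medians[el] * eff * loc_factor
        par = np.exp(rng.normal(0.0, sig_par, size=(n_locations, n_parallels)))
        vals = (loc_mean[:, None] * par).ravel()
        number[el] = vals
        mass_noise = np.exp(rng.normal(0.0, np.log(1.1), size=vals.size))
        mass[el] = vals * mpp[el] * mass_noise

    z = norm.ppf(censoring_rate)  # -inf at 0, +inf at 1
    lod_number = pd.Series(
        {el: float(medians[el] * np.exp(z * sig_loc)) for el in elements}
    )
    lod_mass = lod_number * pd.Series(mpp)

    metadata = pd.DataFrame(
        {
            "classification": classes,
            "season": seasons,
            "sampling_month": months,
            "shell_length": shell,
        },
        index=pd.Index(locations, name="location"),
    )
    table = SurveyTable(
        number=number, mass=mass, metadata=metadata,
        lod_number=lod_number, lod_mass=lod_mass,
    )
    truth = {
        "medians": medians,
        "mean_particle_mass_ng": mpp,
        "class_effects": class_effects or {},
        "season_effects": season_effects or {},
        "gsd_location": gsd_location,
        "gsd_parallel": gsd_parallel,
        # analytic mean of a location mean in the effect-free stratum:
        # E[median * LN(0,s_loc) * mean_p LN(0,s_par)] = median*exp(s_loc^2/2)*exp(s_par^2/2)
        "analytic_location_mean": {
            el: medians[el] * np.exp(sig_loc**2 / 2) * np.exp(sig_par**2 / 2)
            for el in elements
        },
    }
    return table, truth
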