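"""Domain containers for single-particle ICP-MS data reduction.

Unit conventions used throughout the package (converted only at interfaces):

* time in seconds (``dwell_time``, ``acquisition_time``)
* sample uptake ``flow_rate`` in mL/min (as measured gravimetrically)
* particle masses internally in grams
* ionic response (calibration slope) in counts per dwell per (ug/L)
* concentrations per litre of digest; per gram of tissue after dividing by
  the dilution factor (grams of tissue per litre of digest)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AcquisitionSettings",
    "ParticlePopulation",
    "NoiseModel",
    "SimulatedEvent",
    "GroundTruth",
    "TimeTrace",
    "BaselineEstimate",
    "ParticleEvent",
    "IonicCalibration",
    "TransportEfficiency",
    "SampleResult",
    "DetectionLimits",
    "TotalResult",
    "sphere_mass",
]


def sphere_mass(diameter_nm: float, density: float, mass_fraction: float = 1.0) -> float:
    """Element mass (g) of a spherical particle.

    Parameters
    ----------
    diameter_nm : sphere diameter in nm.
    density : compound density in g/cm^3.
    mass_fraction : element mass fraction of the compound, in (0, 1].

    A 60 nm gold sphere (rho = 19.32 g/cm^3, f = 1) weighs 2.185e-15 g.
    """
    d_cm = diameter_nm * 1e-7
    return (math.pi / 6.0) * d_cm**3 * density * mass_fraction


@dataclass(frozen=True)
class AcquisitionSettings:
    """Instrument acquisition settings: 100 us dwell, 45 s runs by default."""

    dwell_time: float = 1e-4  # s
    acquisition_time: float = 45.0  # s
    flow_rate: float = 0.5  # mL/min sample uptake

    def __post_init__(self) -> None:
        if self.dwell_time <= 0:
            raise ValueError("dwell_time must be > 0")
        if self.acquisition_time < self.dwell_time:
            raise ValueError("acquisition_time must be >= dwell_time")
        if self.flow_rate <= 0:
            raise ValueError("flow_rate must be > 0")

    @property
    def n_dwells(self) -> int:
        return int(math.floor(self.acquisition_time / self.dwell_time))

    @property
    def flow_l_per_s(self) -> float:
        """Uptake converted to litres per second."""
        return self.flow_rate / 60000.0


@dataclass(frozen=True)
class ParticlePopulation:
    """A lognormal particle population of one element-bearing compound.

    ``number_concentration`` is particles per mL of the presented suspension.
    ``median_diameter`` (nm) and ``geometric_sd`` parameterize the size
    distribution; ``geometric_sd = 1`` is monodisperse.
    """

    element: str
    density: float  # g/cm^3 of the particle compound
    element_mass_fraction: float = 1.0
    median_diameter: float = 60.0  # nm
    geometric_sd: float = 1.0
    number_concentration: float = 0.0  # particles per mL

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("density must be > 0")
        if not 0 < self.element_mass_fraction <= 1:
            raise ValueError("element_mass_fraction must be in (0, 1]")
        if self.median_diameter <= 0:
            raise ValueError("median_diameter must be > 0")
        if self.geometric_sd < 1:
            raise ValueError("geometric_sd must be >= 1")
        if self.number_concentration < 0:
            raise ValueError("number_concentration must be >= 0")

    @property
    def median_particle_mass(self) -> float:
        """Element mass (g) of the median-diameter particle."""
        return sphere_mass(self.median_diameter, self.density, self.element_mass_fraction)


@dataclass(frozen=True)
class NoiseModel:
    """Poisson background: mean counts per dwell plus optional sinusoidal drift."""

    baseline_mean: float = 1.0  # counts per dwell
    drift_amplitude: float = 0.0  # counts per dwell
    drift_period: float = 10.0  # s

    def __post_init__(self) -> None:
        if self.baseline_mean < 0:
            raise ValueError("baseline_mean must be >= 0")
        if self.drift_amplitude > self.baseline_mean:
            raise ValueError("drift must keep the instantaneous mean >= 0")
        if self.drift_period <= 0:
            raise ValueError("drift_period must be > 0")


@dataclass(frozen=True)
class SimulatedEvent:
    start_dwell: int
    span: int  # dwells
    mass: float  # element grams


@dataclass
class GroundTruth:
    """What the simulator actually put into a trace."""

    events: list[SimulatedEvent]
    true_number_concentration: float  # particles per mL
    true_transport_efficiency: float
    true_ionic_response: float  # counts/dwell per (ug/L)

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def n_coincident(self) -> int:
        """Events whose spans touch or overlap another event's span."""
        if len(self.events) < 2:
            return 0
        ev = sorted(self.events, key=lambda e: e.start_dwell)
        hit = [False] * len(ev)
        for i in range(len(ev) - 1):
            if ev[i].start_dwell + ev[i].span > ev[i + 1].start_dwell:
                hit[i] = hit[i + 1] = True
        return sum(hit)


@dataclass
class TimeTrace:
    """One acquisition: counts per dwell plus identity metadata."""

    counts: np.ndarray
    settings: AcquisitionSettings
    element: str = ""
    sample_id: str = ""
    day_id: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if len(self.counts) != self.settings.n_dwells:
            raise ValueError(
                f"trace length {len(self.counts)} does not match settings "
                f"({self.settings.n_dwells} dwells)"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def __len__(self) -> int:
        return len(self.counts)


@dataclass
class BaselineEstimate:
    """Per-dwell background estimate (lambda-hat trajectory)."""

    values: np.ndarray
    window: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("baseline values must be >= 0")


@dataclass(frozen=True)
class ParticleEvent:
    """One detected transient: inclusive dwell span, peak height and integral."""

    start_dwell: int
    end_dwell: int
    max_intensity: float  # I_max, raw counts at the peak dwell
    integral: float  # S_p, baseline-corrected counts
    local_baseline: float  # counts per dwell at the peak
    threshold: int  # counts; Poisson criterion at the local baseline

    def __post_init__(self) -> None:
        if self.end_dwell < self.start_dwell:
            raise ValueError("end_dwell must be >= start_dwell")

    @property
    def span(self) -> int:
        return self.end_dwell - self.start_dwell + 1


@dataclass(frozen=True)
class IonicCalibration:
    """Ordinary least-squares line of mean counts/dwell vs concentration (ug/L)."""

    slope: float  # b, counts/dwell per (ug/L)
    intercept: float  # a, counts/dwell
    element: str = ""
    day_id: str = ""
    slope_se: float = float("nan")
    residual_se: float = float("nan")
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.n_points and self.n_points < 3:
            raise ValueError("calibration requires >= 3 points")


@dataclass(frozen=True)
class TransportEfficiency:
    """Fraction of nebulized sample reaching the plasma."""

    eta: float
    method: str  # "frequency" | "mass"
    day_id: str = ""

    def __post_init__(self) -> None:
        if 1.0 < self.eta <= 1.0 + 1e-9:  # numerical grace at the physical bound
            object.__setattr__(self, "eta", 1.0)
        if not 0 < self.eta <= 1:
            raise ValueError(f"eta must be in (0, 1], got {self.eta}")
        if self.method not in ("frequency", "mass"):
            raise ValueError("method must be 'frequency' or 'mass'")


@dataclass
class SampleResult:
    """Per-sample, per-element particle concentrations on a wet-tissue basis."""

    element: str
    sample_id: str
    day_id: str = ""
    n_events: int = 0
    number_concentration: float = 0.0  # particles per g wet tissue
    mass_concentration: float = 0.0  # ng per g wet tissue
    dilution: float = 1.0  # g tissue per L of digest
    # pre-blank-subtraction values, kept for audit
    raw_number_concentration: float | None = None
    raw_mass_concentration: float | None = None
    blank_subtracted: bool = False
    floored: bool = False  # blank exceeded sample; result floored at 0
    censored_number: bool = False
    censored_mass: bool = False
    lod_number: float | None = None
    lod_mass: float | None = None

    def __post_init__(self) -> None:
        if self.dilution <= 0:
            raise ValueError("dilution must be > 0")
        if self.n_events < 0:
            raise ValueError("n_events must be >= 0")


@dataclass
class DetectionLimits:
    """Blank-derived limits for one element.

    Concentration limits are means across days; the mass-per-particle limit is
    the maximum across days so false-negative rates stay comparable.
    """

    element: str
    mass_per_particle_lod: float  # fg
    number_lod: float  # particles per g
    number_loq: float
    mass_lod: float  # ng per g
    mass_loq: float
    day_ids: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for lod, loq in ((self.number_lod, self.number_loq), (self.mass_lod, self.mass_loq)):
            if not (loq >= lod >= 0):
                raise ValueError("limits must satisfy LOQ >= LOD >= 0")


@dataclass
class TotalResult:
    """Total element concentration from full digestion, wet-weight basis."""

    element: str
    sample_id: str
    concentration: float  # ng per g wet weight
    dry_weight_fraction: float
    lod: float | None = None  # ng per g wet weight
    censored: bool = False
    flagged_below_intercept: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.dry_weight_fraction <= 1:
            raise ValueError("dry_weight_fraction must be in (0, 1]")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
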