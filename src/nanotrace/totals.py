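"""Total element content from full digestion, and particle/total comparisons.

Digest intensities are converted through the ionic calibration to a dry-weight
concentration and back-calculated to a wet-weight basis with the dry-weight
fraction. Detection limits follow the 3-sigma procedural-blank convention
(twelve blanks by default, six for silver). Particle fractions and
particle-total correlations exclude censored values: any censored operand
censors the derived quantity.
"""

from __future__ import annotations

import numpy as np

from .types import IonicCalibration, SampleResult, TotalResult

__all__ = [
    "total_concentration",
    "total_lod",
    "particle_fraction",
    "particle_total_correlation",
    "AG_BLANK_COUNT",
    "DEFAULT_BLANK_COUNT",
]

DEFAULT_BLANK_COUNT = 12
AG_BLANK_COUNT = 6  # silver: fewer usable procedural blanks


def total_concentration(
    intensity: float,
    calib: IonicCalibration,
    digest_mass: float,
    final_mass: float,
    dry_weight_fraction: float,
    sample_id: str = "",
    lod: float | None = None,
) -> TotalResult:
    """Wet-weight total concentration from a digest intensity.

    The digest of ``digest_mass`` grams of freeze-dried tissue is made up to
    ``final_mass`` grams (== mL at unit density), so the dry-weight
    concentration is ``(intensity - a)/b * final_mass / digest_mass`` and the
    wet-weight value follows by multiplying with the dry-weight fraction.
    Concentration units track the calibration: a slope in counts per (ug/L)
    gives ug/L in the digest, i.e. ng/g tissue for a 1 g / 25 mL digest scaled
    accordingly; callers keep units consistent with their calibration.
    An intensity below the calibration intercept yields 0 and a flag.
    """
    if digest_mass <= 0:
        raise ValueError("digest_mass must be > 0")
    if calib.slope <= 0:
        raise ValueError("calibration slope must be > 0")
    digest_conc = (intensity - calib.intercept) / calib.slope
    flagged = digest_conc < 0
    digest_conc = max(digest_conc, 0.0)
    per_g_dry = digest_conc * final_mass / digest_mass
    per_g_wet = per_g_dry * dry_weight_fraction
    censored = lod is not None and per_g_wet < lod
    return TotalResult(
        element=calib.element,
        sample_id=sample_id,
        concentration=per_g_wet,
        dry_weight_fraction=dry_weight_fraction,
        lod=lod,
        censored=censored,
        flagged_below_intercept=flagged,
    )


def total_lod(blank_values: list[float] | np.ndarray, element: str = "") -> float:
    """Detection limit as 3x the sample standard deviation of procedural blanks.

    Twelve blanks are expected by default, six for Ag; the rule is advisory
    (a warning-free computation needs only >= 2 blanks).
    """
    blanks = np.asarray(blank_values, dtype=float)
    if blanks.size < 2:
        raise ValueError("total LOD requires >= 2 blank values")
    return 3.0 * float(blanks.std(ddof=1))


def expected_blank_count(element: str) -> int:
    return AG_BLANK_COUNT if element == "Ag" else DEFAULT_BLANK_COUNT


def particle_fraction(particle: SampleResult, total: TotalResult) -> float | None:
    """Particulate share of the total element content, in percent.

    ``100 * particle mass concentration / total concentration``; returns None
    when either operand is censored (exclusion rule), raises on a zero total.
    """
    if particle.censored_mass or total.censored:
        return None
    if total.concentration == 0:
        raise ZeroDivisionError("total concentration is zero")
    return 100.0 * particle.mass_concentration / total.concentration


def particle_total_correlation(
    pairs: list[tuple[float, float]] | np.ndarray,
    censored: list[bool] | None = None,
) -> float:
    """Squared Pearson correlation of particle mass vs total concentration.

    ``pairs`` holds (particle, total) per sample; entries flagged censored are
    excluded before the correlation. At least three uncensored pairs are
    required.
    """
    arr = np.asarray(pairs, dtype=float)
    if censored is not None:
        arr = arr[~np.asarray(censored, dtype=bool)]
    if arr.shape[0] < 3:
        raise ValueError("need >= 3 uncensored (particle, total) pairs")
    r = np.corrcoef(arr[:, 0], arr[:, 1])[0, 1]
    return float(r**2)
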