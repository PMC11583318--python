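"""End-to-end orchestration: calibrate -> detect -> quantify -> survey.

`run_pipeline` drives the full chain from a structured-text (YAML) config
listing trace files; `run_synthetic_survey` generates a complete synthetic
campaign with the simulator and pushes it through the same chain, which is
what the smoke tests and the acceptance script exercise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as ntio
from .detect import (
    DEFAULT_FP_RATE,
    DEFAULT_GAP_MERGE,
    DEFAULT_WINDOW,
    detect_events,
    poisson_threshold,
    rolling_median_baseline,
)
from .quantify import (
    blank_subtract,
    concentrations,
    detection_limits,
    fit_ionic_calibration,
    transport_efficiency_frequency,
    transport_efficiency_mass,
)
from .survey import SurveyTable, pca, summarize, ward_cluster, zscore
from .types import AcquisitionSettings, ParticlePopulation, sphere_mass

logger = logging.getLogger("nanotrace")

__all__ = ["RunConfig", "run_pipeline", "run_synthetic_survey"]


@dataclass
class RunConfig:
    """Validated run configuration (see ``RunConfig.from_yaml``)."""

    settings: AcquisitionSettings
    elements: dict[str, dict]  # element -> {density, mass_fraction}
    standards: list[str] = field(default_factory=list)  # trace paths
    references: list[dict] = field(default_factory=list)  # reference NP runs
    blanks: list[str] = field(default_factory=list)
    samples: list[str] = field(default_factory=list)
    window: int = DEFAULT_WINDOW
    fp_rate: float = DEFAULT_FP_RATE
    gap_merge: int = DEFAULT_GAP_MERGE
    dilution: float = 1.0  # g tissue per L digest
    seed: int = 0
    out_dir: str = "nanotrace-out"

    def __post_init__(self) -> None:
        for el, props in self.elements.items():
            if "density" not in props or "mass_fraction" not in props:
                raise ValueError(
                    f"element {el!r} needs 'density' and 'mass_fraction' entries"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        det = raw.get("detection", {})
        return cls(
            settings=AcquisitionSettings(**raw.get("settings", {})),
            elements=raw.get("elements", {}),
            standards=raw.get("standards", []),
            references=raw.get("references", []),
            blanks=raw.get("blanks", []),
            samples=raw.get("samples", []),
            window=int(det.get("window", DEFAULT_WINDOW)),
            fp_rate=float(det.get("fp_rate", DEFAULT_FP_RATE)),
            gap_merge=int(det.get("gap_merge", DEFAULT_GAP_MERGE)),
            dilution=float(raw.get("dilution", 1.0)),
            seed=int(raw.get("seed", 0)),
            out_dir=str(raw.get("out_dir", "nanotrace-out")),
        )


def _detect(trace, config: RunConfig):
    n = len(trace)
    window = config.window
    if window > n:
        window = n if n % 2 else n - 1
    baseline = rolling_median_baseline(trace, window=window)
    events = detect_events(
        trace, baseline, fp_rate=config.fp_rate, gap_merge=config.gap_merge
    )
    return baseline, events


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full chain over the files listed in ``config``.

    Per (element, day): fit the ionic calibration from the standards, detect
    the reference-particle run and calibrate the transport efficiency
    (frequency method; the mass method is computed as a cross-check and
    logged), then detect/quantify every sample and blank, subtract the mean
    blank, and derive per-day detection limits. Elements lacking a calibration
    are skipped with a warning; a missing particle reference refuses
    quantification with an actionable message. Writes events/results CSVs to
    ``config.out_dir`` and returns the result bundle.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- ionic calibrations per (element, day)
    standards: dict[tuple[str, str], list] = {}
    for path in config.standards:
        trace, extra = ntio.read_trace(path)
        if "concentration" not in extra:
            raise ValueError(f"{path}: standard sidecar lacks 'concentration'")
        standards.setdefault((trace.element, trace.day_id), []).append(
            (float(extra["concentration"]), trace)
        )
    calibrations = {key: fit_ionic_calibration(pairs) for key, pairs in standards.items()}
    for (el, day), calib in calibrations.items():
        logger.info(
            "calibration element=%s day=%s slope=%.6g intercept=%.6g", el, day,
            calib.slope, calib.intercept,
        )

    # --- transport efficiency per day from the reference-NP runs
    if not config.references:
        raise ValueError(
            "no reference nanoparticle run configured: quantification needs a "
            "transport-efficiency calibration (add a 'references' entry, e.g. "
            "a 60 nm Au suspension of known concentration)"
        )
    etas: dict[str, object] = {}
    for ref in config.references:
        trace, _ = ntio.read_trace(ref["trace"])
        mass_g = sphere_mass(
            float(ref["diameter_nm"]), float(ref["density"]),
            float(ref.get("mass_fraction", 1.0)),
        )
        number_per_ml = float(ref["mass_concentration_ng_per_l"]) * 1e-9 / mass_g / 1000.0
        population = ParticlePopulation(
            element=trace.element, density=float(ref["density"]),
            element_mass_fraction=float(ref.get("mass_fraction", 1.0)),
            median_diameter=float(ref["diameter_nm"]),
            number_concentration=number_per_ml,
        )
        _, events = _detect(trace, config)
        eta = transport_efficiency_frequency(
            trace, population, config.settings, events=events
        )
        etas[trace.day_id] = eta
        calib = calibrations.get((trace.element, trace.day_id))
        if calib is not None and events:
            eta_mass = transport_efficiency_mass(events, population, calib, config.settings)
            logger.info(
                "transport efficiency day=%s frequency=%.4g mass=%.4g", trace.day_id,
                eta.eta, eta_mass.eta,
            )
        else:
            logger.info("transport efficiency day=%s frequency=%.4g", trace.day_id, eta.eta)

    # --- detect + quantify samples and blanks
    def quantify_file(path):
        trace, extra = ntio.read_trace(path)
        key = (trace.element, trace.day_id)
        if key not in calibrations:
            logger.warning("no calibration for element=%s day=%s; skipped", *key)
            return None, None, None
        if trace.day_id not in etas:
            logger.warning("no transport efficiency for day=%s; skipped", trace.day_id)
            return None, None, None
        baseline, events = _detect(trace, config)
        result = concentrations(
            events, etas[trace.day_id], config.settings, dilution=config.dilution,
            calib=calibrations[key], element=trace.element,
            sample_id=trace.sample_id, day_id=trace.day_id,
        )
        return result, events, (trace, extra, baseline)

    blanks_by_key: dict[tuple[str, str], list] = {}
    thresholds_by_day: dict[str, float] = {}
    for path in config.blanks:
        result, events, ctx = quantify_file(path)
        if result is None:
            continue
        blanks_by_key.setdefault((result.element, result.day_id), []).append(result)
        trace, _, _ = ctx
        # blanks are (near) particle-free, so the plain mean is the day's rate
        lam = float(np.mean(trace.counts))
        thresholds_by_day.setdefault(
            result.day_id,
            poisson_threshold(lam, config.fp_rate, config.settings.dwell_time),
        )

    results, event_frames, sample_meta = [], [], []
    for path in config.samples:
        result, events, ctx = quantify_file(path)
        if result is None:
            continue
        trace, extra, _ = ctx
        matching = blanks_by_key.get((result.element, result.day_id), [])
        if matching:
            result = blank_subtract(result, matching)
        results.append(result)
        sample_meta.append(extra)
        event_frames.append(
            ntio.events_to_frame(events, result.sample_id, result.element, result.day_id)
        )

    # --- per-element pooled detection limits
    limits = {}
    by_element: dict[str, dict[str, list]] = {}
    for (el, day), blanks in blanks_by_key.items():
        by_element.setdefault(el, {})[day] = blanks
    for el, by_day in by_element.items():
        days = [d for d in by_day if len(by_day[d]) >= 2]
        calibs = {d: calibrations[(el, d)] for d in days if (el, d) in calibrations}
        if not calibs:
            continue
        limits[el] = detection_limits(
            {d: by_day[d] for d in calibs}, thresholds_by_day, calibs, etas,
            config.settings, element=el,
        )
        logger.info(
            "limits element=%s number_lod=%.4g mass_lod=%.4g mpp_lod_fg=%.4g", el,
            limits[el].number_lod, limits[el].mass_lod, limits[el].mass_per_particle_lod,
        )
    for r in results:
        lim = limits.get(r.element)
        if lim is not None:
            r.lod_number, r.lod_mass = lim.number_lod, lim.mass_lod
            r.censored_number = r.number_concentration < lim.number_lod
            r.censored_mass = r.mass_concentration < lim.mass_lod

    if event_frames:
        ntio.write_events(
            pd.concat(event_frames, ignore_index=True), out / "events.csv"
        )
    ntio.write_results(results, out / "results.csv")

    bundle = {
        "calibrations": calibrations,
        "transport_efficiencies": etas,
        "detection_limits": limits,
        "results": results,
        "sample_metadata": sample_meta,
    }

    # --- survey stage, when samples carry location metadata
    locations = [m.get("location") for m in sample_meta]
    if results and all(loc is not None for loc in locations):
        bundle["survey"] = _survey_stage(results, sample_meta, limits, out)
    return bundle


def _survey_stage(results, sample_meta, limits, out: Path) -> dict:
    rows = []
    for r, meta in zip(results, sample_meta):
        rows.append(
            {
                "location": meta["location"],
                "parallel": int(meta.get("parallel", 1)),
                "classification": meta.get("classification", "farm"),
                "season": meta.get("season", "summer"),
                "sampling_month": int(meta.get("sampling_month", 7)),
                "shell_length": float(meta.get("shell_length", 4.0)),
                "element": r.element,
                "number": r.number_concentration,
                "mass": r.mass_concentration,
            }
        )
    long = pd.DataFrame(rows)
    number = long.pivot_table(
        index=["location", "parallel"], columns="element", values="number"
    )
    mass = long.pivot_table(
        index=["location", "parallel"], columns="element", values="mass"
    )
    metadata = (
        long.groupby("location")
        .agg(
            classification=("classification", "first"),
            season=("season", "first"),
            sampling_month=("sampling_month", "first"),
            shell_length=("shell_length", "first"),
        )
    )
    elements = list(number.columns)
    lod_number = pd.Series(
        {el: (limits[el].number_lod if el in limits else 0.0) for el in elements}
    )
    lod_mass = pd.Series(
        {el: (limits[el].mass_lod if el in limits else 0.0) for el in elements}
    )
    table = SurveyTable(
        number=number, mass=mass, metadata=metadata,
        lod_number=lod_number, lod_mass=lod_mass,
    )
    return survey_products(table, out)


def survey_products(
    table: SurveyTable, out: Path | None = None, log_scale: bool = True
) -> dict:
    """Summary table, PCA and Ward clustering for a survey table.

    Multivariate analyses standardize per-location mean number concentrations;
    by default on a log10 scale, the appropriate working scale for lognormal
    environmental concentrations (otherwise single hotspot locations dominate
    each column's variance). Non-positive location means (possible after blank
    flooring) are raised to a tenth of the column's smallest positive value
    before taking logs.
    """
    summary = summarize(table)
    means = table.location_means("number")
    if log_scale:
        floor = means.where(means > 0).min() / 10.0
        means = np.log10(means.clip(lower=floor, axis=1))
    std = zscore(means, censored=table.location_censored("number"),
                 max_censored_fraction=0.5)
    products: dict = {"table": table, "summary": summary}
    if std.shape[1] >= 2 and std.shape[0] >= 3:
        groups = table.metadata["classification"]
        pca_result = pca(std, groups=groups)
        dendro = ward_cluster(std)
        products["pca"] = pca_result
        products["dendrogram"] = dendro
        if out is not None:
            pca_result.scores.to_csv(out / "pca_scores.csv", float_format="%.10g")
            pca_result.loadings.to_csv(out / "pca_loadings.csv", float_format="%.10g")
            (out / "dendrogram.newick").write_text(dendro.to_newick() + "\n")
    if out is not None:
        summary.to_csv(out / "summary.csv", float_format="%.10g")
    return products


def run_synthetic_survey(
    n_locations: int = 10,
    elements: tuple[str, ...] = ("Pb", "Ti", "Fe"),
    seed: int = 0,
    out_dir: str | Path | None = None,
    class_effects: dict | None = None,
    censoring_rate: float = 0.1,
) -> dict:
    """Generate a synthetic survey and run the survey-stage products on it.

    A convenience wrapper: the trace-level stages are exercised separately by
    the simulator round-trips; this generates the location x element survey
    with known ground truth and computes summary, PCA and clustering.
    """
    from .simulate import simulate_survey

    table, truth = simulate_survey(
        n_locations=n_locations, elements=elements,
        class_effects=class_effects, censoring_rate=censoring_rate, seed=seed,
    )
    out = None
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
    products = survey_products(table, out)
    products["ground_truth"] = truth
    return products
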