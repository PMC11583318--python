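"""Readers and writers for the package's CSV interchange formats.

All tables are plain CSV (comma, UTF-8, '.' decimal, explicit header row).
A raw trace is a two-column CSV ``dwell_index,counts`` with a sidecar YAML
metadata file (``<trace>.meta.yaml``) holding the acquisition settings and
the trace identity; readers validate counts and cross-check the dwell count
against the metadata.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import (
    AcquisitionSettings,
    GroundTruth,
    ParticleEvent,
    SampleResult,
    TimeTrace,
    TotalResult,
)

__all__ = [
    "read_trace",
    "write_trace",
    "sidecar_path",
    "events_to_frame",
    "write_events",
    "read_events",
    "results_to_frame",
    "write_results",
    "totals_to_frame",
    "write_totals",
    "write_ground_truth",
    "read_ground_truth",
]

EVENT_COLUMNS = [
    "sample_id", "element", "day_id", "start_dwell", "end_dwell",
    "max_intensity", "integral", "local_baseline", "threshold",
]
RESULT_COLUMNS = [
    "sample_id", "element", "day_id", "n_events", "number_conc_per_g",
    "mass_conc_ng_per_g", "censored_number", "censored_mass",
    "lod_number", "lod_mass",
]
TOTAL_COLUMNS = [
    "sample_id", "element", "conc_ng_per_g_ww", "lod", "censored",
    "dry_weight_fraction",
]


def sidecar_path(path: str | Path) -> Path:
    return Path(str(path) + ".meta.yaml")


def write_trace(trace: TimeTrace, path: str | Path, extra: dict | None = None) -> None:
    """Write a trace CSV and its sidecar metadata file."""
    path = Path(path)
    df = pd.DataFrame(
        {"dwell_index": np.arange(len(trace)), "counts": trace.counts}
    )
    df.to_csv(path, index=False)
    meta = {
        "dwell_time": float(trace.settings.dwell_time),
        "acquisition_time": float(trace.settings.acquisition_time),
        "flow_rate": float(trace.settings.flow_rate),
        "element": trace.element,
        "sample_id": trace.sample_id,
        "day_id": trace.day_id,
        "n_dwells": len(trace),
    }
    if extra:
        meta.update(extra)
    sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=True))


def read_trace(path: str | Path) -> tuple[TimeTrace, dict]:
    """Read and validate a trace CSV plus its sidecar metadata.

    Returns ``(trace, extra)`` where ``extra`` holds any sidecar keys beyond
    the settings and identity (e.g. a standard's concentration). Malformed
    rows, negative counts and metadata mismatches each raise a distinct
    diagnostic.
    """
    path = Path(path)
    meta_file = sidecar_path(path)
    if not meta_file.exists():
        raise FileNotFoundError(f"missing sidecar metadata: {meta_file}")
    meta = yaml.safe_load(meta_file.read_text())
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - rewrap with the file name
        raise ValueError(f"{path}: malformed CSV ({exc})") from exc
    if list(df.columns) != ["dwell_index", "counts"]:
        raise ValueError(f"{path}: expected header 'dwell_index,counts'")
    counts = pd.to_numeric(df["counts"], errors="coerce")
    bad = counts.isna()
    if bad.any():
        row = int(bad.idxmax()) + 2  # header + 1-based
        raise ValueError(f"{path}: malformed count at row {row}")
    neg = counts < 0
    if neg.any():
        row = int(neg.idxmax()) + 2
        raise ValueError(f"{path}: negative count at row {row}")
    if "n_dwells" in meta and len(df) != int(meta["n_dwells"]):
        raise ValueError(
            f"{path}: {len(df)} dwells on disk but metadata declares "
            f"{meta['n_dwells']}"
        )
    settings = AcquisitionSettings(
        dwell_time=float(meta["dwell_time"]),
        acquisition_time=float(meta["acquisition_time"]),
        flow_rate=float(meta["flow_rate"]),
    )
    known = {
        "dwell_time", "acquisition_time", "flow_rate", "element",
        "sample_id", "day_id", "n_dwells",
    }
    extra = {k: v for k, v in meta.items() if k not in known}
    values = counts.to_numpy()
    as_int = values.astype(np.int64)
    trace = TimeTrace(
        counts=as_int if np.array_equal(as_int, values) else values,
        settings=settings,
        element=str(meta.get("element", "")),
        sample_id=str(meta.get("sample_id", "")),
        day_id=str(meta.get("day_id", "")),
    )
    return trace, extra


def events_to_frame(
    events: list[ParticleEvent], sample_id: str = "", element: str = "", day_id: str = ""
) -> pd.DataFrame:
    rows = [
        {
            "sample_id": sample_id, "element": element, "day_id": day_id,
            "start_dwell": e.start_dwell, "end_dwell": e.end_dwell,
            "max_intensity": e.max_intensity, "integral": e.integral,
            "local_baseline": e.local_baseline, "threshold": e.threshold,
        }
        for e in events
    ]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def write_events(frame: pd.DataFrame, path: str | Path) -> None:
    # %.17g round-trips doubles exactly
    frame.to_csv(path, index=False, float_format="%.17g")


def read_events(path: str | Path) -> list[ParticleEvent]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        ParticleEvent(
            start_dwell=int(r.start_dwell), end_dwell=int(r.end_dwell),
            max_intensity=float(r.max_intensity), integral=float(r.integral),
            local_baseline=float(r.local_baseline), threshold=int(r.threshold),
        )
        for r in df.itertuples()
    ]


def results_to_frame(results: list[SampleResult]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": r.sample_id, "element": r.element, "day_id": r.day_id,
            "n_events": r.n_events, "number_conc_per_g": r.number_concentration,
            "mass_conc_ng_per_g": r.mass_concentration,
            "censored_number": r.censored_number, "censored_mass": r.censored_mass,
            "lod_number": r.lod_number, "lod_mass": r.lod_mass,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results(results: list[SampleResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, index=False, float_format="%.10g")


def totals_to_frame(totals: list[TotalResult]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": t.sample_id, "element": t.element,
            "conc_ng_per_g_ww": t.concentration, "lod": t.lod,
            "censored": t.censored, "dry_weight_fraction": t.dry_weight_fraction,
        }
        for t in totals
    ]
    return pd.DataFrame(rows, columns=TOTAL_COLUMNS)


def write_totals(totals: list[TotalResult], path: str | Path) -> None:
    totals_to_frame(totals).to_csv(path, index=False, float_format="%.10g")


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    rows = [
        {"start_dwell": e.start_dwell, "span": e.span, "mass_g": e.mass}
        for e in truth.events
    ]
    pd.DataFrame(rows, columns=["start_dwell", "span", "mass_g"]).to_csv(
        path, index=False, float_format="%.10g"
    )


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
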