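"""Readers/writers for accelerometry, annotation and weather tables;
pipeline configuration; run manifests.

All timestamps are stored UTC internally (ISO-8601 in files); conversion
to site-local time happens only in the ephemeris/night grouping.  Readers
validate rather than repair: non-uniform sampling beyond tolerance is a
hard error, and recording gaps are split into segments, never
interpolated — fabricated acceleration would bias the window features.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import date, datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import AccelTrace, AnnotationSet, BehaviorClass, Bout, as_utc

logger = logging.getLogger(__name__)

TIMESTAMP_FMT = "%Y-%m-%dT%H:%M:%S.%fZ"


class ValidationError(ValueError):
    """Input data violates a format or physical-range contract."""


# --- accelerometry ---------------------------------------------------------


def write_accel_csv(trace: AccelTrace, path) -> None:
    """Write a trace as CSV: ISO-8601 UTC timestamp (ms precision), x, y, z.

    Acceleration values are written to nine decimals (well below sensor
    noise), so one write/read round trip preserves them to 1e-9 g.
    """
    times = np.char.add(trace.times().astype("datetime64[ms]").astype(str), "Z")
    df = pd.DataFrame(
        {
            "timestamp": times,
            "x": np.round(trace.samples[:, 0], 9),
            "y": np.round(trace.samples[:, 1], 9),
            "z": np.round(trace.samples[:, 2], 9),
        }
    )
    df.to_csv(path, index=False)


def read_accel_csv(
    path, fs_expected: float, deployment_id: str | None = None
) -> list[AccelTrace]:
    """Read and validate an accelerometry CSV.

    Checks monotone timestamps (duplicates are an error naming the row),
    a constant sampling interval within 1% of ``1/fs_expected``, and the
    +/-10 g sensor range.  Gaps longer than 2 sample intervals are
    reported and the trace is split into segments at each gap; the return
    value is the list of segments in time order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    required = {"timestamp", "x", "y", "z"}
    if not required <= set(df.columns):
        raise ValidationError(f"{path}: missing columns {required - set(df.columns)}")
    dep = deployment_id or path.stem
    if df.empty:
        logger.warning("%s: empty accelerometry file", path)
        return []
    ts = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    tsec = ts.astype("int64").to_numpy() / 1e9
    dt = np.diff(tsec)
    dup = np.nonzero(dt <= 0)[0]
    if dup.size:
        raise ValidationError(
            f"{path}: non-increasing timestamp at row {dup[0] + 3} "
            f"({df['timestamp'].iloc[dup[0] + 1]})"
        )
    nominal = 1.0 / fs_expected
    gap = dt > 2.5 * nominal  # gaps: more than 2 missing samples
    bad = (~gap) & (np.abs(dt - nominal) > 0.01 * nominal)
    if bad.any():
        rows = (np.nonzero(bad)[0] + 2)[:10].tolist()
        raise ValidationError(
            f"{path}: non-uniform sampling interval (beyond 1% of "
            f"{nominal:.4f} s) at rows {rows}"
        )
    xyz = df[["x", "y", "z"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(xyz)):
        raise ValidationError(f"{path}: non-finite acceleration values")
    if np.abs(xyz).max() > AccelTrace.SENSOR_RANGE_G + 1e-9:
        raise ValidationError(
            f"{path}: acceleration outside the +/-10 g sensor range"
        )
    # split at gaps
    cut = np.concatenate([[0], np.nonzero(gap)[0] + 1, [len(df)]])
    segments = []
    for a, b in zip(cut[:-1], cut[1:]):
        if b - a < 1:
            continue
        t0 = ts.iloc[a].to_pydatetime()
        seg_id = dep if len(cut) == 2 else f"{dep}#{len(segments)}"
        segments.append(
            AccelTrace(deployment_id=seg_id, fs=fs_expected, t0=t0, samples=xyz[a:b])
        )
    if len(segments) > 1:
        logger.warning(
            "%s: %d recording gap(s) > 2 samples; split into %d segments",
            path,
            len(segments) - 1,
            len(segments),
        )
    return segments


# --- annotations -----------------------------------------------------------


def write_annotations_csv(annotations: AnnotationSet, path) -> None:
    rows = [
        {
            "behavior": b.behavior.value,
            "start": b.start.strftime(TIMESTAMP_FMT),
            "end": b.end.strftime(TIMESTAMP_FMT),
        }
        for b in annotations
    ]
    pd.DataFrame(rows, columns=["behavior", "start", "end"]).to_csv(path, index=False)


def read_annotations(path, deployment_id: str | None = None) -> AnnotationSet:
    """Read behavior bouts; labels are normalized to the lowercase vocabulary."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if not {"behavior", "start", "end"} <= set(df.columns):
        raise ValidationError(f"{path}: expected columns behavior,start,end")
    dep = deployment_id or path.stem
    if df.empty:
        logger.warning("%s: annotation file has a header but no bouts", path)
        return AnnotationSet(deployment_id=dep, bouts=[])
    bouts = []
    for _, row in df.iterrows():
        behavior = BehaviorClass.parse(str(row["behavior"]))
        start = as_utc(pd.to_datetime(row["start"], utc=True).to_pydatetime())
        end = as_utc(pd.to_datetime(row["end"], utc=True).to_pydatetime())
        bouts.append(Bout(behavior=behavior, start=start, end=end))
    try:
        return AnnotationSet(deployment_id=dep, bouts=bouts)
    except ValueError as exc:
        raise ValidationError(f"{path}: {exc}") from None


# --- weather ---------------------------------------------------------------

_WEATHER_NUMERIC = ["temperature_c", "wind_ms", "humidity_pct", "precip_mmh"]


def write_weather_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.17g")


def read_weather(paths, expected_nights=None) -> pd.DataFrame:
    """Read nightly weather from one or more station files and average them.

    Each file needs columns night, temperature_c (degC), wind_ms (m/s),
    humidity_pct (%RH) and optionally precip_mmh (mm/h).  A duplicated
    night within one station is an error; with several stations the
    per-night mean across stations is returned.  ``expected_nights`` (an
    iterable of dates) flags missing nights with a warning.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    frames = []
    for p in paths:
        p = Path(p)
        if not p.exists():
            raise FileNotFoundError(p)
        df = pd.read_csv(p)
        if "night" not in df.columns:
            raise ValidationError(f"{p}: missing 'night' column")
        df["night"] = pd.to_datetime(df["night"]).dt.date
        if df["night"].duplicated().any():
            dup = df.loc[df["night"].duplicated(), "night"].iloc[0]
            raise ValidationError(f"{p}: duplicate night-date {dup}")
        frames.append(df)
    merged = pd.concat(frames, ignore_index=True)
    cols = [c for c in _WEATHER_NUMERIC if c in merged.columns]
    out = merged.groupby("night", as_index=False)[cols].mean()
    if expected_nights is not None:
        missing = sorted(set(expected_nights) - set(out["night"]))
        if missing:
            logger.warning("weather: missing nights %s", missing)
    return out


# --- configuration ---------------------------------------------------------


@dataclass
class PipelineConfig:
    """End-to-end run configuration (YAML-serializable)."""

    # site
    latitude: float = 30.2
    longitude: float = -103.5
    timezone: str = "America/Chicago"
    # simulation
    n_individuals: int = 14
    n_nights: int = 5
    #: deployment length in hours; defaults to 24 * n_nights
    deployment_hours: float | None = None
    start_date: str = "2021-06-01"
    start_hour_utc: int = 18
    fs: float = 25.0
    # features / training
    window_sizes: tuple[float, ...] = (1.0, 2.0, 3.0, 6.0, 9.0)
    feature_sets: tuple[str, ...] = ("all", "reduced")
    algorithms: tuple[str, ...] = ("linear_svm", "decision_tree", "random_forest")
    train_fraction: float = 0.5
    label_slack_s: float = 1.0
    # moonlight categories
    moon_low_bound: float = 0.33
    moon_high_bound: float = 0.66
    # modeling
    model_formula: str = (
        "proportion ~ temperature_c + wind_ms + humidity_pct + moon_illumination"
    )
    model_weights: str = "n_total"
    moon_analysis: bool = False
    exclude_precipitation: bool = False
    # misc
    seed: int = 0

    def site(self):
        from .ephemeris import SiteContext

        return SiteContext(self.latitude, self.longitude, self.timezone)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("window_sizes", "feature_sets", "algorithms"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


# --- manifest --------------------------------------------------------------


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path, config: PipelineConfig, inputs: list, outputs: list, base=None
) -> None:
    """Machine-readable run manifest: config, seed, versions, input hashes.

    Paths are recorded relative to ``base`` (the run directory) and no
    wall-clock time is stored, so repeat runs with identical inputs
    produce byte-identical manifests wherever they are placed.
    """
    import sklearn

    from . import __version__

    def rel(p):
        p = Path(p)
        if base is not None:
            try:
                return p.relative_to(base).as_posix()
            except ValueError:
                pass
        return str(p)

    manifest = {
        "config": asdict(config),
        "versions": {
            "kratkit": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
        "inputs": {rel(p): file_sha256(p) for p in sorted(map(str, inputs))},
        "outputs": sorted(rel(p) for p in outputs),
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
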