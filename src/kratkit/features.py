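"""Window segmentation and the 41-statistic feature summary.

A trace is tiled into non-overlapping windows of a fixed duration (1, 2,
3, 6 or 9 s by default); any trailing partial window is discarded.  For
each window the 16 summary statistics of the classification feature set
are computed, most of them per axis, giving 41 numbers per window:

  per-axis mean, SD, max, min (12); mean vector norm (1); pairwise
  covariance and Pearson correlation xy/xz/yz (6); per-axis mean |DBA|
  (3); ODBA (1); per-axis mean-diff and std-diff of first differences
  (6); per-axis wave amplitude max-min (3); per-axis DBA line crossings
  (3); per-axis 25/50/75 percentiles (9).

Conventions (fixed so that results are reproducible): moments use the
n-denominator; the static component removed for DBA is the window's own
per-axis mean; ODBA is the mean over samples of |DBAx|+|DBAy|+|DBAz| (a
mean, not a sum, so values are comparable across window sizes);
percentiles interpolate linearly; line crossings count sign changes of
the per-axis DBA sequence with zeros inheriting the previous sign; a
zero-variance axis yields Pearson correlations of 0 (flagged) rather
than NaN.

The reduced feature set is {per-axis mean, per-axis SD, ODBA} (7 numbers).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import timedelta

import numpy as np
import pandas as pd

from .core import AccelTrace, AnnotationSet, BehaviorClass

logger = logging.getLogger(__name__)

_AXES = ("x", "y", "z")
_PAIRS = (("x", "y"), ("x", "z"), ("y", "z"))

#: Column order of the full 41-feature vector.
FEATURE_NAMES: tuple[str, ...] = (
    tuple(f"mean_{a}" for a in _AXES)
    + tuple(f"sd_{a}" for a in _AXES)
    + tuple(f"max_{a}" for a in _AXES)
    + tuple(f"min_{a}" for a in _AXES)
    + ("mean_vecnorm",)
    + tuple(f"cov_{a}{b}" for a, b in _PAIRS)
    + tuple(f"corr_{a}{b}" for a, b in _PAIRS)
    + tuple(f"mean_dba_{a}" for a in _AXES)
    + ("odba",)
    + tuple(f"mean_diff_{a}" for a in _AXES)
    + tuple(f"std_diff_{a}" for a in _AXES)
    + tuple(f"wave_amp_{a}" for a in _AXES)
    + tuple(f"crossings_{a}" for a in _AXES)
    + tuple(f"p25_{a}" for a in _AXES)
    + tuple(f"p50_{a}" for a in _AXES)
    + tuple(f"p75_{a}" for a in _AXES)
)

#: Reduced feature set: mean, SD and ODBA only.
REDUCED_FEATURE_NAMES: tuple[str, ...] = (
    tuple(f"mean_{a}" for a in _AXES) + tuple(f"sd_{a}" for a in _AXES) + ("odba",)
)

FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "all": FEATURE_NAMES,
    "reduced": REDUCED_FEATURE_NAMES,
}


@dataclass
class Window:
    """One fixed-duration window of a trace, with an optional behavior label."""

    deployment_id: str
    start_index: int
    length: int
    window_s: float
    samples: np.ndarray  # (length, 3) view
    label: BehaviorClass | None = None


def segment(trace: AccelTrace, window_s: float) -> list[Window]:
    """Tile ``trace`` into non-overlapping windows of ``window_s`` seconds.

    Windows start at sample 0; a trailing partial window is discarded.
    """
    length = int(round(window_s * trace.fs))
    if length < 2:
        raise ValueError(
            f"window of {window_s} s at {trace.fs} Hz spans {length} samples; "
            "at least 2 are required"
        )
    n_windows = len(trace) // length
    return [
        Window(
            deployment_id=trace.deployment_id,
            start_index=i * length,
            length=length,
            window_s=window_s,
            samples=trace.samples[i * length : (i + 1) * length],
        )
        for i in range(n_windows)
    ]


def _crossings_count(d: np.ndarray) -> int:
    """Sign changes of a sequence; zeros inherit the previous sign."""
    s = np.sign(d)
    nz = s != 0
    if not nz.any():
        return 0
    idx = np.where(nz, np.arange(len(s)), -1)
    last = np.maximum.accumulate(idx)
    filled = np.where(last >= 0, s[np.clip(last, 0, None)], 0.0)
    a, b = filled[:-1], filled[1:]
    return int(np.sum((a != 0) & (b != 0) & (a != b)))


def compute_features(window: Window | np.ndarray) -> np.ndarray:
    """The 41-feature vector of one window, ordered as ``FEATURE_NAMES``."""
    xyz = window.samples if isinstance(window, Window) else np.asarray(window, float)
    return compute_feature_matrix(xyz[np.newaxis, :, :])[0]


def compute_feature_matrix(stack: np.ndarray) -> np.ndarray:
    """Vectorized features for a stack of windows, shape (n_win, length, 3)."""
    stack = np.asarray(stack, dtype=float)
    n_win, n, _ = stack.shape
    mean = stack.mean(axis=1)  # (w, 3)
    dba = stack - mean[:, None, :]
    var = (dba**2).mean(axis=1)
    sd = np.sqrt(var)
    mx = stack.max(axis=1)
    mn = stack.min(axis=1)
    vecnorm = np.sqrt((stack**2).sum(axis=2)).mean(axis=1)
    cov = np.stack(
        [(dba[:, :, i] * dba[:, :, j]).mean(axis=1) for i, j in ((0, 1), (0, 2), (1, 2))],
        axis=1,
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.stack(
            [cov[:, k] / (sd[:, i] * sd[:, j]) for k, (i, j) in enumerate(((0, 1), (0, 2), (1, 2)))],
            axis=1,
        )
    corr = np.nan_to_num(corr, nan=0.0, posinf=0.0, neginf=0.0)
    mean_dba = np.abs(dba).mean(axis=1)
    odba = np.abs(dba).sum(axis=2).mean(axis=1)
    diff = np.diff(stack, axis=1)
    mean_diff = np.abs(diff).mean(axis=1)
    std_diff = diff.std(axis=1)  # n-denominator over the n-1 differences
    wave_amp = mx - mn
    crossings = np.empty((n_win, 3))
    for w in range(n_win):
        for a in range(3):
            crossings[w, a] = _crossings_count(dba[w, :, a])
    pcts = np.percentile(stack, [25, 50, 75], axis=1)  # (3, w, 3)
    return np.concatenate(
        [
            mean,
            sd,
            mx,
            mn,
            vecnorm[:, None],
            cov,
            corr,
            mean_dba,
            odba[:, None],
            mean_diff,
            std_diff,
            wave_amp,
            crossings,
            pcts[0],
            pcts[1],
            pcts[2],
        ],
        axis=1,
    )


def feature_table(
    trace: AccelTrace,
    window_s: float,
    annotations: AnnotationSet | None = None,
    label_slack_s: float = 1.0,
) -> pd.DataFrame:
    """Segment, featurize and (optionally) label a whole trace.

    Returns one row per window: deployment_id, window start timestamp,
    window_s, the 41 feature columns, and a ``label`` column (empty string
    where unlabeled).
    """
    windows = segment(trace, window_s)
    if not windows:
        return pd.DataFrame(
            columns=["deployment_id", "start", "window_s", *FEATURE_NAMES, "label"]
        )
    stack = np.stack([w.samples for w in windows])
    feats = compute_feature_matrix(stack)
    starts = [
        trace.t0 + timedelta(seconds=w.start_index / trace.fs) for w in windows
    ]
    df = pd.DataFrame(feats, columns=list(FEATURE_NAMES))
    df.insert(0, "window_s", window_s)
    df.insert(0, "start", pd.to_datetime([s.replace(tzinfo=None) for s in starts]))
    df.insert(0, "deployment_id", trace.deployment_id)
    if annotations is not None:
        labels = label_windows(trace, windows, annotations, slack_s=label_slack_s)
        df["label"] = [lab.value if lab is not None else "" for lab in labels]
    else:
        df["label"] = ""
    return df


def label_windows(
    trace: AccelTrace,
    windows: list[Window],
    annotations: AnnotationSet,
    slack_s: float = 1.0,
) -> list[BehaviorClass | None]:
    """Assign each window the label of the bout that contains it.

    Behavioral scores are time-matched to the accelerometer only to within
    about a second, so a window is accepted if its span lies inside a bout
    after allowing ``slack_s`` of alignment slack at each bout edge;
    windows straddling transitions by more than the slack stay unlabeled.
    """
    out: list[BehaviorClass | None] = []
    dropped = 0
    for w in windows:
        t_start = trace.t0 + timedelta(seconds=w.start_index / trace.fs)
        t_end = t_start + timedelta(seconds=w.length / trace.fs)
        label = None
        for bout in annotations:
            if (
                bout.start - timedelta(seconds=slack_s) <= t_start
                and t_end <= bout.end + timedelta(seconds=slack_s)
            ):
                label = bout.behavior
                break
        if label is None:
            dropped += 1
        out.append(label)
    if dropped:
        logger.info(
            "label_windows: %d of %d windows left unlabeled (bout boundaries)",
            dropped,
            len(windows),
        )
    for w, lab in zip(windows, out):
        w.label = lab
    return out
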