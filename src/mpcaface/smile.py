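"""Smile amplitude and automatic segmentation of the seven smile phases.

The smile amplitude at frame ``t`` is the Euclidean distance between the left
and right chelion (mouth-corner landmarks) divided by *twice* the distance at
the rest frame ``t = 0``, so every trajectory starts at amplitude 0.5 exactly
and a doubling of mouth width reads 1.0.

A dynamic smile decomposes into seven phases — rest pre-smile, onset
acceleration, onset deceleration, apex, offset acceleration, offset
deceleration, rest post-smile — where the acceleration/deceleration split of
onset and offset sits at the inflexion of the amplitude curve.  The
segmenter automates the identification from the smoothed amplitude and its
first two derivatives, with explicit, configurable thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PHASE_NAMES = (
    "rest_pre",
    "onset_accel",
    "onset_decel",
    "apex",
    "offset_accel",
    "offset_decel",
    "rest_post",
)


@dataclass
class Trajectory:
    """Time-ordered mouth-landmark frames for one subject.

    ``frames`` is ``(n_frames, k, 3)``; frame 0 is the rest reference.
    """

    frames: np.ndarray
    subject_id: str = "s1"
    frame_rate: float | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_frames, k, d)")
        if self.frames.shape[0] < 20:
            raise ValueError("a trajectory needs at least 20 frames")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class AmplitudeSeries:
    """Per-frame smile amplitudes with optional smoothed/derivative series."""

    values: np.ndarray
    smoothed: np.ndarray | None = None
    d1: np.ndarray | None = None
    d2: np.ndarray | None = None
    frame_rate: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, float)

    def __len__(self) -> int:
        return self.values.size

    @property
    def working(self) -> np.ndarray:
        """Smoothed series if present, else the raw values."""
        return self.values if self.smoothed is None else self.smoothed


@dataclass
class PhaseSegmentation:
    """Six boundary frame indices partitioning a series into the seven phases.

    ``boundaries[i]`` is the first frame of phase ``i + 1``; phase 0 starts at
    frame 0 and the last phase ends at ``n_frames``.
    """

    boundaries: tuple[int, int, int, int, int, int]
    n_frames: int
    labels: tuple[str, ...] = PHASE_NAMES

    def __post_init__(self):
        b = tuple(int(x) for x in self.boundaries)
        edges = (0,) + b + (self.n_frames,)
        if any(e2 <= e1 for e1, e2 in zip(edges, edges[1:])):
            raise ValueError(f"boundaries {b} do not give seven non-empty phases")
        self.boundaries = b

    def intervals(self) -> dict[str, tuple[int, int]]:
        edges = (0,) + self.boundaries + (self.n_frames,)
        return {name: (edges[i], edges[i + 1]) for i, name in enumerate(self.labels)}

    def frame_labels(self) -> np.ndarray:
        out = np.empty(self.n_frames, object)
        for name, (a, b) in self.intervals().items():
            out[a:b] = name
        return out

    def to_frame(self, subject_id: str = "s1") -> pd.DataFrame:
        rows = [
            {"subject_id": subject_id, "phase": name, "start_frame": a,
             "end_frame": b - 1}
            for name, (a, b) in self.intervals().items()
        ]
        return pd.DataFrame(rows)


def smile_amplitude(trajectory: Trajectory, left_chelion: int,
                    right_chelion: int) -> AmplitudeSeries:
    """Inter-chelion distance over twice the frame-0 distance (baseline 0.5)."""
    k = trajectory.frames.shape[1]
    for idx in (left_chelion, right_chelion):
        if not 0 <= idx < k:
            raise ValueError(f"chelion index {idx} out of range for {k} landmarks")
    diff = trajectory.frames[:, left_chelion] - trajectory.frames[:, right_chelion]
    dist = np.linalg.norm(diff, axis=1)
    if dist[0] <= 0:
        raise ValueError("zero inter-chelion distance at the rest frame")
    return AmplitudeSeries(dist / (2.0 * dist[0]), frame_rate=trajectory.frame_rate)


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; near the edges the window shrinks symmetrically."""
    values = np.asarray(values, float)
    n = values.size
    if window < 1 or window % 2 == 0 or window > n:
        raise ValueError("window must be odd, >= 1, and <= the series length")
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = values[i - h: i + h + 1].mean()
    return out


def smooth_series(series: AmplitudeSeries, window: int = 5) -> AmplitudeSeries:
    """Attach a centered moving-average smooth of the amplitude values."""
    if window < 3 and window != 1:
        raise ValueError("window must be 1 or an odd number >= 3")
    return AmplitudeSeries(series.values,
                           smoothed=moving_average(series.values, window),
                           d1=series.d1, d2=series.d2,
                           frame_rate=series.frame_rate)


def differentiate(series: AmplitudeSeries) -> AmplitudeSeries:
    """Attach central-difference first and second derivatives.

    Derivatives are of the smoothed series when present, per frame unless a
    frame rate is set (then per second).
    """
    if len(series) < 5:
        raise ValueError("need at least 5 frames to differentiate")
    dt = 1.0 if series.frame_rate is None else 1.0 / series.frame_rate
    base = series.working
    d1 = np.gradient(base, dt)
    d2 = np.gradient(d1, dt)
    return AmplitudeSeries(series.values, smoothed=series.smoothed,
                           d1=d1, d2=d2, frame_rate=series.frame_rate)


@dataclass(frozen=True)
class SegmentationParams:
    """Thresholds for the automatic phase segmentation.

    rest_tol : amplitude band around the 0.5 baseline counted as rest.
    rise_tol : first-derivative threshold (per frame) for a sustained rise.
    min_run : minimum consecutive frames above threshold to accept a rise.
    apex_frac : fraction of (peak - baseline) above which frames are apex.
    window : smoothing window (frames) for the amplitude and derivatives.
    """

    rest_tol: float = 0.02
    rise_tol: float = 0.002
    min_run: int = 3
    apex_frac: float = 0.95
    window: int = 5


def _runs(mask: np.ndarray, min_run: int) -> list[tuple[int, int]]:
    """(start, end) of maximal true runs of length >= min_run; end exclusive."""
    out = []
    i, n = 0, mask.size
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            if j - i >= min_run:
                out.append((i, j))
            i = j
        else:
            i += 1
    return out


def _nearest_sign_change(values: np.ndarray, lo: int, hi: int, target: int) -> int | None:
    """Index of the sign change of ``values`` in [lo, hi) nearest ``target``.

    A change between i and i+1 is located at i + 1; ties pick the earlier
    frame.
    """
    crossings = []
    for i in range(max(lo, 0), min(hi - 1, values.size - 1)):
        if values[i] == 0.0 or (values[i] > 0) != (values[i + 1] > 0):
            crossings.append(i + 1 if values[i] != 0.0 else i)
    if not crossings:
        return None
    crossings.sort(key=lambda c: (abs(c - target), c))
    return crossings[0]


def segment_phases(series: AmplitudeSeries,
                   params: SegmentationParams | None = None) -> PhaseSegmentation:
    """Segment an amplitude series into the seven canonical smile phases.

    The series is smoothed and differentiated with the configured window if
    that has not been done already.  Onset starts at the first sustained rise
    of the first derivative, offset ends where the last sustained fall stops;
    apex collects the frames above ``apex_frac`` of the peak elevation; the
    acceleration/deceleration splits sit at the second-derivative zero
    crossing nearest the extremum of the first derivative on each limb.
    """
    p = params or SegmentationParams()
    if series.smoothed is None:
        series = smooth_series(series, p.window)
    a = series.working
    # thresholds are per frame, so differentiate in frame units regardless of
    # the frame rate, and smooth the derivatives like the amplitude
    win = min(p.window, len(series) | 1)
    d1 = moving_average(np.gradient(a), win)
    d2 = moving_average(np.gradient(d1), win)
    n = a.size
    baseline = 0.5

    peak_idx = int(np.argmax(a))
    span = a[peak_idx] - baseline
    rising = _runs(d1 > p.rise_tol, p.min_run)
    falling = _runs(d1 < -p.rise_tol, p.min_run)
    if span <= 2 * p.rest_tol or not rising or not falling:
        raise ValueError("no smile detected: amplitude never leaves the rest band")
    if len(rising) > 1 or len(falling) > 1:
        warnings.warn("multiple rise/fall episodes; segmenting around the "
                      "global amplitude maximum")
    # the onset limb is the sustained rise with the largest amplitude gain
    # ending at or before the peak; the offset limb mirrors it.  The limb
    # boundary sits right after (before) the series was last (first) at
    # rest — amplitude inside the rest band with a near-zero derivative —
    # so noise excursions glued to the limb's tail do not drag it outward.
    at_rest = (np.abs(a - baseline) <= p.rest_tol) & (np.abs(d1) <= 2 * p.rise_tol)
    before = [r for r in rising if r[0] < peak_idx] or rising
    r0, r1 = max(before, key=lambda r: a[min(r[1], n - 1)] - a[r[0]])
    anchor = r0 + int(np.argmax(d1[r0:r1]))
    onset_start = r0
    for i in range(anchor, -1, -1):
        if at_rest[i]:
            onset_start = i + 1
            break
    after = [f for f in falling if f[1] > peak_idx] or falling
    f0, f1 = max(after, key=lambda f: a[f[0]] - a[min(f[1], n - 1)])
    anchor = f0 + int(np.argmin(d1[f0:f1]))
    offset_end = f1
    for i in range(anchor, n):
        if at_rest[i]:
            offset_end = i
            break

    # apex: frames around the peak above the apex threshold.  A departure
    # only counts when the amplitude stays below a confirmation level
    # (5% of span under the threshold) for min_run frames, so brief noise
    # dips do not split the plateau; the boundary sits at the threshold
    # crossing that leads into the confirmed departure.
    thresh = baseline + p.apex_frac * span
    confirm = baseline + max(p.apex_frac - 0.05, 0.5) * span
    conf_runs = _runs(a < confirm, p.min_run)
    hi = n
    for i, _ in conf_runs:
        if i > peak_idx:
            hi = i
            break
    while hi - 1 > peak_idx and a[hi - 1] < thresh:
        hi -= 1
    lo = 0
    for _, j in conf_runs:
        if j <= peak_idx:
            lo = j
    while lo < peak_idx and a[lo] < thresh:
        lo += 1
    apex_start, apex_end = lo, hi

    # inflexions: d2 zero crossing nearest the d1 extremum on each limb
    rise_lo, rise_hi = onset_start, max(apex_start, onset_start + 2)
    i1 = rise_lo + int(np.argmax(d1[rise_lo:rise_hi]))
    b1 = _nearest_sign_change(d2, rise_lo, rise_hi, i1)
    fall_lo, fall_hi = min(apex_end, offset_end - 2), offset_end
    i2 = fall_lo + int(np.argmin(d1[fall_lo:fall_hi]))
    b4 = _nearest_sign_change(d2, fall_lo, fall_hi, i2)
    b1 = i1 if b1 is None else b1
    b4 = i2 if b4 is None else b4

    bounds = [onset_start, b1, apex_start, apex_end, b4, offset_end]
    # enforce seven non-empty phases with deterministic nudges
    bounds[0] = max(1, bounds[0])
    for i in range(1, 6):
        bounds[i] = max(bounds[i], bounds[i - 1] + 1)
    bounds[5] = min(bounds[5], n - 1)
    for i in range(4, -1, -1):
        bounds[i] = min(bounds[i], bounds[i + 1] - 1)
    if bounds[0] < 1:
        raise ValueError("cannot segment: series too short for seven phases")
    return PhaseSegmentation(tuple(bounds), n)


def phase_cycle_report(model, trajectories, segmentations,
                       left_chelion: int | None = None,
                       right_chelion: int | None = None,
                       n_components: int = 2) -> tuple[pd.DataFrame, list[str]]:
    """Per-phase centroids of standardized middle-level scores.

    ``model`` is a fitted :class:`~mpcaface.mpca.MultilevelPCA` trained on the
    (centered) frame shape vectors of the trajectories.  Frames are pooled
    across trajectories by phase label; the report lists the centroid of the
    first ``n_components`` standardized level-2 scores for each phase in
    canonical order, which traces the smile cycle as a closed polygon.

    Returns the centroid table and the polygon ordering (the canonical phase
    order).
    """
    rows, labels = [], []
    for traj, seg in zip(trajectories, segmentations):
        pts = traj.frames - traj.frames.mean(axis=1, keepdims=True)
        rows.append(pts.reshape(traj.n_frames, -1))
        labels.append(seg.frame_labels())
    X = np.vstack(rows)
    phase = np.concatenate(labels)
    scores = model.transform(X)[1]  # middle level = between smile phases
    scores = scores[:, :n_components]

    from .mpca import score_centroids

    present = set(phase)
    missing = [ph for ph in PHASE_NAMES if ph not in present]
    if len(present) == 1:
        # degenerate single-phase input: the table collapses to column means
        cent = score_centroids(scores, phase)
        return cent, list(cent.index)
    if missing:
        raise ValueError(f"phase(s) absent in all trajectories: {missing}")

    cent = score_centroids(scores, phase)
    cent = cent.loc[[ph for ph in PHASE_NAMES if ph in cent.index]]
    return cent, list(cent.index)
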