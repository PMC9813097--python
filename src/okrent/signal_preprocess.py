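"""Raw trace -> per-cycle amplitude table.

Converts stimulus/eye-angle recordings (irregularly sampled, degrees) into a
table of per-stimulus-cycle peak-to-peak response amplitudes:

1. resample onto a uniform grid (default 200 Hz) and low-pass filter
   (zero-phase 4th-order Butterworth, default 4 Hz cutoff),
2. segment the session into full stimulus cycles at the analytically known
   extrema of the triangular stimulus command,
3. average left and right eye into a conjugate trace,
4. flag artifact cycles (fast phases / jerks) with a velocity criterion,
5. measure max-minus-min of the conjugate trace within each cycle.

The cycle table is a plain :class:`pandas.DataFrame` with the columns in
:data:`CYCLE_COLUMNS`; ``reason`` is one of ``""``, ``"edge"``,
``"fast_phase"``, ``"missing"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

if TYPE_CHECKING:  # avoid a runtime import cycle with synthetic_data
    from .synthetic_data import StimulusProfile

logger = logging.getLogger(__name__)

#: Columns of a cycle table, in order.
CYCLE_COLUMNS = ["cycle_index", "t_start_s", "t_end_s", "pp_deg", "valid", "reason"]

#: Minimum number of valid cycles a session must retain after artifact
#: exclusion for downstream immediate/entrained statistics to be meaningful.
MIN_VALID_CYCLES = 10

#: Gaps in the original sampling longer than this (s) are not bridged by
#: interpolation; cycles overlapping them are excluded (reason "missing").
MAX_INTERP_GAP_S = 0.5


@dataclass
class TraceRecording:
    """A stimulus/eye recording: time stamps plus three angle series (deg).

    ``time`` must be strictly increasing but may be irregular (the camera in
    the emulated setup runs at a nominal 30 frames/s with jitter).  Missing
    eye samples are NaN.  ``gaps`` lists (t0, t1) intervals in which the
    original sampling had holes longer than :data:`MAX_INTERP_GAP_S`; they
    survive resampling so artifact detection can void overlapping cycles.
    """

    time: np.ndarray
    stim: np.ndarray
    left: np.ndarray
    right: np.ndarray
    profile: "StimulusProfile | None" = None
    gaps: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.stim = np.asarray(self.stim, dtype=float)
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        n = self.time.size
        if not (self.stim.size == self.left.size == self.right.size == n):
            raise ValueError("time/stim/left/right must have equal lengths")
        if n >= 2 and not np.all(np.diff(self.time) > 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def __len__(self) -> int:
        return self.time.size


def _interp_series(t_new: np.ndarray, t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Linear interpolation that tolerates NaN stretches in ``y``."""
    ok = np.isfinite(y)
    if not ok.any():
        return np.full(t_new.shape, np.nan)
    return np.interp(t_new, t[ok], y[ok])


def _find_gaps(t: np.ndarray, max_gap: float) -> list[tuple[float, float]]:
    dt = np.diff(t)
    idx = np.nonzero(dt > max_gap)[0]
    return [(float(t[i]), float(t[i + 1])) for i in idx]


def _resample(rec: TraceRecording, rate: float) -> TraceRecording:
    """Linear interpolation of all three series onto a uniform grid."""
    t0, t1 = rec.time[0], rec.time[-1]
    n = int(np.floor((t1 - t0) * rate)) + 1
    t_new = t0 + np.arange(n) / rate
    series = {
        name: _interp_series(t_new, rec.time, getattr(rec, name))
        for name in ("stim", "left", "right")
    }
    gaps = sorted(set(rec.gaps) | set(_find_gaps(rec.time, MAX_INTERP_GAP_S)))
    return replace(rec, time=t_new, gaps=gaps, **series)


def lowpass(
    y: np.ndarray, rate: float, cutoff: float, order: int = 4
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass of one series."""
    b, a = butter(order, cutoff, btype="low", fs=rate)
    if np.isfinite(y).all():
        return filtfilt(b, a, y)
    if not np.isfinite(y).any():
        return y.copy()
    yy = y.copy()
    finite = np.isfinite(yy)
    yy[finite] = filtfilt(b, a, yy[finite])
    return yy


def resample_filter(
    rec: TraceRecording,
    rate: float = 200.0,
    cutoff: float = 4.0,
    order: int = 4,
) -> TraceRecording:
    """Resample onto a uniform grid and apply a zero-phase Butterworth low-pass.

    Linear interpolation onto an evenly spaced grid at ``rate`` Hz spanning the
    recording, then a forward-backward (zero-phase) Butterworth filter of the
    given ``order`` and ``cutoff`` applied to stimulus and both eye series.
    Zero-phase filtering is used because cycle segmentation and peak-to-peak
    measurement are timing-sensitive; a causal filter would drag the response
    peaks by its group delay.
    """
    if len(rec) < 2:
        raise ValueError("need at least 2 samples to resample")
    if rec.duration <= 1.0 / cutoff:
        raise ValueError("recording shorter than one filter time constant")
    uni = _resample(rec, rate)
    return replace(
        uni,
        stim=lowpass(uni.stim, rate, cutoff, order),
        left=lowpass(uni.left, rate, cutoff, order),
        right=lowpass(uni.right, rate, cutoff, order),
    )


def segment_cycles(
    rec: TraceRecording,
    phase0: float = 0.0,
    tol_samples: float = 1.5,
) -> pd.DataFrame:
    """Split a uniformly sampled recording into full stimulus cycles.

    Cycle boundaries are the analytically known positive extrema of the
    triangular stimulus command (at ``phase0 + k*period``), not extrema
    detected on the recorded stimulus: the command is deterministic, so
    segmentation should be too.  A cycle runs from one positive extremum to
    the next (duration = one full period).  Partial leading/trailing segments
    are kept as rows flagged invalid with reason ``"edge"``.

    Returns a cycle table (pp_deg still NaN).  Raises if the recording is
    shorter than one full period.
    """
    if rec.profile is None:
        raise ValueError("recording has no stimulus profile")
    period = rec.profile.period
    t0, t1 = float(rec.time[0]), float(rec.time[-1])
    if t1 - t0 < period:
        raise ValueError("no full cycles: recording shorter than one period")
    dt = float(np.median(np.diff(rec.time)))
    tol = tol_samples * dt
    # first boundary at or before the trace start
    k0 = int(np.floor((t0 - phase0 - tol) / period))
    rows = []
    index = 0
    k = k0
    while phase0 + k * period < t1 - tol:
        start = phase0 + k * period
        end = start + period
        if end <= t0 + tol:  # window does not overlap the trace
            k += 1
            continue
        full = (start >= t0 - tol) and (end <= t1 + tol)
        index += 1
        rows.append(
            {
                "cycle_index": index,
                "t_start_s": max(start, t0),
                "t_end_s": min(end, t1),
                "pp_deg": np.nan,
                "valid": bool(full),
                "reason": "" if full else "edge",
            }
        )
        k += 1
    table = pd.DataFrame(rows, columns=CYCLE_COLUMNS)
    if not table["valid"].any():
        raise ValueError("no full cycles in recording")
    return table


def conjugate_average(rec: TraceRecording) -> np.ndarray:
    """Sample-wise mean of left and right eye in the shared sign convention.

    If one eye is entirely missing the other is returned with a warning.  A
    negative left/right correlation suggests a sign-convention error in the
    inputs and is warned about (conjugate eyes should co-vary).
    """
    left_ok = np.isfinite(rec.left).any()
    right_ok = np.isfinite(rec.right).any()
    if not left_ok and not right_ok:
        raise ValueError("both eye series are missing")
    if not right_ok:
        logger.warning("right eye missing entirely; using left eye only")
        return rec.left.copy()
    if not left_ok:
        logger.warning("left eye missing entirely; using right eye only")
        return rec.right.copy()
    both = np.isfinite(rec.left) & np.isfinite(rec.right)
    if both.sum() >= 2:
        l, r = rec.left[both], rec.right[both]
        if np.std(l) > 0 and np.std(r) > 0:
            corr = float(np.corrcoef(l, r)[0, 1])
            if corr < 0:
                logger.warning(
                    "left/right eye correlation is negative (%.2f): "
                    "possible sign-convention mismatch",
                    corr,
                )
    if both.all():
        return 0.5 * (rec.left + rec.right)
    with np.errstate(invalid="ignore"):
        return np.nanmean(np.vstack([rec.left, rec.right]), axis=0)


def _window_slice(t: np.ndarray, start: float, end: float) -> slice:
    i0 = int(np.searchsorted(t, start - 1e-9, side="left"))
    i1 = int(np.searchsorted(t, end + 1e-9, side="right"))
    return slice(i0, i1)


def detect_artifact_cycles(
    table: pd.DataFrame,
    rec: TraceRecording,
    conj: np.ndarray,
    velocity_factor: float = 3.0,
    velocity_abs: float = 20.0,
    min_valid: int = MIN_VALID_CYCLES,
) -> pd.DataFrame:
    """Flag cycles contaminated by fast phases or jerks.

    A cycle is invalid when the peak conjugate eye speed inside it exceeds
    ``max(velocity_abs, velocity_factor * stimulus speed)`` (deg/s) -- an
    automated surrogate for manual fast-phase screening: slow-phase tracking
    cannot move much faster than the stimulus, resetting movements do.
    Cycles overlapping unbridged sampling gaps are excluded as ``"missing"``.

    Raises when fewer than ``min_valid`` valid cycles remain.
    """
    if rec.profile is None:
        raise ValueError("recording has no stimulus profile")
    threshold = max(velocity_abs, velocity_factor * rec.profile.speed)
    vel = np.gradient(conj, rec.time)
    out = table.copy()
    for i, row in out.iterrows():
        if not row["valid"]:
            continue
        sl = _window_slice(rec.time, row["t_start_s"], row["t_end_s"])
        gap_hit = any(
            g0 < row["t_end_s"] and g1 > row["t_start_s"] for g0, g1 in rec.gaps
        )
        v = vel[sl]
        if gap_hit or not np.isfinite(v).all():
            out.at[i, "valid"] = False
            out.at[i, "reason"] = "missing"
        elif np.max(np.abs(v)) > threshold:
            out.at[i, "valid"] = False
            out.at[i, "reason"] = "fast_phase"
    n_valid = int(out["valid"].sum())
    if n_valid < min_valid:
        raise ValueError(
            f"insufficient valid cycles: {n_valid} < {min_valid} after exclusion"
        )
    return out


def cycle_amplitudes(
    table: pd.DataFrame, rec: TraceRecording, conj: np.ndarray
) -> pd.DataFrame:
    """Fill ``pp_deg``: max minus min of the conjugate trace per cycle window."""
    out = table.copy()
    for i, row in out.iterrows():
        sl = _window_slice(rec.time, row["t_start_s"], row["t_end_s"])
        seg = conj[sl]
        seg = seg[np.isfinite(seg)]
        if seg.size:
            out.at[i, "pp_deg"] = float(seg.max() - seg.min())
    return out


def preprocess_recording(
    rec: TraceRecording,
    rate: float = 200.0,
    cutoff: float = 4.0,
    detect_cutoff: float = 10.0,
    velocity_factor: float = 3.0,
    velocity_abs: float = 20.0,
    min_valid: int = MIN_VALID_CYCLES,
    phase0: float = 0.0,
) -> pd.DataFrame:
    """Full preprocessing chain: resample+filter, segment, average, flag, measure.

    Artifact detection runs on a lightly smoothed conjugate trace
    (``detect_cutoff``, default 10 Hz) rather than the response-filtered one:
    a fast phase completes within ~100 ms, so the 4 Hz amplitude filter
    blunts exactly the velocity transients the exclusion criterion must see.
    """
    if len(rec) < 2:
        raise ValueError("need at least 2 samples to resample")
    if rec.duration <= 1.0 / cutoff:
        raise ValueError("recording shorter than one filter time constant")
    uni = _resample(rec, rate)
    filtered = replace(
        uni,
        stim=lowpass(uni.stim, rate, cutoff),
        left=lowpass(uni.left, rate, cutoff),
        right=lowpass(uni.right, rate, cutoff),
    )
    table = segment_cycles(filtered, phase0=phase0)
    conj_raw = conjugate_average(uni)
    conj = lowpass(conj_raw, rate, cutoff)
    conj_detect = lowpass(conj_raw, rate, detect_cutoff)
    table = detect_artifact_cycles(
        table,
        filtered,
        conj_detect,
        velocity_factor=velocity_factor,
        velocity_abs=velocity_abs,
        min_valid=min_valid,
    )
    return cycle_amplitudes(table, filtered, conj)


def write_cycle_table(table: pd.DataFrame, path, meta: str = "") -> None:
    """Write a cycle table CSV, with an optional '#'-prefixed metadata line."""
    with open(path, "w") as fh:
        if meta:
            fh.write(f"# {meta}\n")
        table.to_csv(fh, index=False)


def read_cycle_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, comment="#")
    missing = set(CYCLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"cycle table missing columns: {sorted(missing)}")
    table["reason"] = table["reason"].fillna("")
    return table[CYCLE_COLUMNS]
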