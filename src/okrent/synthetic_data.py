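"""Synthetic optokinetic-reflex (OKR) sessions.

Generates everything the downstream stages consume, without any external
data: triangular visual-motion stimulus waveforms, cohorts of simulated
eye-angle recordings that obey a parameterized homeostatic plasticity rule,
and (optionally) rendered grayscale image stacks of two dark elliptical
"eyes" for validating the tracker.

The plasticity rule
-------------------
During a training session of K full stimulus cycles, the per-cycle
peak-to-peak response amplitude relaxes geometrically toward a setpoint::

    A[k+1] = A[k] + rho * (x0 - A[k]) + noise

where ``x0`` is the setpoint amplitude (deg) and ``rho`` the per-cycle
retention.  The session-level observables are the *immediate* response I
(mean of the first ``n_edge`` cycles) and the *entrained* response E (mean of
the last ``n_edge``).  ``rho`` is calibrated as::

    rho = 1 - (1 + m)**(1 / (K - n_edge))

so that the amplitude-change-vs-immediate-amplitude relation measured by that
windowed protocol has slope exactly ``m`` and x-axis zero-intercept exactly
``x0`` in expectation: the ratio of the last-window to first-window mean
deviation from ``x0`` is ``(1+m)`` by construction, hence
``E - I = m * (I - x0)``.

Animal-level residual scatter is realized as a per-animal offset eps added
to the amplitude trajectory along a ramp that is zero over the first
measurement window and averages one over the last: the measured change is
``m * (I - x0) + eps`` exactly, with the residual uncorrelated with the
measured immediate response.  eps is drawn so that the entrained level is
multiplied by a mean-one lognormal factor, which keeps amplitudes positive
and the residual SD homoskedastic (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

from .signal_preprocess import TraceRecording

#: Stimulus profile ids -> (speed deg/s, period s): the four velocity/cycle
#: duration combinations used for training.
PROFILE_TABLE: dict[int, tuple[float, float]] = {
    1: (4.0, 20.0),
    2: (8.0, 20.0),
    3: (8.0, 10.0),
    4: (4.0, 10.0),
}

#: Initial amplitudes are drawn from a normal truncated at this floor (deg).
AMPLITUDE_FLOOR = 0.5

#: Amplitude trajectories are clipped at this floor (deg); effectively never
#: reached under realistic parameters.
TRAJECTORY_FLOOR = 0.05

CAMERA_FPS = 30.0


@dataclass(frozen=True)
class StimulusProfile:
    """Triangular position stimulus: constant-|velocity| bidirectional motion.

    ``speed`` in deg/s, ``period`` (full cycle duration) in s, ``duration``
    total stimulation time in s (default 30 min).  The half-cycle excursion
    (peak-to-peak positional travel) is ``speed * period / 2``.
    """

    speed: float
    period: float
    duration: float = 1800.0

    def __post_init__(self) -> None:
        if self.speed <= 0:
            raise ValueError("speed must be positive")
        if self.period <= 0:
            raise ValueError("period must be positive")

    @classmethod
    def from_id(cls, profile_id: int, duration: float = 1800.0) -> "StimulusProfile":
        if profile_id not in PROFILE_TABLE:
            raise ValueError(f"unknown stimulus profile id {profile_id!r} (1-4)")
        speed, period = PROFILE_TABLE[profile_id]
        return cls(speed=speed, period=period, duration=duration)

    @property
    def half_cycle_excursion(self) -> float:
        """Peak-to-peak positional travel per half cycle (deg)."""
        return self.speed * self.period / 2.0

    @property
    def n_cycles(self) -> int:
        """Number of complete stimulus cycles in the session."""
        return int(math.floor(self.duration / self.period + 1e-9))


@dataclass(frozen=True)
class PlasticityParams:
    """Ground-truth homeostatic rule for a simulated cohort.

    ``slope_m``: regression slope of amplitude change vs immediate amplitude
    (dimensionless, in (-1, 0]).  ``setpoint_x0``: amplitude (deg) at which
    training induces no change.  ``residual_sd``: animal-level residual
    scatter of the amplitude change (deg).  ``cycle_count``: K, full cycles
    in the session.  ``n_edge``: width of the immediate/entrained measurement
    windows the retention is calibrated to.
    """

    slope_m: float
    setpoint_x0: float
    residual_sd: float = 0.0
    cycle_count: int = 90
    n_edge: int = 5

    def __post_init__(self) -> None:
        if not (-1.0 < self.slope_m <= 0.0):
            raise ValueError("slope_m must lie in (-1, 0]")
        if self.setpoint_x0 < 0:
            raise ValueError("setpoint_x0 must be >= 0")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        if self.cycle_count <= self.n_edge:
            raise ValueError("cycle_count must exceed n_edge")

    @property
    def retention(self) -> float:
        """Per-cycle retention rho in [0, 1)."""
        rho = 1.0 - (1.0 + self.slope_m) ** (1.0 / (self.cycle_count - self.n_edge))
        if not (0.0 <= rho < 1.0):
            raise ValueError("retention outside [0, 1)")
        return rho

    def window_factor(self) -> float:
        """Mean of (1-rho)**k over the first measurement window (k=0..n_edge-1)."""
        r = 1.0 - self.retention
        return float(np.mean(r ** np.arange(self.n_edge)))

    def predicted_immediate(self, initial: float) -> float:
        """Expected first-window mean amplitude for starting amplitude ``initial``."""
        x0 = self.setpoint_x0
        return x0 + self.window_factor() * (initial - x0)

    def predicted_entrained(self, initial: float, residual: float = 0.0) -> float:
        """Expected last-window mean amplitude for starting amplitude ``initial``."""
        x0 = self.setpoint_x0
        return (
            x0
            + (1.0 + self.slope_m) * self.window_factor() * (initial - x0)
            + residual
        )


@dataclass(frozen=True)
class AnimalSpec:
    """Per-animal simulation parameters.

    ``initial_amplitude``: peak-to-peak response at training onset (deg).
    ``gain_noise_sd``: per-cycle noise on the amplitude update (deg).
    ``fast_phase_rate``: resetting fast-phase events per minute.
    ``timestamp_jitter_sd``: camera timing jitter (s) around the nominal
    30 frames/s grid.  ``eye_noise_sd``: per-sample independent angle noise on
    each eye (deg), emulating tracker pixel noise.
    """

    initial_amplitude: float
    gain_noise_sd: float = 0.05
    fast_phase_rate: float = 0.2
    timestamp_jitter_sd: float = 0.003
    eye_noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_amplitude <= 0:
            raise ValueError("initial_amplitude must be positive")
        for name in ("gain_noise_sd", "fast_phase_rate", "timestamp_jitter_sd", "eye_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class RenderGeometry:
    """Layout of the rendered top-view frame: two dark ellipses on light ground."""

    shape: tuple[int, int] = (120, 200)  # rows, cols
    center_left: tuple[float, float] = (60.0, 55.0)  # row, col
    center_right: tuple[float, float] = (60.0, 145.0)
    semi_major: float = 30.0
    semi_minor: float = 15.0
    background: int = 200
    foreground: int = 40

    def __post_init__(self) -> None:
        if not (self.semi_major > self.semi_minor > 0):
            raise ValueError("require semi_major > semi_minor > 0 (orientation undefined otherwise)")
        d = math.hypot(
            self.center_left[0] - self.center_right[0],
            self.center_left[1] - self.center_right[1],
        )
        if d <= 2 * self.semi_major:
            raise ValueError("eyes overlap: center distance must exceed 2*semi_major")

    def rois(self, margin: float = 5.0) -> tuple[tuple[int, int, int, int], ...]:
        """Bounding rectangles (min_row, min_col, max_row, max_col) per eye."""
        out = []
        for cr, cc in (self.center_left, self.center_right):
            r = self.semi_major + margin
            out.append(
                (
                    max(0, int(cr - r)),
                    max(0, int(cc - r)),
                    min(self.shape[0], int(cr + r) + 1),
                    min(self.shape[1], int(cc + r) + 1),
                )
            )
        return tuple(out)


# ---------------------------------------------------------------------------
# stimulus
# ---------------------------------------------------------------------------

def triangle_wave(t: np.ndarray, period: float, amplitude: float) -> np.ndarray:
    """Triangle wave starting at +amplitude, descending, period ``period``."""
    phase = np.mod(np.asarray(t, dtype=float), period) / period
    return amplitude * np.where(phase < 0.5, 1.0 - 4.0 * phase, 4.0 * phase - 3.0)


def make_stimulus(
    profile: StimulusProfile, rate: float = 200.0
) -> tuple[np.ndarray, np.ndarray]:
    """Uniformly sampled stimulus position trace (deg).

    Starts at the positive extremum and alternates direction every half
    period with constant |velocity| = ``profile.speed``.
    """
    if profile.duration <= 0:
        raise ValueError("non-positive duration: empty stimulus trace")
    n = int(round(profile.duration * rate)) + 1
    t = np.arange(n) / rate
    amp = profile.speed * profile.period / 4.0
    return t, triangle_wave(t, profile.period, amp)


# ---------------------------------------------------------------------------
# per-animal simulation
# ---------------------------------------------------------------------------

def residual_ramp(params: PlasticityParams) -> np.ndarray:
    """Weights w[1..K] along which an animal's residual offset accrues.

    Zero over the first measurement window (so the residual cannot leak into
    the measured immediate response and correlate with the regressor) and
    normalized to average one over the last window; in between it follows
    the same geometric time course as the relaxation itself.
    """
    K, n_edge = params.cycle_count, params.n_edge
    r = 1.0 - params.retention
    k = np.arange(1, K + 1)
    raw = np.where(k <= n_edge, 0.0, 1.0 - r ** (k - n_edge))
    norm = raw[-n_edge:].mean()
    return raw / norm if norm > 0 else raw


def amplitude_series(
    initial: float,
    params: PlasticityParams,
    residual: float = 0.0,
    gain_noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-cycle amplitude sequence A[1..K] under the homeostatic update.

    ``residual`` is the animal's session-level change offset eps (deg),
    applied along :func:`residual_ramp` so that the windowed change equals
    ``m * (I_window - x0) + eps``.
    """
    x0 = params.setpoint_x0
    rho = params.retention
    K = params.cycle_count
    amps = np.empty(K)
    amps[0] = initial
    if gain_noise_sd > 0 and rng is not None:
        noise = rng.normal(0.0, gain_noise_sd, K - 1)
    else:
        noise = np.zeros(K - 1)
    for k in range(1, K):
        amps[k] = amps[k - 1] + rho * (x0 - amps[k - 1]) + noise[k - 1]
    if residual != 0.0:
        amps = amps + residual * residual_ramp(params)
    return np.maximum(amps, TRAJECTORY_FLOOR)


def _draw_residual(
    initial: float, params: PlasticityParams, rng: np.random.Generator
) -> float:
    """Animal-level residual eps of the session amplitude change (deg).

    Generated as ``eps = E_model * (L - 1)`` with L a mean-one lognormal
    whose scale is set per animal so that SD(eps) = residual_sd
    (homoskedastic); the lognormal form keeps the entrained level
    ``E_model * L`` positive even at small amplitudes.
    """
    if params.residual_sd == 0.0:
        return 0.0
    e_model = max(params.predicted_entrained(initial), TRAJECTORY_FLOOR)
    s2 = math.log1p((params.residual_sd / e_model) ** 2)
    lognorm = math.exp(rng.normal(-s2 / 2.0, math.sqrt(s2)))
    return e_model * (lognorm - 1.0)


def _fast_phase_waveform(
    t: np.ndarray, rng: np.random.Generator, rate_per_min: float, duration: float
) -> np.ndarray:
    """Sum of brief triangular 'hat' transients emulating resetting fast phases.

    Each event is a 5-15 deg excursion completing within ~100 ms, i.e. a
    transient eye speed of >= 100 deg/s, far above slow-phase tracking.
    """
    wave = np.zeros_like(t)
    n_events = rng.poisson(rate_per_min * duration / 60.0)
    if n_events == 0:
        return wave
    centers = rng.uniform(1.0, max(duration - 1.0, 1.0), n_events)
    amplitudes = rng.uniform(5.0, 15.0, n_events) * rng.choice([-1.0, 1.0], n_events)
    half = 0.05  # s rise/fall
    for tc, amp in zip(centers, amplitudes):
        wave += amp * np.clip(1.0 - np.abs(t - tc) / half, 0.0, None)
    return wave


def simulate_animal(
    spec: AnimalSpec,
    profile: StimulusProfile,
    params: PlasticityParams,
    rng: np.random.Generator | None = None,
    return_truth: bool = False,
):
    """Simulate one animal's 30-min training session.

    The conjugate eye response within cycle k is the stimulus triangle scaled
    to peak-to-peak amplitude A[k]; both eyes are that response plus small
    independent noise; timestamps sit on a jittered ~30 frames/s grid; fast
    phases appear as brief high-velocity transients.

    Returns a :class:`TraceRecording`, or ``(recording, truth)`` when
    ``return_truth`` is set, with ``truth`` holding the generator ground
    truth (initial amplitude, animal setpoint, predicted windowed I and E).
    """
    if params.cycle_count != profile.n_cycles:
        params = PlasticityParams(
            slope_m=params.slope_m,
            setpoint_x0=params.setpoint_x0,
            residual_sd=params.residual_sd,
            cycle_count=profile.n_cycles,
            n_edge=params.n_edge,
        )
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    eps = _draw_residual(spec.initial_amplitude, params, rng)
    amps = amplitude_series(
        spec.initial_amplitude,
        params,
        residual=eps,
        gain_noise_sd=spec.gain_noise_sd,
        rng=rng,
    )

    n = int(math.floor(profile.duration * CAMERA_FPS)) + 1
    base = np.arange(n) / CAMERA_FPS
    if spec.timestamp_jitter_sd > 0:
        t = np.sort(base + rng.normal(0.0, spec.timestamp_jitter_sd, n))
        t -= min(t[0], 0.0)  # keep the session starting at/after 0
        # enforce strict monotonicity at float resolution
        t = np.maximum.accumulate(t + np.arange(n) * 1e-9)
    else:
        t = base

    stim_amp = profile.speed * profile.period / 4.0
    stim = triangle_wave(t, profile.period, stim_amp)
    cycle_of = np.minimum(
        (t // profile.period).astype(int), params.cycle_count - 1
    )
    gain = amps[cycle_of] / profile.half_cycle_excursion
    conj = gain * stim
    conj = conj + _fast_phase_waveform(t, rng, spec.fast_phase_rate, profile.duration)
    left = conj + rng.normal(0.0, spec.eye_noise_sd, n)
    right = conj + rng.normal(0.0, spec.eye_noise_sd, n)

    rec = TraceRecording(time=t, stim=stim, left=left, right=right, profile=profile)
    if not return_truth:
        return rec
    truth = {
        "initial": spec.initial_amplitude,
        "residual_eps": eps,
        "immediate_pred": params.predicted_immediate(spec.initial_amplitude),
        "entrained_pred": params.predicted_entrained(spec.initial_amplitude, eps),
        "n_cycles": params.cycle_count,
    }
    return rec, truth


def simulate_cohort(
    n: int,
    amplitude_mean: float,
    amplitude_sd: float,
    profile: StimulusProfile,
    params: PlasticityParams,
    seed: int,
    spec_kwargs: dict | None = None,
) -> tuple[list[TraceRecording], pd.DataFrame]:
    """Simulate ``n`` animals with initial amplitudes from a truncated normal.

    The distribution is N(mean, sd) truncated below at
    :data:`AMPLITUDE_FLOOR`.  Returns the recordings plus a ground-truth
    table (one row per animal) for recovery tests.  Fully reproducible for a
    fixed seed.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    if amplitude_sd <= 0:
        raise ValueError("amplitude_sd must be positive")
    rng = np.random.default_rng(seed)
    a = (AMPLITUDE_FLOOR - amplitude_mean) / amplitude_sd
    initials = truncnorm.rvs(
        a, np.inf, loc=amplitude_mean, scale=amplitude_sd, size=n, random_state=rng
    )
    spec_kwargs = spec_kwargs or {}
    recordings, rows = [], []
    for i, initial in enumerate(initials):
        animal_seed = int(rng.integers(0, 2**31 - 1))
        spec = AnimalSpec(
            initial_amplitude=float(initial), seed=animal_seed, **spec_kwargs
        )
        rec, truth = simulate_animal(
            spec, profile, params, rng=np.random.default_rng(animal_seed),
            return_truth=True,
        )
        recordings.append(rec)
        rows.append({"animal_id": i, "seed": animal_seed, **truth})
    return recordings, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rendering (tracker phantom)
# ---------------------------------------------------------------------------

def render_frames(
    recording: TraceRecording,
    geometry: RenderGeometry,
    max_frames: int | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a recording as an 8-bit grayscale stack of two dark ellipses.

    The long axis of each ellipse is rotated to the frame's eye angle
    (degrees, counterclockwise positive with the image y-axis taken upward).
    Returns the stack (frames, rows, cols) and a ground-truth table of the
    rendered angles.
    """
    from skimage.draw import ellipse as sk_ellipse

    n = len(recording) if max_frames is None else min(max_frames, len(recording))
    h, w = geometry.shape
    stack = np.full((n, h, w), geometry.background, dtype=np.uint8)
    rows = []
    for i in range(n):
        for (cr, cc), angle in (
            (geometry.center_left, recording.left[i]),
            (geometry.center_right, recording.right[i]),
        ):
            rr, cols = sk_ellipse(
                cr,
                cc,
                geometry.semi_minor,
                geometry.semi_major,
                shape=(h, w),
                rotation=np.radians(angle),
            )
            stack[i, rr, cols] = geometry.foreground
        rows.append(
            {
                "frame": i,
                "time_s": recording.time[i],
                "left_deg": recording.left[i],
                "right_deg": recording.right[i],
            }
        )
    return stack, pd.DataFrame(rows)


def make_ellipsoid_mask_stack(
    semi_axes_um: tuple[float, float, float],
    pixel_size_um: float,
    thickness_um: float,
    pad_um: float = 5.0,
) -> np.ndarray:
    """Boolean mask stack of a solid ellipsoid sliced at ``thickness_um``.

    Slices sample the ellipsoid cross-section at each slice's mid-plane --
    a phantom with the analytic volume (4/3) pi a b c for validating
    area-times-thickness volume estimation.
    """
    a, b, c = semi_axes_um
    n_slices = int(math.ceil(2 * c / thickness_um))
    half_w = a + pad_um
    half_h = b + pad_um
    nx = int(math.ceil(2 * half_w / pixel_size_um))
    ny = int(math.ceil(2 * half_h / pixel_size_um))
    x = (np.arange(nx) + 0.5) * pixel_size_um - half_w
    y = (np.arange(ny) + 0.5) * pixel_size_um - half_h
    xx, yy = np.meshgrid(x, y)
    stack = np.zeros((n_slices, ny, nx), dtype=bool)
    for k in range(n_slices):
        z = -c + (k + 0.5) * thickness_um
        rem = 1.0 - (z / c) ** 2
        if rem <= 0:
            continue
        stack[k] = (xx / (a * math.sqrt(rem))) ** 2 + (
            yy / (b * math.sqrt(rem))
        ) ** 2 <= 1.0
    return stack


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def write_trace_csv(rec: TraceRecording, path, meta: str = "") -> None:
    """Trace CSV: columns time_s, stim_deg, left_deg, right_deg (header row)."""
    frame = pd.DataFrame(
        {
            "time_s": rec.time,
            "stim_deg": rec.stim,
            "left_deg": rec.left,
            "right_deg": rec.right,
        }
    )
    with open(path, "w") as fh:
        if meta:
            fh.write(f"# {meta}\n")
        frame.to_csv(fh, index=False)


def read_trace_csv(path, profile: StimulusProfile | None = None) -> TraceRecording:
    frame = pd.read_csv(path, comment="#")
    required = {"time_s", "stim_deg", "left_deg", "right_deg"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"trace file missing columns: {sorted(missing)}")
    return TraceRecording(
        time=frame["time_s"].to_numpy(),
        stim=frame["stim_deg"].to_numpy(),
        left=frame["left_deg"].to_numpy(),
        right=frame["right_deg"].to_numpy(),
        profile=profile,
    )


def load_cohort_config(path):
    """Read a YAML cohort spec.

    Expected keys: ``profile`` (id 1-4 or {speed, period, duration}), ``n``,
    ``amplitude_mean``, ``amplitude_sd``, ``plasticity`` ({slope_m,
    setpoint_x0, residual_sd}), ``seed``.  Returns
    (n, mean, sd, StimulusProfile, PlasticityParams, seed).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    prof = cfg["profile"]
    if isinstance(prof, dict):
        profile = StimulusProfile(**prof)
    else:
        profile = StimulusProfile.from_id(int(prof), duration=cfg.get("duration", 1800.0))
    plast = cfg.get("plasticity", {})
    params = PlasticityParams(
        slope_m=float(plast.get("slope_m", 0.0)),
        setpoint_x0=float(plast.get("setpoint_x0", 0.0)),
        residual_sd=float(plast.get("residual_sd", 0.0)),
        cycle_count=profile.n_cycles,
    )
    return (
        int(cfg["n"]),
        float(cfg["amplitude_mean"]),
        float(cfg["amplitude_sd"]),
        profile,
        params,
        int(cfg.get("seed", 0)),
    )
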