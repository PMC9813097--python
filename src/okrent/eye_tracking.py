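"""Moment-based ellipse-fit eye tracking on grayscale image stacks.

Each frame shows two dark eyes on a light background (infrared top view).
Per frame and per eye: threshold the region of interest (Otsu), keep the
largest dark connected component, and fit an ellipse from the mask's
second-order central moments.  The reported eye position is the angle between
the ellipse's long axis and the horizontal image axis, in degrees,
counterclockwise positive with the image y-axis taken upward (raster rows
flipped), mapped to (-90, +90] and temporally unwrapped across frames.

Moments rather than boundary least-squares: on filled masks the moment fit is
robust to boundary rasterization and has an exact small-case oracle
(the orientation of a solid ellipse's covariance eigenvectors).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

#: An ellipse flatter than this axis ratio has a well-defined orientation.
MIN_AXIS_RATIO = 1.2

#: Fraction of frames that may be missing per eye before tracking fails.
MAX_MISSING_FRACTION = 0.5

Rect = tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col)


@dataclass(frozen=True)
class EllipseFit:
    """Moment ellipse of a binary mask.

    ``center`` is (row, col); ``orientation`` in degrees, (-90, +90],
    counterclockwise positive (y-up convention); ``eccentricity_ok`` is False
    when the mask is too round for the orientation to be meaningful.
    """

    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    orientation: float
    eccentricity_ok: bool


@dataclass
class EyeTrack:
    """Per-frame orientation series for both eyes (deg; NaN where missing)."""

    time: np.ndarray
    left: np.ndarray
    right: np.ndarray
    left_ok: np.ndarray
    right_ok: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "left_deg": self.left,
                "right_deg": self.right,
                "left_ok": self.left_ok,
                "right_ok": self.right_ok,
            }
        )

    def to_csv(self, path, meta: str = "") -> None:
        with open(path, "w") as fh:
            if meta:
                fh.write(f"# {meta}\n")
            self.to_frame().to_csv(fh, index=False)


def _check_rois(shape: tuple[int, int], rois: tuple[Rect, Rect]) -> None:
    h, w = shape
    for r0, c0, r1, c1 in rois:
        if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
            raise ValueError(f"ROI {(r0, c0, r1, c1)} outside frame bounds {shape}")
    (a0, b0, a1, b1), (x0, y0, x1, y1) = rois
    if a0 < x1 and x0 < a1 and b0 < y1 and y0 < b1:
        raise ValueError("ROIs overlap")


def segment_eyes(
    frame: np.ndarray,
    rois: tuple[Rect, Rect],
    polarity: str = "dark",
) -> tuple[np.ndarray, np.ndarray]:
    """Binary mask of each eye: largest thresholded component within its ROI.

    ``polarity`` is ``"dark"`` for dark eyes on a light background (the
    default under infrared illumination) or ``"light"`` for the inverse.
    Returns full-frame boolean masks; a mask is all-False when its ROI
    contains no component (caller flags the frame as missing).
    """
    _check_rois(frame.shape, rois)
    masks = []
    for r0, c0, r1, c1 in rois:
        sub = np.asarray(frame[r0:r1, c0:c1], dtype=float)
        full = np.zeros(frame.shape, dtype=bool)
        if sub.max() > sub.min():
            thr = threshold_otsu(sub)
            binary = sub < thr if polarity == "dark" else sub > thr
            if binary.any():
                labels = cc_label(binary)
                counts = np.bincount(labels.ravel())
                counts[0] = 0
                full[r0:r1, c0:c1] = labels == int(np.argmax(counts))
        masks.append(full)
    return masks[0], masks[1]


def fit_ellipse(mask: np.ndarray, min_axis_ratio: float = MIN_AXIS_RATIO) -> EllipseFit:
    """Ellipse parameters from the second-order central moments of a mask.

    Orientation: theta = 0.5 * atan2(2*mu11, mu20 - mu02) with image
    coordinates x = column, y = -row (counterclockwise positive), mapped to
    (-90, +90].  Semi-axes from the covariance eigenvalues: for a solid
    ellipse the second moment along the major axis is a^2/4, so
    a = 2*sqrt(lambda_max).  A near-circular mask (a/b below
    ``min_axis_ratio``) gets ``eccentricity_ok = False``.
    """
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("empty mask")
    x = cols.astype(float)
    y = -rows.astype(float)  # y-axis upward
    xc, yc = x.mean(), y.mean()
    dx, dy = x - xc, y - yc
    mu20 = np.mean(dx * dx)
    mu02 = np.mean(dy * dy)
    mu11 = np.mean(dx * dy)
    theta = 0.5 * np.degrees(np.arctan2(2.0 * mu11, mu20 - mu02))
    if theta <= -90.0:
        theta += 180.0
    elif theta > 90.0:
        theta -= 180.0
    common = np.sqrt(max((mu20 - mu02) ** 2 + 4.0 * mu11**2, 0.0))
    lam_max = (mu20 + mu02 + common) / 2.0
    lam_min = (mu20 + mu02 - common) / 2.0
    a = 2.0 * np.sqrt(max(lam_max, 0.0))
    b = 2.0 * np.sqrt(max(lam_min, 0.0))
    ok = b > 0 and (a / b) >= min_axis_ratio
    return EllipseFit(
        center=(float(-yc), float(xc)),
        semi_major=float(a),
        semi_minor=float(b),
        orientation=float(theta),
        eccentricity_ok=bool(ok),
    )


def _unwrap_step(prev: float, theta: float) -> float:
    """Pick the 180-deg-equivalent of ``theta`` closest to ``prev``."""
    return theta + 180.0 * round((prev - theta) / 180.0)


def track_eyes(
    stack: np.ndarray,
    rois: tuple[Rect, Rect],
    timestamps: np.ndarray | None = None,
    polarity: str = "dark",
    min_axis_ratio: float = MIN_AXIS_RATIO,
    max_missing: float = MAX_MISSING_FRACTION,
) -> EyeTrack:
    """Frame-by-frame eye angles for an image stack.

    Frames whose segmentation is empty or whose ellipse is too round are
    flagged missing (NaN); no interpolation happens here (that is the
    preprocessing stage's job).  Orientation series are unwrapped by choosing
    the +-180-deg-equivalent closest to the previous valid frame.  Raises
    when more than ``max_missing`` of the frames are missing for either eye.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise ValueError("stack must be a non-empty (frames, rows, cols) array")
    n = stack.shape[0]
    if timestamps is None:
        timestamps = np.arange(n, dtype=float)
    timestamps = np.asarray(timestamps, dtype=float)
    if timestamps.size != n:
        raise ValueError("timestamps length must match frame count")

    angles = np.full((2, n), np.nan)
    ok = np.zeros((2, n), dtype=bool)
    prev = [np.nan, np.nan]
    for i in range(n):
        masks = segment_eyes(stack[i], rois, polarity=polarity)
        for e, mask in enumerate(masks):
            if not mask.any():
                continue
            fit = fit_ellipse(mask, min_axis_ratio=min_axis_ratio)
            if not fit.eccentricity_ok:
                continue
            theta = fit.orientation
            if np.isfinite(prev[e]):
                theta = _unwrap_step(prev[e], theta)
            angles[e, i] = theta
            ok[e, i] = True
            prev[e] = theta

    for e, name in enumerate(("left", "right")):
        frac = 1.0 - ok[e].mean()
        if frac > max_missing:
            raise ValueError(
                f"{name} eye missing in {frac:.0%} of frames (> {max_missing:.0%})"
            )
    return EyeTrack(
        time=timestamps,
        left=angles[0],
        right=angles[1],
        left_ok=ok[0],
        right_ok=ok[1],
    )
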