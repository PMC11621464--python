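"""Image-based activity extraction and open-field walking speed.

Three extractors convert image sequences into activity series:

- :func:`pixel_change_activity` — per transition, the proportion of ROI
  pixels whose adaptively thresholded (binary) value changed; estimates the
  proportion of ants that moved between successive nest images.
- :func:`optical_flow_activity` — mean dense optical-flow magnitude per
  transition, for noisy camcorder footage where thresholding is unreliable.
- :func:`centroid_displacement_series` — per-frame centroid of a single
  dark object (an isolated ant) and its Euclidean displacement.

:func:`open_field_speed` turns a coordinate track into a mean moving speed
in body-lengths/s, averaging only frames above the 0.5 BL/s moving
threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import convolve, uniform_filter
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .series import ActivityTimeSeries
from .synth import ImageStack

__all__ = [
    "OpenFieldResult",
    "NeverMovingError",
    "DetectionError",
    "pixel_change_activity",
    "optical_flow_activity",
    "horn_schunck_flow",
    "open_field_speed",
    "centroid_displacement_series",
    "read_image_stack",
]


class NeverMovingError(RuntimeError):
    """No frame exceeded the moving threshold; mean moving speed undefined."""


class DetectionError(RuntimeError):
    """Object detection failed in too many frames."""


@dataclass(frozen=True)
class OpenFieldResult:
    """Open-field walking-speed summary for one assay."""

    mean_moving_speed: float  # body-lengths / s over supra-threshold frames
    moving_frame_count: int
    total_frame_count: int
    body_length_px: float


# ---------------------------------------------------------------------------
# colony-level extractors
# ---------------------------------------------------------------------------

def _adaptive_binarize(frame: np.ndarray, sensitivity: float) -> np.ndarray:
    """Foreground (dark-object) mask by local-mean adaptive thresholding.

    A pixel is foreground when it is darker than its local mean by more
    than ``(1 - sensitivity) / 2`` times the frame's intensity range, with
    the averaging window about 1/8 of the shorter frame side. Higher
    sensitivity lowers the required darkness margin (more pixels detected).
    Both the local mean and the range-relative offset scale with any global
    affine intensity change, so the mask is invariant to brightness shifts.
    """
    h, w = frame.shape
    block = max(3, (min(h, w) // 8) | 1)  # odd window
    local_mean = uniform_filter(frame, size=block, mode="reflect")
    spread = float(frame.max() - frame.min())
    if spread == 0:
        warnings.warn("constant-intensity frame: threshold undefined, "
                      "binarizing to background", stacklevel=3)
        return np.zeros_like(frame, dtype=bool)
    offset = 0.5 * (1.0 - sensitivity) * spread
    return frame < local_mean - offset


def pixel_change_activity(
    stack: ImageStack,
    roi: tuple[int, int, int, int] | None = None,
    sensitivity: float = 0.5,
) -> ActivityTimeSeries:
    """Proportion of ROI pixels whose binary value changes per transition.

    ``roi`` is (x0, y0, x1, y1), 0-based half-open in pixel coordinates;
    ``None`` uses the whole frame. Output length is ``n_frames - 1``.
    """
    if not 0 < sensitivity < 1:
        raise ValueError("sensitivity must be in (0, 1)")
    h, w = stack.shape
    if roi is None:
        roi = (0, 0, w, h)
    x0, y0, x1, y1 = roi
    if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
        raise ValueError(f"roi {roi} empty or outside {w}x{h} frame bounds")
    n_px = (x1 - x0) * (y1 - y0)
    masks = np.stack(
        [_adaptive_binarize(f[y0:y1, x0:x1], sensitivity) for f in stack.frames]
    )
    changed = (masks[1:] != masks[:-1]).sum(axis=(1, 2))
    return ActivityTimeSeries(
        values=changed / n_px,
        sample_interval_s=stack.frame_interval_s,
        source="pixel_change",
    )


_HS_AVG = np.array(
    [[1 / 12, 1 / 6, 1 / 12], [1 / 6, 0.0, 1 / 6], [1 / 12, 1 / 6, 1 / 12]]
)


def horn_schunck_flow(
    a: np.ndarray, b: np.ndarray, alpha: float = 1.0, n_iter: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Dense (u, v) displacement field between two frames, Horn–Schunck style.

    Minimizes the brightness-constancy residual plus an ``alpha``-weighted
    global smoothness penalty by the classic Jacobi iteration. Displacements
    are in pixels per transition; flow is zero wherever both frames carry no
    gradient information.
    """
    ky = np.array([[-1.0, -1.0], [1.0, 1.0]]) * 0.25
    kx = np.array([[-1.0, 1.0], [-1.0, 1.0]]) * 0.25
    fy = convolve(a, ky) + convolve(b, ky)
    fx = convolve(a, kx) + convolve(b, kx)
    ft = convolve(b - a, np.full((2, 2), 0.25))
    u = np.zeros_like(a)
    v = np.zeros_like(a)
    for _ in range(n_iter):
        ub = convolve(u, _HS_AVG)
        vb = convolve(v, _HS_AVG)
        d = (fx * ub + fy * vb + ft) / (alpha**2 + fx**2 + fy**2)
        u = ub - fx * d
        v = vb - fy * d
    return u, v


def optical_flow_activity(
    stack: ImageStack, alpha: float = 1.0, n_iter: int = 100
) -> ActivityTimeSeries:
    """Mean dense optical-flow magnitude per transition (pixels/transition).

    Per transition a Horn–Schunck displacement field is estimated from the
    brightness-constancy constraint with global smoothness regularization,
    and the value is the mean flow-vector magnitude over the frame. Each
    frame pair is jointly rescaled to [0, 1] first, which makes the output
    invariant to global affine intensity changes. All-uniform frames give
    zero flow (not an error).
    """
    values = np.empty(stack.n_frames - 1)
    for t in range(stack.n_frames - 1):
        a, b = stack.frames[t], stack.frames[t + 1]
        lo = min(a.min(), b.min())
        hi = max(a.max(), b.max())
        if hi > lo:
            a = (a - lo) / (hi - lo)
            b = (b - lo) / (hi - lo)
        u, v = horn_schunck_flow(a, b, alpha=alpha, n_iter=n_iter)
        values[t] = float(np.sqrt(u**2 + v**2).mean())
    return ActivityTimeSeries(
        values=values,
        sample_interval_s=stack.frame_interval_s,
        source="optical_flow",
    )


# ---------------------------------------------------------------------------
# individual-level tracking
# ---------------------------------------------------------------------------

def _locate_dark_object(frame: np.ndarray) -> tuple[float, float] | None:
    """Centroid of the largest dark connected component, or None on failure.

    Failure means nothing is detected or detection is ambiguous (a second
    component at least half the largest one's area). Ties between equal
    components break toward the lowest (row, col) centroid.
    """
    if np.ptp(frame) == 0:
        return None
    fg = frame < threshold_otsu(frame)
    lab = label(fg)
    props = regionprops(lab)
    if not props:
        return None
    props.sort(key=lambda p: (-p.area, p.centroid))
    if len(props) > 1 and props[1].area >= 0.5 * props[0].area:
        return None
    return props[0].centroid  # (row, col)


def centroid_displacement_series(stack: ImageStack) -> ActivityTimeSeries:
    """Per-transition centroid displacement of a single dark object (pixels).

    Frames where detection fails are flagged and the last valid centroid is
    carried forward; more than 20% failed frames is an error.
    """
    centroids: list[tuple[float, float] | None] = [
        _locate_dark_object(f) for f in stack.frames
    ]
    n_failed = sum(c is None for c in centroids)
    if n_failed > 0.2 * stack.n_frames:
        raise DetectionError(
            f"object detection failed in {n_failed}/{stack.n_frames} frames"
        )
    # carry the last valid centroid through failed frames
    filled: list[tuple[float, float]] = []
    last = next(c for c in centroids if c is not None)
    for c in centroids:
        last = c if c is not None else last
        filled.append(last)
    pts = np.asarray(filled)
    disp = np.sqrt(((pts[1:] - pts[:-1]) ** 2).sum(axis=1))
    return ActivityTimeSeries(
        values=disp,
        sample_interval_s=stack.frame_interval_s,
        level="individual",
        source="centroid_displacement",
    )


def open_field_speed(
    track: np.ndarray,
    body_length_px: float,
    fps: float,
    moving_threshold_bl_s: float = 0.5,
) -> OpenFieldResult:
    """Mean moving speed in body-lengths/s from an (n, 2) coordinate track.

    Instantaneous speed is the per-transition Euclidean displacement times
    ``fps`` divided by the body length; only frames whose speed exceeds the
    moving threshold enter the mean. A track that never exceeds the
    threshold raises :class:`NeverMovingError` (the mean of zero moving
    frames is undefined, not zero).
    """
    track = np.asarray(track, dtype=float)
    if track.ndim != 2 or track.shape[1] != 2 or track.shape[0] < 2:
        raise ValueError("track must be an (n >= 2, 2) coordinate array")
    if body_length_px <= 0 or fps <= 0:
        raise ValueError("body_length_px and fps must be > 0")
    disp = np.sqrt(((track[1:] - track[:-1]) ** 2).sum(axis=1))
    speeds = disp * fps / body_length_px
    moving = speeds > moving_threshold_bl_s
    if not moving.any():
        raise NeverMovingError(
            f"no frame exceeded {moving_threshold_bl_s} body-lengths/s"
        )
    return OpenFieldResult(
        mean_moving_speed=float(speeds[moving].mean()),
        moving_frame_count=int(moving.sum()),
        total_frame_count=int(speeds.size),
        body_length_px=float(body_length_px),
    )


# ---------------------------------------------------------------------------
# image I/O
# ---------------------------------------------------------------------------

def read_image_stack(source: str | Path, frame_interval_s: float = 30.0) -> ImageStack:
    """Read a stack from a multi-page TIFF or a directory of image files.

    Directory entries are ordered lexicographically; grayscale conversion
    averages color channels.
    """
    import tifffile
    from skimage.io import imread

    source = Path(source)
    if source.is_dir():
        paths = sorted(p for p in source.iterdir()
                       if p.suffix.lower() in {".png", ".tif", ".tiff"})
        if len(paths) < 2:
            raise ValueError(f"need >= 2 frames in {source}")
        frames = [np.asarray(imread(p), dtype=float) for p in paths]
    else:
        frames = [np.asarray(f, dtype=float) for f in tifffile.imread(source)]
    frames = [f.mean(axis=-1) if f.ndim == 3 else f for f in frames]
    return ImageStack(frames=np.stack(frames), frame_interval_s=frame_interval_s)
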