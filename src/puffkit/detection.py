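"""Threshold-cluster event detection and sub-pixel centroid localization.

Events are segmented on the blurred, SD-normalized detection stack: voxels
brighter than a threshold are grouped into 26-connected components over
(t, y, x), and each component is one candidate puff.  The component's
brightest voxel seeds a 2D Gaussian fit on the *unblurred* measurement stack
at the peak frame, giving a sub-pixel centroid; an F/F0 trace is then read
from a small square ROI centred on that centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit

from .preprocess import RatioStack

__all__ = ["PuffEvent", "detect_events", "fit_centroid", "extract_trace"]


@dataclass
class PuffEvent:
    """One detected transient and (once measured) its kinetic metrics."""

    id: int
    start_frame: int
    peak_frame: int
    end_frame: int
    peak_y_px: int
    peak_x_px: int
    peak_detection_value: float
    n_voxels: int
    centroid_x_um: float | None = None
    centroid_y_um: float | None = None
    trace: np.ndarray | None = None
    amplitude_dFF0: float | None = None
    rise_ms: float | None = None
    decay_ms: float | None = None
    duration_ms: float | None = None
    baseline_level: float | None = None
    peak_time_s: float | None = None
    is_square: bool = False
    site_id: int | None = None
    flags: list[str] = field(default_factory=list)


def detect_events(detection_stack: np.ndarray, threshold: float = 0.25,
                  min_voxels: int = 4) -> list[PuffEvent]:
    """Segment candidate puffs as connected suprathreshold voxel clusters.

    Voxels strictly brighter than ``threshold`` (in baseline-SD units) are
    binarized and grouped with 26-connectivity over (t, y, x); components
    smaller than ``min_voxels`` are discarded as noise.  Two events at one
    site separated by at least one sub-threshold frame come out distinct.
    Returns events sorted by start frame.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    stack = np.asarray(detection_stack)
    if stack.ndim != 3:
        raise ValueError("detection stack must be T x Y x X")
    mask = stack > threshold
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), bool))
    if n == 0:
        return []
    sizes = np.bincount(labels.ravel())[1:]
    keep = np.flatnonzero(sizes >= min_voxels) + 1
    if keep.size == 0:
        return []
    peaks = ndimage.maximum_position(stack, labels, index=keep)
    objects = ndimage.find_objects(labels)
    events = []
    for lab, (pt, py, px) in zip(keep, peaks):
        tsl = objects[lab - 1][0]
        events.append(PuffEvent(
            id=-1,
            start_frame=int(tsl.start),
            peak_frame=int(pt),
            end_frame=int(tsl.stop - 1),
            peak_y_px=int(py),
            peak_x_px=int(px),
            peak_detection_value=float(stack[pt, py, px]),
            n_voxels=int(sizes[lab - 1]),
        ))
    events.sort(key=lambda e: (e.start_frame, e.peak_frame, e.peak_y_px, e.peak_x_px))
    for i, ev in enumerate(events):
        ev.id = i
    return events


def _gauss2d(coords, amp, x0, y0, sigma, offset):
    x, y = coords
    return offset + amp * np.exp(-((x - x0) ** 2 + (y - y0) ** 2) / (2 * sigma ** 2))


def fit_centroid(measurement_stack, event: PuffEvent, pixel_size_um: float | None = None,
                 patch_px: int = 9) -> tuple[float, float] | None:
    """Sub-pixel centroid of an event from an isotropic 2D Gaussian fit.

    A ``patch_px`` x ``patch_px`` window around the seed voxel at the peak
    frame is fitted with a Gaussian plus constant offset by least squares.
    On non-convergence, or a fitted centre outside the patch, falls back to
    the intensity-weighted centre of mass (flagged).  An event whose usable
    patch is clipped below 3 x 3 pixels is flagged unlocalizable and returns
    None.  Sets ``centroid_x_um``/``centroid_y_um`` on the event and returns
    them (in um).
    """
    if isinstance(measurement_stack, RatioStack):
        data = measurement_stack.data
        if pixel_size_um is None:
            pixel_size_um = measurement_stack.pixel_size_um
    else:
        data = np.asarray(measurement_stack)
        if pixel_size_um is None:
            raise ValueError("pixel_size_um required with a bare array")
    half = patch_px // 2
    frame = data[event.peak_frame]
    y0 = max(0, event.peak_y_px - half)
    y1 = min(frame.shape[0], event.peak_y_px + half + 1)
    x0 = max(0, event.peak_x_px - half)
    x1 = min(frame.shape[1], event.peak_x_px + half + 1)
    patch = frame[y0:y1, x0:x1].astype(float)
    if patch.shape[0] < 3 or patch.shape[1] < 3:
        event.flags.append("unlocalizable")
        return None
    yy, xx = np.mgrid[y0:y1, x0:x1].astype(float)
    offset0 = patch.min()
    amp0 = patch.max() - offset0
    p0 = (max(amp0, 1e-12), float(event.peak_x_px), float(event.peak_y_px), 1.5, offset0)
    cx = cy = None
    try:
        popt, _ = curve_fit(_gauss2d, (xx.ravel(), yy.ravel()), patch.ravel(),
                            p0=p0, maxfev=2000)
        if popt[0] > 0 and x0 - 0.5 <= popt[1] <= x1 - 0.5 and y0 - 0.5 <= popt[2] <= y1 - 0.5:
            cx, cy = float(popt[1]), float(popt[2])
    except RuntimeError:
        pass
    if cx is None:
        w = patch - patch.min()
        tot = w.sum()
        if tot <= 0:
            event.flags.append("unlocalizable")
            return None
        cx = float((w * xx).sum() / tot)
        cy = float((w * yy).sum() / tot)
        event.flags.append("centroid_com_fallback")
    event.centroid_x_um = cx * pixel_size_um
    event.centroid_y_um = cy * pixel_size_um
    return event.centroid_x_um, event.centroid_y_um


def extract_trace(ratio_stack, centroid_x_um: float, centroid_y_um: float,
                  roi_side_um: float = 1.76, pixel_size_um: float | None = None,
                  flags: list[str] | None = None) -> np.ndarray:
    """Mean F/F0 trace from a square ROI centred on the event centroid.

    The ROI side is converted to the nearest odd pixel count (1.76 um at
    0.16 um/px gives 11 px) so the centroid pixel sits centrally.  The ROI is
    clipped at field edges (flagged via ``flags`` if supplied); the returned
    trace spans the full stack.
    """
    if isinstance(ratio_stack, RatioStack):
        data = ratio_stack.data
        if pixel_size_um is None:
            pixel_size_um = ratio_stack.pixel_size_um
    else:
        data = np.asarray(ratio_stack)
        if pixel_size_um is None:
            raise ValueError("pixel_size_um required with a bare array")
    n = int(round(roi_side_um / pixel_size_um))
    if n % 2 == 0:
        n += 1 if (roi_side_um / pixel_size_um) >= n else -1
    n = max(n, 1)
    cx = int(round(centroid_x_um / pixel_size_um))
    cy = int(round(centroid_y_um / pixel_size_um))
    T, H, W = data.shape
    if not (0 <= cx < W and 0 <= cy < H):
        raise ValueError("centroid outside the field")
    half = n // 2
    y0, y1 = max(0, cy - half), min(H, cy + half + 1)
    x0, x1 = max(0, cx - half), min(W, cx + half + 1)
    if flags is not None and ((y1 - y0) < n or (x1 - x0) < n):
        flags.append("roi_clipped")
    return data[:, y0:y1, x0:x1].mean(axis=(1, 2))
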