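"""Movie preprocessing: background correction, flash removal, F/F0 and detection stacks.

The analysis keeps two parallel representations of a movie:

* the *measurement* stack — the raw F/F0 ratio, unsmoothed, on which traces
  and kinetics are read out so amplitudes stay on the dF/F0 scale;
* the *detection* stack — the ratio expressed in units of each pixel's
  baseline standard deviation and then Gaussian-blurred, on which events are
  segmented.

Blurring and SD scaling improve detection SNR but distort amplitudes, hence
the two-stack discipline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter
from skimage.restoration import rolling_ball

__all__ = [
    "MovieStack",
    "RatioStack",
    "subtract_background",
    "rolling_ball_subtract",
    "remove_flash_frames",
    "compute_ratio_stack",
    "make_detection_stack",
    "butterworth_detrend",
]


@dataclass
class MovieStack:
    """A T x Y x X fluorescence stack with acquisition bookkeeping.

    ``flash_frame`` indexes the first photolysis-flash frame in *original*
    acquisition coordinates.  ``removed_frames`` lists original indices that
    have been dropped (flash artifact); ``orig_index`` maps each current
    frame back to its original index so times can always be reported in
    acquisition time.
    """

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    flash_frame: int | None = None
    removed_frames: list[int] = field(default_factory=list)
    orig_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("data must be a T x Y x X stack")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel_size_um and frame_interval_s must be > 0")
        if self.orig_index is None:
            self.orig_index = np.arange(self.data.shape[0])

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def frame_time_s(self, i) -> float | np.ndarray:
        """Acquisition time of current frame ``i`` (accounts for removed frames)."""
        return self.orig_index[i] * self.frame_interval_s


@dataclass
class RatioStack:
    """F/F0 stack with its per-pixel baseline statistics and movie metadata."""

    data: np.ndarray
    baseline_frames: int
    f0: np.ndarray
    baseline_sd: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    flash_frame: int | None = None
    orig_index: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def frame_time_s(self, i) -> float | np.ndarray:
        idx = self.orig_index if self.orig_index is not None else np.arange(self.n_frames)
        return idx[i] * self.frame_interval_s


def _as_array(stack):
    return stack.data if isinstance(stack, MovieStack) else np.asarray(stack)


def subtract_background(stack, background, per_frame: bool = True):
    """Subtract a background level, floored at zero.

    ``background`` may be a scalar (applied everywhere) or a ``(yslice, xslice)``
    pair selecting a cell-free region whose mean intensity is subtracted —
    per frame by default, which is robust to slow illumination drift.
    Returns the same type as the input.
    """
    data = _as_array(stack).astype(float)
    if np.isscalar(background):
        if background < 0:
            raise ValueError("scalar background must be >= 0")
        out = data - float(background)
    else:
        ys, xs = background
        region = data[:, ys, xs]
        if region.size == 0:
            raise ValueError("background region is empty")
        if per_frame:
            bg = region.reshape(region.shape[0], -1).mean(axis=1)
            out = data - bg[:, None, None]
        else:
            out = data - region.mean()
    out = np.clip(out, 0.0, None)
    if isinstance(stack, MovieStack):
        return MovieStack(out, stack.pixel_size_um, stack.frame_interval_s,
                          stack.flash_frame, list(stack.removed_frames),
                          stack.orig_index.copy())
    return out


def rolling_ball_subtract(image: np.ndarray, radius_px: int = 50) -> np.ndarray:
    """Rolling-ball background subtraction of a single 2D image.

    The background is the surface traced by a ball of the given radius rolled
    under the intensity landscape; sharp peaks narrower than the ball are
    preserved.  Output is floored at zero.
    """
    image = np.asarray(image, float)
    if image.ndim != 2:
        raise ValueError("rolling_ball_subtract expects a single 2D image")
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    if radius_px > max(image.shape):
        raise ValueError("radius_px larger than the image")
    bg = rolling_ball(image, radius=radius_px)
    return np.clip(image - bg, 0.0, None)


def remove_flash_frames(stack: MovieStack, flash_frame: int | None = None,
                        n_frames: int = 2) -> MovieStack:
    """Drop the frames containing the photolysis-flash artifact.

    The removed original indices are recorded so downstream event times are
    still reported in acquisition time.
    """
    if flash_frame is None:
        flash_frame = stack.flash_frame
    if flash_frame is None:
        raise ValueError("flash_frame not set on the stack and not supplied")
    if n_frames < 0 or flash_frame < 0 or flash_frame + n_frames > stack.n_frames:
        raise ValueError("flash window out of range")
    if n_frames == 0:
        return stack
    keep = np.ones(stack.n_frames, bool)
    keep[flash_frame:flash_frame + n_frames] = False
    removed = list(stack.orig_index[flash_frame:flash_frame + n_frames])
    return MovieStack(stack.data[keep], stack.pixel_size_um, stack.frame_interval_s,
                      stack.flash_frame,
                      list(stack.removed_frames) + [int(r) for r in removed],
                      stack.orig_index[keep].copy())


def compute_ratio_stack(stack: MovieStack, baseline_frames: int = 390) -> RatioStack:
    """Divide each pixel by its mean over the pre-flash baseline frames.

    The per-pixel baseline standard deviation of the *ratio* is stored for
    the SD normalization of the detection stack.  If fewer pre-flash frames
    than requested exist, all of them are used (with a warning).
    """
    n_pre = stack.n_frames
    if stack.flash_frame is not None:
        n_pre = int(np.searchsorted(stack.orig_index, stack.flash_frame))
    if baseline_frames > n_pre:
        warnings.warn(f"only {n_pre} pre-flash frames available; "
                      f"using them all as baseline", stacklevel=2)
        baseline_frames = n_pre
    if baseline_frames < 2:
        raise ValueError("need at least 2 baseline frames")
    base = stack.data[:baseline_frames].astype(float)
    f0 = base.mean(axis=0)
    bad = np.argwhere(f0 <= 0)
    if bad.size:
        y, x = bad[0]
        raise ValueError(f"non-positive baseline F0 at pixel (y={y}, x={x}); "
                         f"check background subtraction")
    ratio = stack.data / f0[None]
    sd = ratio[:baseline_frames].std(axis=0, ddof=1)
    return RatioStack(ratio, baseline_frames, f0, sd, stack.pixel_size_um,
                      stack.frame_interval_s, stack.flash_frame,
                      stack.orig_index.copy())


def make_detection_stack(ratio: RatioStack, blur_sigma_px: float = 2.0) -> np.ndarray:
    """Detection stack: baseline-subtracted ratio in baseline-SD units, blurred.

    Each pixel's dF/F0 (ratio minus its own baseline mean, which is 1 by
    construction) is divided by that pixel's baseline SD, then a spatial
    Gaussian blur is applied frame by frame.  The result has a zero baseline
    and is thresholded directly by the event detector.  Pixels with zero
    baseline SD (noiseless synthetic data) fall back to the field median SD.
    """
    sd = ratio.baseline_sd.astype(float).copy()
    zero = sd <= 0
    if zero.all():
        raise ValueError("baseline SD is zero everywhere; nothing to normalize by")
    if zero.any():
        sd[zero] = np.median(sd[~zero])
    base_mean = ratio.data[:ratio.baseline_frames].mean(axis=0)
    norm = (ratio.data - base_mean[None]) / sd[None]
    if blur_sigma_px > 0:
        norm = gaussian_filter(norm, sigma=(0.0, blur_sigma_px, blur_sigma_px))
    return norm


def butterworth_detrend(data: np.ndarray, low_cutoff: float = 0.01,
                        axis: int = 0, baseline_frames: int | None = None,
                        order: int = 2) -> np.ndarray:
    """Remove slow baseline drift with a zero-phase Butterworth high-pass filter.

    ``low_cutoff`` is a fraction of the Nyquist frequency.  Filtering is
    forward-backward (zero phase); the mean over ``baseline_frames`` initial
    samples (or the whole record) is added back so an F/F0 trace keeps its
    baseline near 1.
    """
    if not 0 < low_cutoff < 1:
        raise ValueError("low_cutoff must lie in (0, 1) as a fraction of Nyquist")
    data = np.asarray(data, float)
    sos = signal.butter(order, low_cutoff, btype="highpass", output="sos")
    filtered = signal.sosfiltfilt(sos, data, axis=axis)
    sl = [slice(None)] * data.ndim
    if baseline_frames is not None:
        sl[axis] = slice(0, baseline_frames)
    offset = data[tuple(sl)].mean(axis=axis, keepdims=True)
    return filtered + offset
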