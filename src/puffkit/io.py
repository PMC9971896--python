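"""TIFF and table I/O."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .preprocess import MovieStack

__all__ = ["write_movie_tiff", "read_movie_tiff", "read_image_tiff",
           "events_to_dataframe", "sites_to_dataframe"]


def write_movie_tiff(stack: MovieStack, path: str | Path) -> None:
    """Write a movie as 16-bit multi-page TIFF with ImageJ-style metadata."""
    data = np.clip(np.rint(stack.data), 0, 65535).astype(np.uint16)
    res = 1.0 / stack.pixel_size_um
    meta = {"finterval": stack.frame_interval_s, "unit": "um", "axes": "TYX"}
    if stack.flash_frame is not None:
        meta["flash_frame"] = stack.flash_frame
    tifffile.imwrite(str(path), data, imagej=True, resolution=(res, res),
                     metadata=meta)


def read_movie_tiff(path: str | Path, pixel_size_um: float | None = None,
                    frame_interval_s: float | None = None,
                    flash_frame: int | None = None) -> MovieStack:
    """Read a multi-page TIFF as a MovieStack, recovering metadata when present.

    Explicit arguments win over metadata in the file; missing values raise.
    """
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray().astype(float)
        ij = tf.imagej_metadata or {}
        if frame_interval_s is None:
            frame_interval_s = ij.get("finterval")
        if flash_frame is None:
            flash_frame = ij.get("flash_frame")
        if pixel_size_um is None:
            page = tf.pages[0]
            xres = page.tags.get("XResolution")
            if xres is not None:
                num, den = xres.value
                if num:
                    pixel_size_um = den / num
    if data.ndim == 2:
        data = data[None]
    if pixel_size_um is None or frame_interval_s is None:
        raise ValueError("pixel_size_um and frame_interval_s must be supplied "
                         "or present in the TIFF metadata")
    return MovieStack(data, float(pixel_size_um), float(frame_interval_s),
                      None if flash_frame is None else int(flash_frame))


def read_image_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(float)


def events_to_dataframe(events) -> pd.DataFrame:
    """One row per detected event: frames, coordinates, metrics, flags."""
    cols = ["id", "start_frame", "peak_frame", "end_frame", "peak_time_s",
            "centroid_x_um", "centroid_y_um", "peak_detection_value", "n_voxels",
            "baseline_level", "amplitude_dFF0", "rise_ms", "decay_ms",
            "duration_ms", "is_square", "site_id", "flags"]
    rows = [{c: (";".join(ev.flags) if c == "flags" else getattr(ev, c))
             for c in cols} for ev in events]
    return pd.DataFrame(rows, columns=cols)


def sites_to_dataframe(sites) -> pd.DataFrame:
    return pd.DataFrame(
        [{"site_id": s.site_id, "centroid_x_um": s.centroid_x_um,
          "centroid_y_um": s.centroid_y_um, "n_events": s.n_events,
          "member_event_ids": ";".join(map(str, s.member_event_ids))}
         for s in sites],
        columns=["site_id", "centroid_x_um", "centroid_y_um", "n_events",
                 "member_event_ids"])
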