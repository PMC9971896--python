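"""End-to-end puff analysis: preprocess, detect, measure, cluster, summarize.

`analyze_movie` chains the full workflow on a MovieStack and returns a
PuffAnalysis holding the events, both site partitions, the per-cell summary
and (when ground truth is supplied) a recovery report with recall,
precision, localization error, amplitude bias and site-count comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import detection, kinetics, preprocess, sites as sites_mod
from .config import merge_config
from .preprocess import MovieStack
from .synthetic import GroundTruth

__all__ = ["PuffAnalysis", "analyze_movie", "recovery_report", "roi_attenuation"]


@dataclass
class PuffAnalysis:
    events: list = field(default_factory=list)
    sites_centroid_update: list = field(default_factory=list)
    sites_chain: list = field(default_factory=list)
    summary: kinetics.CellSummary | None = None
    recovery: dict | None = None
    config: dict = field(default_factory=dict)
    ratio: preprocess.RatioStack | None = None


def analyze_movie(stack: MovieStack, config: dict | None = None,
                  ground_truth: GroundTruth | None = None,
                  keep_ratio: bool = False) -> PuffAnalysis:
    """Run the whole puff pipeline on a movie.

    Steps: flash-frame removal, F/F0 normalization over the pre-flash
    baseline, optional Butterworth detrending, SD-normalized blurred
    detection stack, threshold-cluster detection, sub-pixel centroiding and
    trace extraction on the unblurred ratio stack, kinetic metrics with
    square-event flagging, site clustering (both variants) and the per-cell
    summary.
    """
    cfg = merge_config(config)
    pp, det_cfg, kin_cfg, site_cfg = (cfg["preprocess"], cfg["detection"],
                                      cfg["kinetics"], cfg["sites"])

    if pp["background"]:
        stack = preprocess.subtract_background(stack, pp["background"])
    if stack.flash_frame is not None and pp["flash_artifact_frames"] > 0 \
            and not stack.removed_frames:
        stack = preprocess.remove_flash_frames(stack, n_frames=pp["flash_artifact_frames"])

    ratio = preprocess.compute_ratio_stack(stack, pp["baseline_frames"])
    if pp["detrend"]:
        ratio.data = preprocess.butterworth_detrend(
            ratio.data, pp["butterworth_cutoff"],
            baseline_frames=ratio.baseline_frames, order=pp["butterworth_order"])

    det_stack = preprocess.make_detection_stack(ratio, pp["blur_sigma_px"])
    events = detection.detect_events(det_stack, det_cfg["threshold"],
                                     det_cfg["min_voxels"])

    flash_idx = 0
    if ratio.flash_frame is not None:
        flash_idx = int(np.searchsorted(ratio.orig_index, ratio.flash_frame))

    kept = []
    for ev in events:
        if detection.fit_centroid(ratio, ev, patch_px=det_cfg["patch_px"]) is None:
            continue
        ev.trace = detection.extract_trace(ratio, ev.centroid_x_um, ev.centroid_y_um,
                                           det_cfg["roi_side_um"], flags=ev.flags)
        m = kinetics.measure_kinetics(ev.trace, (ev.start_frame, ev.end_frame),
                                      ratio.frame_interval_s,
                                      kin_cfg["baseline_window_frames"],
                                      min_frame=flash_idx)
        ev.amplitude_dFF0 = m.amplitude_dFF0
        ev.rise_ms, ev.decay_ms, ev.duration_ms = m.rise_ms, m.decay_ms, m.duration_ms
        ev.baseline_level = m.baseline_level
        ev.flags.extend(m.flags)
        ev.is_square = kinetics.flag_square(ev.trace, m, ratio.frame_interval_s,
                                            (ev.start_frame, ev.end_frame),
                                            kin_cfg["plateau_frac"],
                                            kin_cfg["plateau_min_ms"])
        ref = m.peak_index if kin_cfg["latency_reference"] == "peak" else ev.start_frame
        ev.peak_time_s = float(ratio.frame_time_s(ref))
        kept.append(ev)
    events = kept
    for i, ev in enumerate(events):
        ev.id = i

    pts = np.array([[e.centroid_x_um, e.centroid_y_um] for e in events]).reshape(-1, 2)
    ids = [e.id for e in events]
    s_cu = sites_mod.cluster_sites_centroid_update(pts, site_cfg["radius_um"], ids)
    s_ch = sites_mod.cluster_sites_chain(pts, site_cfg["radius_um"], ids)
    chosen = s_cu if site_cfg["method"] == "centroid_update" else s_ch
    by_event = {eid: s.site_id for s in chosen for eid in s.member_event_ids}
    for ev in events:
        ev.site_id = by_event.get(ev.id)

    flash_t = (ratio.flash_frame or 0) * ratio.frame_interval_s
    end_t = float(ratio.frame_time_s(ratio.n_frames - 1))
    obscured = kinetics.estimate_obscured_time(ratio, kin_cfg["obscured_level"])
    summary = kinetics.summarize_cell(events, flash_t, end_t, obscured)

    recovery = None
    if ground_truth is not None:
        recovery = recovery_report(events, ground_truth, ratio,
                                   n_sites_cu=len(s_cu), n_sites_chain=len(s_ch),
                                   roi_side_um=det_cfg["roi_side_um"])
    return PuffAnalysis(events, s_cu, s_ch, summary, recovery, cfg,
                        ratio if keep_ratio else None)


def roi_attenuation(site_x_um: float, site_y_um: float, pixel_size_um: float,
                    spatial_sigma_um: float, roi_side_um: float = 1.76) -> float:
    """Fraction of an event's peak dF/F0 surviving the square ROI average.

    The measured trace averages the Gaussian spatial profile over an n x n
    pixel ROI centred on the event, so the measured amplitude is the true
    amplitude times this factor.
    """
    n = int(round(roi_side_um / pixel_size_um))
    if n % 2 == 0:
        n += 1
    cx = round(site_x_um / pixel_size_um)
    cy = round(site_y_um / pixel_size_um)
    half = n // 2
    xs = np.arange(cx - half, cx + half + 1, dtype=float)
    ys = np.arange(cy - half, cy + half + 1, dtype=float)
    sig_px = spatial_sigma_um / pixel_size_um
    gx = np.exp(-(xs - site_x_um / pixel_size_um) ** 2 / (2 * sig_px ** 2))
    gy = np.exp(-(ys - site_y_um / pixel_size_um) ** 2 / (2 * sig_px ** 2))
    return float(np.outer(gy, gx).mean())


def recovery_report(events, truth: GroundTruth, ratio, n_sites_cu: int,
                    n_sites_chain: int, match_frames: int = 3,
                    match_px: float = 3.0, roi_side_um: float = 1.76) -> dict:
    """Match detections to ground-truth events and score the recovery.

    A detection matches a truth event when their peak frames (in original
    acquisition coordinates) differ by at most ``match_frames`` and their
    positions by at most ``match_px`` pixels; matching is greedy by distance,
    one-to-one.  Amplitude bias compares the measured trace amplitude to the
    ROI-attenuated true amplitude.
    """
    px = ratio.pixel_size_um
    site_pos = {s["id"]: (s["x_um"], s["y_um"]) for s in truth.sites}
    sigma_um = truth.config.get("spatial_sigma_um", 0.4)

    cand = []
    for di, ev in enumerate(events):
        ev_frame = int(ratio.orig_index[ev.peak_frame])
        for ti, tr in enumerate(truth.events):
            if abs(ev_frame - tr["peak_frame"]) > match_frames:
                continue
            tx, ty = site_pos[tr["site_id"]]
            d = math.hypot(ev.centroid_x_um - tx, ev.centroid_y_um - ty) / px
            if d <= match_px:
                cand.append((d, di, ti))
    cand.sort()
    used_d, used_t, pairs = set(), set(), []
    for d, di, ti in cand:
        if di in used_d or ti in used_t:
            continue
        used_d.add(di)
        used_t.add(ti)
        pairs.append((d, di, ti))

    n_truth, n_det = len(truth.events), len(events)
    recall = len(pairs) / n_truth if n_truth else math.nan
    precision = len(pairs) / n_det if n_det else math.nan
    cent_err = [d for d, _, _ in pairs]
    amp_bias = []
    for _, di, ti in pairs:
        tr = truth.events[ti]
        tx, ty = site_pos[tr["site_id"]]
        expected = tr["amplitude_dFF0"] * roi_attenuation(tx, ty, px, sigma_um,
                                                          roi_side_um)
        meas = events[di].amplitude_dFF0
        if meas is not None and expected > 0:
            amp_bias.append((meas - expected) / expected)
    return {
        "n_truth_events": n_truth,
        "n_detected_events": n_det,
        "n_matched": len(pairs),
        "recall": recall,
        "precision": precision,
        "centroid_error_px_mean": float(np.mean(cent_err)) if cent_err else math.nan,
        "centroid_error_px_max": float(np.max(cent_err)) if cent_err else math.nan,
        "amplitude_rel_bias_mean": float(np.mean(amp_bias)) if amp_bias else math.nan,
        "n_true_sites": len(truth.sites),
        "n_sites_centroid_update": n_sites_cu,
        "n_sites_chain": n_sites_chain,
    }
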