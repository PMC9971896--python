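"""Seeded synthetic TIRF movies and two-channel puncta images with ground truth.

The movie generator emulates the acquisition geometry of high-speed puff
recordings: a small region of interest (default 19.2 x 19.2 um at
0.16 um/px) streamed at 200 frames/s, with a photolysis flash after 2 s of
baseline recording.  Immobile release sites emit transient fluorescence
events (linear rise, optional plateau, exponential decay) as a Poisson
process starting at the flash; events are multiplicative on the baseline so
ground-truth amplitudes are directly on the dF/F0 scale measured downstream.

Simplifications relative to real data (additive Gaussian noise, no
photobleaching, no camera gain model) are deliberate: the generator exists
to verify the analysis chain against known truth, not to model photophysics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .preprocess import MovieStack

__all__ = [
    "SimMovieConfig",
    "SimPunctaConfig",
    "GroundTruth",
    "PunctaGroundTruth",
    "simulate_puff_trace",
    "simulate_movie",
    "simulate_puncta_pair",
]


@dataclass
class SimMovieConfig:
    """Parameters of a synthetic puff movie.

    Spatial positions are in um with pixel centers at integer pixel
    coordinates times ``pixel_size_um``.  ``plateau_ms`` applies only to
    events drawn as 'square' (sustained plateau at peak); ordinary puffs
    have no plateau.
    """

    field_size_px: int = 120
    pixel_size_um: float = 0.16
    frame_interval_s: float = 0.005
    n_frames: int = 6000
    flash_frame: int = 400
    flash_artifact_frames: int = 2
    baseline_level: float = 1000.0
    noise_sd: float = 20.0
    site_positions_um: list[tuple[float, float]] | None = None
    n_sites: int = 10
    min_separation_um: float = 2.5
    event_rate_per_site_hz: float = 0.2
    min_event_separation_s: float = 0.5
    amplitude_mean_dFF0: float = 1.0
    amplitude_cv: float = 0.3
    rise_ms: float = 25.0
    decay_tau_ms: float = 40.0
    plateau_ms: float = 100.0
    square_fraction: float = 0.0
    spatial_sigma_um: float = 0.4
    global_rise_per_s: float = 0.0
    edge_margin_um: float = 1.5
    sensor_max: float = 65535.0
    seed: int = 0

    def validate(self) -> None:
        if self.field_size_px < 1:
            raise ValueError("field_size_px must be >= 1")
        for name in ("pixel_size_um", "frame_interval_s", "baseline_level",
                     "rise_ms", "decay_tau_ms", "spatial_sigma_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.plateau_ms < 0 or self.noise_sd < 0:
            raise ValueError("plateau_ms and noise_sd must be >= 0")
        if not (0 <= self.flash_frame < self.n_frames):
            raise ValueError("flash_frame must lie inside the stack")
        if not (0.0 <= self.square_fraction <= 1.0):
            raise ValueError("square_fraction must be in [0, 1]")
        if self.event_rate_per_site_hz < 0:
            raise ValueError("event_rate_per_site_hz must be >= 0")


@dataclass
class SimPunctaConfig:
    """Parameters of a synthetic two-channel punctate image pair."""

    field_size_px: int = 120
    pixel_size_um: float = 0.16
    n_spots: int = 50
    colocalized_fraction: float = 1.0
    intensity_correlation: float = 1.0
    spot_sigma_um: float = 0.2
    intensity_range: tuple[float, float] = (100.0, 500.0)
    min_separation_um: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.colocalized_fraction <= 1.0):
            raise ValueError("colocalized_fraction must be in [0, 1]")
        if not (-1.0 <= self.intensity_correlation <= 1.0):
            raise ValueError("intensity_correlation must be in [-1, 1]")
        if self.pixel_size_um <= 0 or self.spot_sigma_um <= 0:
            raise ValueError("pixel sizes and spot sigma must be > 0")
        if self.n_spots < 0 or self.noise_sd < 0:
            raise ValueError("n_spots and noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Record of the true sites, events and settings behind a synthetic movie.

    ``events`` entries hold: site_id, start_frame, peak_frame,
    amplitude_dFF0, rise_ms, decay_tau_ms, plateau_ms, is_square.
    """

    sites: list[dict] = field(default_factory=list)
    events: list[dict] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(sites=d["sites"], events=d["events"], config=d.get("config", {}))


@dataclass
class PunctaGroundTruth:
    """True spot positions, channel membership and intensities for an image pair."""

    spots: list[dict] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def simulate_puff_trace(amplitude_dFF0: float, rise_ms: float, decay_tau_ms: float,
                        plateau_ms: float, frame_interval_s: float,
                        n_frames: int) -> np.ndarray:
    """Single-event dF/F0 time course: linear rise, optional plateau, exponential decay.

    The trace starts at 0, reaches ``amplitude_dFF0`` at t = rise_ms, holds it
    for ``plateau_ms``, then decays exponentially with time constant
    ``decay_tau_ms``.  Sampled at the frame interval starting at t = 0.
    """
    if rise_ms <= 0 or decay_tau_ms <= 0 or frame_interval_s <= 0:
        raise ValueError("rise_ms, decay_tau_ms and frame_interval_s must be > 0")
    if plateau_ms < 0:
        raise ValueError("plateau_ms must be >= 0")
    if amplitude_dFF0 < 0:
        raise ValueError("amplitude_dFF0 must be >= 0")
    t_ms = np.arange(n_frames) * frame_interval_s * 1e3
    out = np.zeros(n_frames)
    rising = t_ms <= rise_ms
    out[rising] = amplitude_dFF0 * t_ms[rising] / rise_ms
    flat = (t_ms > rise_ms) & (t_ms <= rise_ms + plateau_ms)
    out[flat] = amplitude_dFF0
    falling = t_ms > rise_ms + plateau_ms
    out[falling] = amplitude_dFF0 * np.exp(-(t_ms[falling] - rise_ms - plateau_ms)
                                           / decay_tau_ms)
    return out


def _draw_positions(rng: np.random.Generator, n: int, field_um: float,
                    min_sep_um: float, margin_um: float,
                    max_tries: int = 5000) -> np.ndarray:
    """Dart-throwing placement with a minimum pairwise separation."""
    lo = min(margin_um, field_um / 2)
    hi = field_um - lo
    if hi <= lo:
        raise ValueError("field too small for the requested edge margin")
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < n:
        cand = rng.uniform(lo, hi, size=2)
        if all(np.hypot(*(cand - p)) >= min_sep_um for p in pts):
            pts.append(cand)
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"could not place {n} points with separation {min_sep_um} um "
                f"in a {field_um:.1f} um field")
    return np.array(pts)


def _draw_amplitudes(rng: np.random.Generator, n: int, mean: float, cv: float) -> np.ndarray:
    if cv <= 0:
        return np.full(n, mean)
    s2 = math.log1p(cv * cv)
    mu = math.log(mean) - s2 / 2
    return rng.lognormal(mu, math.sqrt(s2), size=n)


def simulate_movie(config: SimMovieConfig) -> tuple[MovieStack, GroundTruth]:
    """Render a synthetic puff movie and its ground truth.

    Signal model per pixel: ``F = baseline * G(t) * (1 + sum_i a_i s_i(t) PSF_i)``
    plus optional Gaussian noise, where ``G(t)`` is an optional global ramp
    starting at the flash and ``PSF_i`` is an isotropic Gaussian of width
    ``spatial_sigma_um`` centred on the emitting site.  Flash-artifact frames
    are saturated at ``sensor_max``.

    Ground-truth events are restricted to those whose above-20% window
    (rise + plateau + tau*ln5) lies inside the stack, so every listed event
    is fully measurable.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    npx = config.field_size_px
    field_um = npx * config.pixel_size_um
    dt = config.frame_interval_s
    dt_ms = dt * 1e3

    if config.site_positions_um is not None:
        sites_um = np.asarray(config.site_positions_um, float)
        if len(sites_um) > 1:
            from scipy.spatial.distance import pdist
            if pdist(sites_um).min() < config.min_separation_um - 1e-9:
                raise ValueError("site_positions_um violate min_separation_um")
    else:
        sites_um = _draw_positions(rng, config.n_sites, field_um,
                                   config.min_separation_um, config.edge_margin_um)

    flash_t = config.flash_frame * dt
    t_end = config.n_frames * dt
    sigma_px = config.spatial_sigma_um / config.pixel_size_um

    truth = GroundTruth(config=asdict(config))
    truth.config["site_positions_um"] = [list(map(float, p)) for p in sites_um]
    for i, (x, y) in enumerate(sites_um):
        truth.sites.append({"id": i, "x_um": float(x), "y_um": float(y)})

    # Poisson arrivals per site from the flash onward
    events: list[dict] = []
    rate = config.event_rate_per_site_hz
    for i in range(len(sites_um)):
        if rate <= 0:
            break
        t = flash_t
        last_accepted = -math.inf
        while True:
            t += rng.exponential(1.0 / rate)
            if t >= t_end:
                break
            # dead time after each accepted event: overlapping same-site
            # transients merge into one suprathreshold cluster and are not
            # separable by threshold segmentation
            if t - last_accepted < config.min_event_separation_s:
                continue
            is_square = bool(rng.random() < config.square_fraction)
            plateau = config.plateau_ms if is_square else 0.0
            amp = float(_draw_amplitudes(rng, 1, config.amplitude_mean_dFF0,
                                         config.amplitude_cv)[0])
            start = int(round(t / dt))
            window_ms = config.rise_ms + plateau + config.decay_tau_ms * math.log(5.0)
            if start * dt_ms + window_ms >= config.n_frames * dt_ms:
                continue
            if start <= config.flash_frame + config.flash_artifact_frames:
                continue
            last_accepted = t
            events.append({
                "site_id": i,
                "start_frame": start,
                "peak_frame": start + int(round(config.rise_ms / dt_ms)),
                "amplitude_dFF0": amp,
                "rise_ms": config.rise_ms,
                "decay_tau_ms": config.decay_tau_ms,
                "plateau_ms": plateau,
                "is_square": is_square,
            })
    events.sort(key=lambda e: e["start_frame"])
    truth.events = events

    # render the fractional signal S(t, y, x)
    yy, xx = np.mgrid[0:npx, 0:npx].astype(float)
    psfs = []
    for (x, y) in sites_um:
        xp, yp = x / config.pixel_size_um, y / config.pixel_size_um
        psfs.append(np.exp(-((xx - xp) ** 2 + (yy - yp) ** 2) / (2 * sigma_px ** 2)))
    S = np.zeros((config.n_frames, npx, npx))
    for ev in events:
        start = ev["start_frame"]
        # 28 decay constants leaves a relative tail below 1e-12
        n_ev = min(config.n_frames - start,
                   int(math.ceil((ev["rise_ms"] + ev["plateau_ms"]
                                  + 28 * ev["decay_tau_ms"]) / dt_ms)) + 1)
        tr = simulate_puff_trace(ev["amplitude_dFF0"], ev["rise_ms"],
                                 ev["decay_tau_ms"], ev["plateau_ms"], dt, n_ev)
        S[start:start + n_ev] += tr[:, None, None] * psfs[ev["site_id"]][None]

    g = np.ones(config.n_frames)
    if config.global_rise_per_s:
        t_s = np.arange(config.n_frames) * dt
        g = 1.0 + config.global_rise_per_s * np.clip(t_s - flash_t, 0.0, None)
    data = config.baseline_level * g[:, None, None] * (1.0 + S)
    if config.noise_sd > 0:
        data = data + rng.normal(0.0, config.noise_sd, size=data.shape)
    a0, a1 = config.flash_frame, config.flash_frame + config.flash_artifact_frames
    data[a0:a1] = config.sensor_max

    stack = MovieStack(data=data, pixel_size_um=config.pixel_size_um,
                       frame_interval_s=dt, flash_frame=config.flash_frame)
    return stack, truth


def simulate_puncta_pair(config: SimPunctaConfig
                         ) -> tuple[np.ndarray, np.ndarray, PunctaGroundTruth]:
    """Render a two-channel punctate image pair with a controlled overlap.

    Each channel carries ``n_spots`` Gaussian spots; ``round(f * n_spots)``
    positions are shared between channels (f = ``colocalized_fraction``), the
    rest are placed independently per channel.  Paired intensities of shared
    spots are drawn from a bivariate normal with the requested Pearson
    correlation; unshared intensities are independent draws from the same
    marginal.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    npx = config.field_size_px
    field_um = npx * config.pixel_size_um
    n_shared = int(round(config.colocalized_fraction * config.n_spots))
    n_only = config.n_spots - n_shared

    # one joint draw keeps all spots (shared + both singles) mutually separated
    all_pos = _draw_positions(rng, n_shared + 2 * n_only, field_um,
                              config.min_separation_um,
                              margin_um=3 * config.spot_sigma_um)
    pos_shared = all_pos[:n_shared]
    pos_a = all_pos[n_shared:n_shared + n_only]
    pos_b = all_pos[n_shared + n_only:]

    lo, hi = config.intensity_range
    mean, sd = (lo + hi) / 2.0, max((hi - lo) / 6.0, 1e-12)
    rho = config.intensity_correlation
    cov = [[sd * sd, rho * sd * sd], [rho * sd * sd, sd * sd]]
    # svd method tolerates the singular covariance at |rho| = 1
    pair_int = rng.multivariate_normal([mean, mean], cov, size=max(n_shared, 1),
                                       method="svd")
    pair_int = np.clip(pair_int, 0.0, None)[:n_shared]
    int_a = np.clip(rng.normal(mean, sd, size=n_only), 0.0, None)
    int_b = np.clip(rng.normal(mean, sd, size=n_only), 0.0, None)

    sigma_px = config.spot_sigma_um / config.pixel_size_um
    yy, xx = np.mgrid[0:npx, 0:npx].astype(float)

    def render(positions: np.ndarray, intensities: np.ndarray) -> np.ndarray:
        img = np.zeros((npx, npx))
        for (x, y), inten in zip(positions, intensities):
            xp, yp = x / config.pixel_size_um, y / config.pixel_size_um
            img += inten * np.exp(-((xx - xp) ** 2 + (yy - yp) ** 2)
                                  / (2 * sigma_px ** 2))
        return img

    img_a = render(np.vstack([pos_shared, pos_a]) if n_only or n_shared else pos_shared,
                   np.concatenate([pair_int[:, 0], int_a]))
    img_b = render(np.vstack([pos_shared, pos_b]) if n_only or n_shared else pos_shared,
                   np.concatenate([pair_int[:, 1], int_b]))
    if config.noise_sd > 0:
        img_a = img_a + rng.normal(0, config.noise_sd, img_a.shape)
        img_b = img_b + rng.normal(0, config.noise_sd, img_b.shape)

    truth = PunctaGroundTruth(config=asdict(config))
    for k, (x, y) in enumerate(pos_shared):
        truth.spots.append({"channel": "both", "x_um": float(x), "y_um": float(y),
                            "intensity_a": float(pair_int[k, 0]),
                            "intensity_b": float(pair_int[k, 1])})
    for k, (x, y) in enumerate(pos_a):
        truth.spots.append({"channel": "A", "x_um": float(x), "y_um": float(y),
                            "intensity_a": float(int_a[k]), "intensity_b": None})
    for k, (x, y) in enumerate(pos_b):
        truth.spots.append({"channel": "B", "x_um": float(x), "y_um": float(y),
                            "intensity_a": None, "intensity_b": float(int_b[k])})
    return img_a, img_b, truth
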