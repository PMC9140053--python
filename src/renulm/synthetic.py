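"""Synthetic renal-flow phantom and frame simulator.

Emulates the study conditions the pipeline is designed for: a 2-D coronal
kidney cross-section with three concentric regions (cortex, outer medulla,
inner medulla), six vascular beds with opposed arterial/venous flow, Poisson
microbubble arrivals advected along vessel centerlines, Gaussian point-spread
blobs with additive noise at 54 Hz, residual respiratory tissue motion, and a
prazosin event that depresses mean arterial pressure (MAP) and bed-specific
flow speeds during scan 2.

Everything downstream (localization, motion correction, tracking, bed
separation, statistics) is tested against the ground truth this module emits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .core import (
    ARTERIAL_BED,
    BED_REGION,
    BEDS,
    DEFAULT_FRAME_RATE,
    REGION_LABELS,
    FrameStack,
    direction_angle_deg,
)

logger = logging.getLogger(__name__)

#: Default per-bed baseline flow speeds (scan 1), mm/s.  Cortical arterial and
#: outer-medulla DVR means follow the study's baseline report; the remaining
#: beds (for which only relative ordering is known: venous/ascending slower
#: than the paired arterial/descending bed) use plausible values.
DEFAULT_BED_SPEEDS = {
    "cortex_art": 1.59,
    "cortex_ven": 1.00,
    "om_dvr": 0.70,
    "om_avr": 0.55,
    "im_dvr": 0.60,
    "im_avr": 0.50,
}

#: Default per-bed speed multipliers for scans 1/2/3.  Scan-2 and scan-3
#: multipliers of the responding beds reproduce the reported scan means
#: (cortex_art 1.59 -> 1.14 -> 1.18 mm/s; om_dvr 0.70 -> 0.66 -> 0.69 mm/s).
#: Cortical veins get a small non-significant dip; inner medulla no response.
DEFAULT_MULTIPLIERS = {
    "cortex_art": (1.0, 1.14 / 1.59, 1.18 / 1.59),
    "cortex_ven": (1.0, 0.95, 0.97),
    "om_dvr": (1.0, 0.66 / 0.70, 0.69 / 0.70),
    "om_avr": (1.0, 0.95, 1.00),
    "im_dvr": (1.0, 1.00, 1.00),
    "im_avr": (1.0, 1.00, 1.00),
}

#: Ventilation rate, breaths/min -> respiratory frequency in Hz.
RESPIRATORY_RATE_HZ = 69.0 / 60.0


# ---------------------------------------------------------------------------
# Phantom geometry
# ---------------------------------------------------------------------------

@dataclass
class PhantomVessel:
    """One straight vessel segment of the phantom.

    ``centerline`` is an (N, 2) polyline of (x, y) points in mm ordered in the
    flow direction; microbubbles enter at the first point.
    """

    centerline: np.ndarray
    radius: float
    bed: str
    base_speed: float
    id: int = 0

    def __post_init__(self) -> None:
        self.centerline = np.atleast_2d(np.asarray(self.centerline, dtype=float))
        if self.radius <= 0:
            raise ValueError("vessel radius must be positive")
        if not 0.0 <= self.base_speed <= 15.0:
            raise ValueError("base_speed must lie in [0, 15] mm/s")
        if self.bed not in BEDS:
            raise ValueError(f"unknown bed {self.bed!r}")
        seg = np.diff(self.centerline, axis=0)
        self._seg_len = np.hypot(seg[:, 0], seg[:, 1])
        self._cum_len = np.concatenate([[0.0], np.cumsum(self._seg_len)])

    @property
    def length(self) -> float:
        """Total centerline arclength, mm."""
        return float(self._cum_len[-1])

    @property
    def flow_direction(self) -> np.ndarray:
        """Unit vector of the mean flow direction along the centerline."""
        d = self.centerline[-1] - self.centerline[0]
        return d / np.hypot(*d)

    @property
    def direction_deg(self) -> float:
        d = self.flow_direction
        return float(direction_angle_deg(d[0], d[1]))

    def point_at(self, s) -> np.ndarray:
        """Position(s) at arclength ``s`` (mm) along the centerline."""
        s = np.clip(np.asarray(s, dtype=float), 0.0, self.length)
        x = np.interp(s, self._cum_len, self.centerline[:, 0])
        y = np.interp(s, self._cum_len, self.centerline[:, 1])
        return np.stack([x, y], axis=-1)


@dataclass
class PhantomConfig:
    """Geometry and flow configuration of the renal phantom.

    The default field of view is 128 x 128 pixels at 0.05 mm pitch
    (6.4 x 6.4 mm).  The three regions are concentric annuli about ``center``
    and each bed's vessels are radial segments inside an angular fan pointing
    toward the transducer; arterial flow in the cortex runs outward (toward
    the renal surface) while the descending vasa recta run inward, with the
    paired venous/ascending bed opposed in every region.
    """

    grid_shape: tuple[int, int] = (128, 128)
    pixel_pitch: float = 0.05
    center: tuple[float, float] = (3.2, 6.0)
    # (inner radius, outer radius) of each region, mm from center
    region_radii: dict = field(default_factory=lambda: {
        "inner_medulla": (0.0, 1.5),
        "outer_medulla": (1.5, 3.0),
        "cortex": (3.0, 4.5),
    })
    # half-width of the angular fan the vessels occupy, deg about "up"
    fan_half_deg: dict = field(default_factory=lambda: {
        "cortex": 40.0, "outer_medulla": 30.0, "inner_medulla": 30.0,
    })
    n_vessels: dict = field(default_factory=lambda: {
        "cortex_art": 6, "cortex_ven": 6,
        "om_dvr": 4, "om_avr": 4,
        "im_dvr": 3, "im_avr": 3,
    })
    bed_speeds: dict = field(default_factory=lambda: dict(DEFAULT_BED_SPEEDS))
    vessel_radius: float = 0.05
    boundary_margin: float = 0.1   # keep centerline ends off region borders, mm
    im_inner_stop: float = 0.7     # inner-medulla vessels stop short of center, mm
    venous_offset: float = 0.45    # lateral offset of the venous twin vessel, mm

    def validate(self) -> None:
        for bed, v in self.bed_speeds.items():
            if not 0.0 <= v <= 15.0:
                raise ValueError(f"bed speed for {bed} outside [0, 15] mm/s")
        intervals = sorted(self.region_radii.values())
        for (a0, a1), (b0, b1) in zip(intervals, intervals[1:]):
            if a1 > b0 + 1e-12:
                raise ValueError("invalid geometry: region radii overlap")
            if a0 >= a1 or b0 >= b1:
                raise ValueError("invalid geometry: empty region interval")


@dataclass
class RenalPhantom:
    """A built phantom: vessels, ground-truth region label map, flow sectors."""

    vessels: list
    label_map: np.ndarray
    config: PhantomConfig

    def vessels_in_bed(self, bed: str) -> list:
        return [v for v in self.vessels if v.bed == bed]

    def mean_bed_direction_deg(self, bed: str) -> float:
        """Circular mean flow direction of a bed's vessels, degrees."""
        angs = np.radians([v.direction_deg for v in self.vessels_in_bed(bed)])
        if angs.size == 0:
            raise ValueError(f"bed {bed} has no vessels")
        return float(np.degrees(np.arctan2(np.mean(np.sin(angs)),
                                           np.mean(np.cos(angs)))) % 360.0)

    def sectors(self, cortex_span: float = 125.0, medulla_span: float = 90.0) -> dict:
        """Ground-truth :class:`~renulm.separation.FlowSector` per region."""
        from .separation import FlowSector
        spans = {"cortex": cortex_span,
                 "outer_medulla": medulla_span,
                 "inner_medulla": medulla_span}
        out = {}
        for region, art_bed in ARTERIAL_BED.items():
            if self.vessels_in_bed(art_bed):
                out[region] = FlowSector(
                    region=region,
                    mean_angle_deg=self.mean_bed_direction_deg(art_bed),
                    span_deg=spans[region],
                )
        return out


def _fan_azimuths(n: int, half_deg: float) -> np.ndarray:
    if n == 0:
        return np.zeros(0)
    if n == 1:
        return np.zeros(1)
    return np.linspace(-half_deg, half_deg, n)


def build_renal_phantom(config: PhantomConfig | None = None) -> RenalPhantom:
    """Build the vessel set and ground-truth region label map.

    Arterial (``cortex_art``) and ascending (``om_avr``/``im_avr``) vessels
    run radially outward, descending vasa recta and cortical veins inward, so
    that the venous/ascending bed of every region opposes its paired
    arterial/descending bed by 180 degrees.  The venous twin of each vessel is
    offset laterally so opposed beds do not overlap in space.
    """
    cfg = config or PhantomConfig()
    cfg.validate()
    cx, cy = cfg.center
    vessels: list[PhantomVessel] = []
    vid = 0

    outward_beds = {"cortex_art", "om_avr", "im_avr"}
    for region, (r_in, r_out) in cfg.region_radii.items():
        r0 = max(r_in + cfg.boundary_margin,
                 cfg.im_inner_stop if region == "inner_medulla" else 0.0)
        r1 = r_out - cfg.boundary_margin
        half = cfg.fan_half_deg[region]
        art_bed = ARTERIAL_BED[region]
        ven_bed = {"cortex": "cortex_ven", "outer_medulla": "om_avr",
                   "inner_medulla": "im_avr"}[region]
        for bed, offset_sign in ((art_bed, 0.0), (ven_bed, 1.0)):
            n = cfg.n_vessels.get(bed, 0)
            # the venous twin is shifted laterally; shorten its outer end so
            # the offset endpoint stays inside the region annulus
            r1_bed = r1
            if offset_sign and cfg.venous_offset < r1:
                r1_bed = np.sqrt(r1 ** 2 - cfg.venous_offset ** 2)
            for alpha in _fan_azimuths(n, half):
                a = np.radians(alpha)
                u = np.array([np.sin(a), -np.cos(a)])       # outward radial
                perp = np.array([np.cos(a), np.sin(a)])
                off = offset_sign * cfg.venous_offset * perp
                p_in = np.array([cx, cy]) + r0 * u + off
                p_out = np.array([cx, cy]) + r1_bed * u + off
                if bed in outward_beds:
                    line = np.stack([p_in, p_out])
                else:
                    line = np.stack([p_out, p_in])
                vessels.append(PhantomVessel(
                    centerline=line, radius=cfg.vessel_radius, bed=bed,
                    base_speed=cfg.bed_speeds[bed], id=vid))
                vid += 1

    label_map = _region_label_map(cfg)
    return RenalPhantom(vessels=vessels, label_map=label_map, config=cfg)


def _region_label_map(cfg: PhantomConfig) -> np.ndarray:
    h, w = cfg.grid_shape
    yy = (np.arange(h)[:, None] + 0.5) * cfg.pixel_pitch
    xx = (np.arange(w)[None, :] + 0.5) * cfg.pixel_pitch
    r = np.hypot(xx - cfg.center[0], yy - cfg.center[1])
    labels = np.zeros((h, w), dtype=np.uint8)
    for region, (r_in, r_out) in cfg.region_radii.items():
        labels[(r >= r_in) & (r < r_out)] = REGION_LABELS[region]
    return labels


# ---------------------------------------------------------------------------
# Hemodynamics: MAP trace and prazosin speed modulation
# ---------------------------------------------------------------------------

@dataclass
class HemodynamicsParams:
    """Landmark parameterization of the prazosin MAP response.

    The noise-free trace is flat at ``map_baseline`` until
    ``t_inj + t_drop_onset``, decays exponentially to ``map_min`` reaching it
    at ``t_inj + t_drop_peak`` (trough 52-82 s after injection in the study;
    default peak 67 s), then relaxes exponentially toward ``map_recovery``.
    """

    map_baseline: float = 84.0
    map_min: float = 54.0
    map_recovery: float = 65.0
    t_drop_onset: float = 10.0
    t_drop_peak: float = 67.0
    noise_sd: float = 4.0
    drop_sharpness: float = 4.0    # drop time constant = interval / sharpness
    recovery_tau: float = 100.0    # s
    multipliers: dict = field(default_factory=lambda: {
        bed: tuple(m) for bed, m in DEFAULT_MULTIPLIERS.items()})
    seed: int = 0

    def validate(self) -> None:
        if not self.map_min < self.map_recovery < self.map_baseline:
            raise ValueError("require map_min < map_recovery < map_baseline")
        if self.t_drop_peak <= self.t_drop_onset:
            raise ValueError("t_drop_peak must exceed t_drop_onset")
        for bed, m in self.multipliers.items():
            if np.any(np.asarray(m) <= 0):
                raise ValueError(f"multipliers for {bed} must be positive")


def map_model(t, params: HemodynamicsParams, t_inj: float):
    """Noise-free MAP (mmHg) at time(s) ``t`` seconds of scan 2."""
    params.validate()
    t = np.asarray(t, dtype=float)
    t_on = t_inj + params.t_drop_onset
    t_pk = t_inj + params.t_drop_peak
    tau_d = (params.t_drop_peak - params.t_drop_onset) / params.drop_sharpness
    drop = params.map_min + (params.map_baseline - params.map_min) * np.exp(
        -(np.minimum(t, t_pk) - t_on) / tau_d)
    v_pk = params.map_min + (params.map_baseline - params.map_min) * np.exp(
        -(params.t_drop_peak - params.t_drop_onset) / tau_d)
    rec = params.map_recovery - (params.map_recovery - v_pk) * np.exp(
        -(t - t_pk) / params.recovery_tau)
    out = np.where(t < t_on, params.map_baseline, np.where(t < t_pk, drop, rec))
    return out if out.ndim else float(out)


def simulate_map_trace(params: HemodynamicsParams, duration: float, t_inj: float,
                       rng=None):
    """1-Hz MAP trace (t, mmHg) for scan 2 with additive Gaussian noise."""
    if not duration > t_inj >= 0:
        raise ValueError("require duration > t_inj >= 0")
    params.validate()
    t = np.arange(0.0, duration, 1.0)
    values = map_model(t, params, t_inj)
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed) if rng is None else rng
        values = values + rng.normal(0.0, params.noise_sd, size=t.shape)
    return t, values


def map_excursion(t, params: HemodynamicsParams, t_inj: float):
    """Normalized MAP excursion g(t) in [0, 1]; 0 before the drop onset."""
    m = map_model(t, params, t_inj)
    g = (params.map_baseline - m) / (params.map_baseline - params.map_min)
    return np.clip(g, 0.0, 1.0)


def speed_multiplier(params: HemodynamicsParams, bed: str, t, scan: int,
                     t_inj: float | None = None,
                     analysis_window: float = 410.0):
    """Commanded speed multiplier for ``bed`` at time(s) ``t`` of ``scan``.

    Scans 1 and 3 use a constant multiplier.  During scan 2 the multiplier is
    coupled to the normalized MAP excursion, ``m(t) = 1 - alpha * g(t)``, with
    ``alpha`` scaled so the mean multiplier over the post-injection analysis
    window ``[t_inj, t_inj + analysis_window]`` equals the configured scan-2
    target.  Before injection the multiplier is the scan-1 level.
    """
    m1, m2, m3 = params.multipliers.get(bed, (1.0, 1.0, 1.0))
    t = np.asarray(t, dtype=float)
    if scan == 1:
        out = np.full(t.shape, m1)
    elif scan == 3:
        out = np.full(t.shape, m3)
    elif scan == 2:
        if t_inj is None:
            raise ValueError("scan 2 requires t_inj")
        tg = np.linspace(t_inj, t_inj + analysis_window, 2049)
        g_mean = float(np.mean(map_excursion(tg, params, t_inj)))
        alpha = 0.0 if g_mean == 0 else (1.0 - m2 / m1) / g_mean
        out = m1 * (1.0 - alpha * map_excursion(t, params, t_inj))
        out = np.where(t < t_inj, m1, out)
    else:
        raise ValueError("scan must be 1, 2, or 3")
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Microbubble trajectories
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthTrajectory:
    """True path of one simulated microbubble, sampled at frame times."""

    id: int
    vessel_id: int
    bed: str
    entry_time: float
    frames: np.ndarray    # (n,) int
    times: np.ndarray     # (n,) s
    x: np.ndarray         # (n,) mm
    y: np.ndarray         # (n,) mm
    speeds: np.ndarray    # (n,) commanded speed at each frame, mm/s
    disruption_time: float | None = None

    def __len__(self) -> int:
        return len(self.frames)


def simulate_microbubbles(vessels, hemo: HemodynamicsParams, duration: float,
                          arrival_rate: float, rng, *,
                          frame_rate: float = DEFAULT_FRAME_RATE,
                          scan: int = 1, t_inj: float | None = None,
                          analysis_window: float = 410.0,
                          disruption_prob: float = 0.02) -> list:
    """Simulate microbubble ground-truth trajectories for one scan.

    Arrivals form a Poisson process of total rate ``arrival_rate`` (MB/s)
    split evenly across vessels (thinning keeps each vessel's process
    Poisson).  Each microbubble is advected along its vessel's centerline at
    ``base_speed * speed_multiplier(t)``, advanced per frame, and truncated at
    the vessel exit, scan end, or an exponential disruption time with
    per-second disruption probability ``disruption_prob``.
    """
    if arrival_rate <= 0:
        raise ValueError("arrival_rate must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    vessels = list(vessels)
    if not vessels:
        return []
    n_frames = int(round(duration * frame_rate))
    frame_times = np.arange(n_frames) / frame_rate
    # commanded multiplier per bed per frame (piecewise-constant advection)
    mult = {bed: np.asarray(speed_multiplier(
        hemo, bed, frame_times, scan, t_inj=t_inj,
        analysis_window=analysis_window)) for bed in BEDS}
    lam_disrupt = -np.log1p(-disruption_prob) if disruption_prob > 0 else 0.0

    trajectories = []
    tid = 0
    rate_v = arrival_rate / len(vessels)
    for vessel in vessels:
        n_arrivals = rng.poisson(rate_v * duration)
        entries = np.sort(rng.uniform(0.0, duration, size=n_arrivals))
        for t0 in entries:
            k0 = int(np.ceil(t0 * frame_rate - 1e-12))
            if k0 >= n_frames:
                continue
            t_disrupt = None
            t_end = duration
            if lam_disrupt > 0:
                t_disrupt = t0 + rng.exponential(1.0 / lam_disrupt)
                t_end = min(t_end, t_disrupt)
            v = vessel.base_speed * mult[vessel.bed]
            # advect per frame: s advances by v[k]/frame_rate each frame
            frames, speeds, ss = [], [], []
            s = v[k0] * (k0 / frame_rate - t0)  # distance covered before first frame
            k = k0
            while k < n_frames and s <= vessel.length and k / frame_rate <= t_end:
                frames.append(k)
                speeds.append(v[k])
                ss.append(s)
                s += v[k] / frame_rate
                k += 1
            if not frames:
                continue
            frames = np.asarray(frames, dtype=int)
            pts = vessel.point_at(np.asarray(ss))
            trajectories.append(GroundTruthTrajectory(
                id=tid, vessel_id=vessel.id, bed=vessel.bed, entry_time=float(t0),
                frames=frames, times=frames / frame_rate,
                x=pts[:, 0], y=pts[:, 1],
                speeds=np.asarray(speeds, dtype=float),
                disruption_time=(float(t_disrupt) if t_disrupt is not None
                                 and t_disrupt < duration else None)))
            tid += 1
    return trajectories


# ---------------------------------------------------------------------------
# Tissue motion
# ---------------------------------------------------------------------------

@dataclass
class TissueMotion:
    """Residual respiratory tissue motion model.

    A smooth, periodic (ventilator frequency), spatially varying axial
    displacement: ``d_y(x, t) = amplitude * sin(2 pi f t + phase) * w(x)``
    with weight ``w(x) = cos(pi x / (2 Lx))`` so the peak displacement equals
    ``amplitude`` exactly (at ``x = 0`` and sine peak) and decays smoothly
    across the field of view.
    """

    amplitude: float = 0.1            # mm
    frequency: float = RESPIRATORY_RATE_HZ
    phase: float = 0.0
    extent_x: float = 6.4             # mm, field width (sets spatial scale)

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")

    @property
    def period(self) -> float:
        return 1.0 / self.frequency

    def displacement(self, points, t: float) -> np.ndarray:
        """(N, 2) displacement (dx, dy) in mm at positions ``points`` (mm)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self.amplitude == 0:
            return np.zeros_like(pts)
        w = np.cos(0.5 * np.pi * pts[:, 0] / self.extent_x)
        dy = self.amplitude * np.sin(2 * np.pi * self.frequency * t + self.phase) * w
        out = np.zeros_like(pts)
        out[:, 1] = dy
        return out

    def field_on_grid(self, grid_shape, pixel_pitch: float, t: float) -> np.ndarray:
        """Dense (H, W, 2) displacement field (dx, dy) in mm at time ``t``."""
        h, w = grid_shape
        xx = (np.arange(w) + 0.5) * pixel_pitch
        field = np.zeros((h, w, 2))
        if self.amplitude == 0:
            return field
        wt = np.cos(0.5 * np.pi * xx / self.extent_x)
        dy = self.amplitude * np.sin(2 * np.pi * self.frequency * t + self.phase) * wt
        field[:, :, 1] = dy[None, :]
        return field


def apply_tissue_motion(t: float, motion: TissueMotion, grid_shape,
                        pixel_pitch: float) -> np.ndarray:
    """Dense displacement field of the motion model at time ``t`` (mm)."""
    return motion.field_on_grid(grid_shape, pixel_pitch, t)


# ---------------------------------------------------------------------------
# Frame rendering
# ---------------------------------------------------------------------------

@dataclass
class RenderParams:
    """Point-spread and noise model for frame rendering."""

    psf_sigma: float = 0.075      # mm, isotropic Gaussian PSF
    amplitude: float = 100.0      # blob peak intensity, a.u.
    noise_sd: float = 2.0         # additive Gaussian noise sd, a.u.
    speckle_sigma_px: float = 1.5  # B-mode speckle correlation length
    speckle_amplitude: float = 40.0

    def __post_init__(self) -> None:
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")


def render_frames(trajectories, grid_shape, pixel_pitch: float, n_frames: int,
                  rng, *, frame_rate: float = DEFAULT_FRAME_RATE,
                  params: RenderParams | None = None,
                  motion: TissueMotion | None = None,
                  bmode: bool = True) -> tuple:
    """Render contrast and B-mode frame stacks from ground-truth trajectories.

    Each in-frame microbubble becomes an isotropic Gaussian blob at its
    (motion-displaced) true position; additive Gaussian background noise is
    applied per frame.  The B-mode channel is a static speckle pattern warped
    by the same motion field.  Trajectory points outside the grid are silently
    out of view (logged at debug level).

    Returns ``(contrast_stack, bmode_stack_or_None)``.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    prm = params or RenderParams()
    h, w = grid_shape
    extent = (w * pixel_pitch, h * pixel_pitch)

    # bucket trajectory points by frame
    per_frame_pts: list[list] = [[] for _ in range(n_frames)]
    n_oov = 0
    for traj in trajectories:
        for k, x, y in zip(traj.frames, traj.x, traj.y):
            if 0 <= k < n_frames:
                per_frame_pts[k].append((x, y))

    sigma_px = prm.psf_sigma / pixel_pitch
    halfw = max(2, int(np.ceil(4 * sigma_px)))
    contrast = np.zeros((n_frames, h, w), dtype=np.float32)
    for k in range(n_frames):
        t = k / frame_rate
        frame = contrast[k]
        pts = per_frame_pts[k]
        if pts:
            pts = np.asarray(pts, dtype=float)
            if motion is not None:
                pts = pts + motion.displacement(pts, t)
            for x, y in pts:
                c = x / pixel_pitch - 0.5
                r = y / pixel_pitch - 0.5
                if not (-halfw < r < h - 1 + halfw and -halfw < c < w - 1 + halfw):
                    n_oov += 1
                    continue
                r0 = max(0, int(np.floor(r)) - halfw)
                r1 = min(h, int(np.ceil(r)) + halfw + 1)
                c0 = max(0, int(np.floor(c)) - halfw)
                c1 = min(w, int(np.ceil(c)) + halfw + 1)
                rr = np.arange(r0, r1)[:, None]
                cc = np.arange(c0, c1)[None, :]
                frame[r0:r1, c0:c1] += prm.amplitude * np.exp(
                    -((rr - r) ** 2 + (cc - c) ** 2) / (2 * sigma_px ** 2))
        if prm.noise_sd > 0:
            frame += rng.normal(0.0, prm.noise_sd, size=(h, w)).astype(np.float32)
    if n_oov:
        logger.debug("%d microbubble points fell outside the grid", n_oov)

    contrast_stack = FrameStack(contrast, pixel_pitch, frame_rate, channel="contrast")
    if not bmode:
        return contrast_stack, None

    # static speckle background, warped by the same motion field
    base = gaussian_filter(rng.normal(0.0, 1.0, size=(h, w)), prm.speckle_sigma_px)
    base = prm.speckle_amplitude * base / max(base.std(), 1e-12)
    rows = np.arange(h, dtype=float)[:, None] * np.ones((1, w))
    cols = np.ones((h, 1)) * np.arange(w, dtype=float)[None, :]
    bmode_frames = np.empty((n_frames, h, w), dtype=np.float32)
    for k in range(n_frames):
        t = k / frame_rate
        if motion is None or motion.amplitude == 0:
            bmode_frames[k] = base
            continue
        d = motion.field_on_grid((h, w), pixel_pitch, t)  # (H, W, 2) mm
        # inverse warp: sample the static pattern at x - d
        coords = np.stack([rows - d[:, :, 1] / pixel_pitch,
                           cols - d[:, :, 0] / pixel_pitch])
        bmode_frames[k] = map_coordinates(base, coords, order=1, mode="nearest")
    bmode_stack = FrameStack(bmode_frames, pixel_pitch, frame_rate, channel="bmode")
    return contrast_stack, bmode_stack
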