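"""Core containers and conventions shared across the pipeline.

Coordinate convention
---------------------
Images are indexed ``[row, col]`` with row = axial depth and col = lateral
position.  The center of pixel ``(r, c)`` sits at physical position
``x = (c + 0.5) * pixel_pitch`` (lateral, mm) and
``y = (r + 0.5) * pixel_pitch`` (axial, mm), origin at the image's top-left
corner.  Flow direction angles are reported in degrees in [0, 360) using the
mathematical convention on an ``x``-right / ``y``-up axis set, i.e.
``angle = atan2(-dy, dx)`` so that flow toward the transducer (decreasing
axial depth) is 90 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The six renal vascular beds velocities are estimated in.
BEDS = ("cortex_art", "cortex_ven", "om_dvr", "om_avr", "im_dvr", "im_avr")

#: Anatomical regions of the coronal kidney cross-section.
REGIONS = ("cortex", "outer_medulla", "inner_medulla")

#: Integer codes used in region label maps (0 = background).
REGION_LABELS = {"background": 0, "cortex": 1, "outer_medulla": 2, "inner_medulla": 3}
LABEL_NAMES = {v: k for k, v in REGION_LABELS.items()}

#: Arterial-side / venous-side bed of each region.
ARTERIAL_BED = {"cortex": "cortex_art", "outer_medulla": "om_dvr", "inner_medulla": "im_dvr"}
VENOUS_BED = {"cortex": "cortex_ven", "outer_medulla": "om_avr", "inner_medulla": "im_avr"}

#: Region each bed belongs to.
BED_REGION = {
    "cortex_art": "cortex",
    "cortex_ven": "cortex",
    "om_dvr": "outer_medulla",
    "om_avr": "outer_medulla",
    "im_dvr": "inner_medulla",
    "im_avr": "inner_medulla",
}

#: Tracker velocity span ceiling (mm/s); per-step speeds above it are invalid.
MAX_SPEED_MM_S = 15.0

#: Default acquisition frame rate (Hz).
DEFAULT_FRAME_RATE = 54.0


@dataclass
class FrameStack:
    """Time-ordered stack of 2-D frames for one imaging channel.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Image frames, ``[row=axial, col=lateral]``.
    pixel_pitch : float
        Pixel size in mm/pixel (isotropic).
    frame_rate : float
        Acquisition rate in Hz.
    timestamps : ndarray, shape (T,), optional
        Frame times in seconds; defaults to ``arange(T) / frame_rate``.
    channel : str
        ``"contrast"`` (microbubble channel) or ``"bmode"``.
    """

    frames: np.ndarray
    pixel_pitch: float
    frame_rate: float = DEFAULT_FRAME_RATE
    timestamps: np.ndarray | None = None
    channel: str = "contrast"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.timestamps is None:
            self.timestamps = np.arange(self.frames.shape[0]) / self.frame_rate
        else:
            self.timestamps = np.asarray(self.timestamps, dtype=float)
            if self.timestamps.shape != (self.frames.shape[0],):
                raise ValueError("timestamps length must match frame count")
            if self.frames.shape[0] > 1 and not np.all(np.diff(self.timestamps) > 0):
                raise ValueError("timestamps must be strictly increasing")
        if self.channel not in ("contrast", "bmode"):
            raise ValueError(f"unknown channel {self.channel!r}")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def extent_mm(self) -> tuple[float, float]:
        """(width, height) of the field of view in mm."""
        h, w = self.frame_shape
        return w * self.pixel_pitch, h * self.pixel_pitch


@dataclass
class Track:
    """A linked microbubble trajectory with per-step velocity estimates.

    Positions are Kalman-smoothed, in mm.  Step ``i`` connects position ``i``
    to ``i + 1``; per-step velocity vectors and speeds therefore have length
    ``n_positions - 1`` and are timestamped by the later frame of the step.
    """

    id: int
    frames: np.ndarray           # (n,) int frame indices
    times: np.ndarray            # (n,) s
    x: np.ndarray                # (n,) mm, lateral
    y: np.ndarray                # (n,) mm, axial depth
    vx: np.ndarray = field(default=None)  # (n-1,) mm/s
    vy: np.ndarray = field(default=None)  # (n-1,) mm/s
    bed: str | None = None
    region: str | None = None

    def __post_init__(self) -> None:
        n = len(self.x)
        if not (len(self.y) == len(self.times) == len(self.frames) == n):
            raise ValueError("track arrays must share a common length")
        if n >= 2:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("track timestamps must be strictly increasing")
            if self.vx is None:
                self.vx = np.diff(self.x) / dt
                self.vy = np.diff(self.y) / dt
        elif self.vx is None:
            self.vx = np.zeros(0)
            self.vy = np.zeros(0)

    def __len__(self) -> int:
        return len(self.x)

    @property
    def speeds(self) -> np.ndarray:
        """Per-step speed magnitudes, mm/s."""
        return np.hypot(self.vx, self.vy)

    @property
    def step_times(self) -> np.ndarray:
        """Timestamp of each step (the later frame's time), s."""
        return self.times[1:]

    @property
    def step_angles_deg(self) -> np.ndarray:
        """Per-step flow direction, degrees in [0, 360), y-up convention."""
        ang = np.degrees(np.arctan2(-self.vy, self.vx))
        return np.mod(ang, 360.0)

    @property
    def step_lengths(self) -> np.ndarray:
        """Per-step displacement magnitudes, mm."""
        return np.hypot(np.diff(self.x), np.diff(self.y))

    def positions(self) -> np.ndarray:
        """(n, 2) array of (x, y) positions in mm."""
        return np.column_stack([self.x, self.y])


def angular_distance_deg(a, b):
    """Smallest absolute angular distance between angles ``a`` and ``b`` (deg)."""
    return np.abs((np.asarray(a, dtype=float) - np.asarray(b, dtype=float) + 180.0) % 360.0 - 180.0)


def direction_angle_deg(dx, dy):
    """Flow angle in [0, 360) for image-space displacement (dx, dy), y-up."""
    return np.mod(np.degrees(np.arctan2(-np.asarray(dy, float), np.asarray(dx, float))), 360.0)
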