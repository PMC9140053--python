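"""Super-resolved density images and RGB direction/velocity maps.

Track positions are accumulated on a grid upsampled relative to the
acquisition grid (default factor 4).  The velocity map encodes, per
high-resolution pixel, the mean velocity vector of the contributing track
steps: hue = flow direction on the color wheel, brightness = speed saturated
at ``vmax`` (display scale; independent of the 15 mm/s tracking span).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.colors import hsv_to_rgb

from .core import direction_angle_deg


@dataclass
class GridSpec:
    """High-resolution accumulation grid derived from the acquisition grid."""

    shape: tuple[int, int]        # acquisition (H, W) pixels
    pixel_pitch: float            # acquisition pitch, mm
    upsample: int = 4

    def __post_init__(self) -> None:
        if self.upsample < 1:
            raise ValueError("upsample factor must be >= 1")

    @property
    def hr_shape(self) -> tuple[int, int]:
        return self.shape[0] * self.upsample, self.shape[1] * self.upsample

    @property
    def hr_pitch(self) -> float:
        return self.pixel_pitch / self.upsample

    def bin_of(self, x, y):
        """High-res (row, col) bin of positions in mm; out-of-grid -> -1."""
        r = np.floor(np.asarray(y, float) / self.hr_pitch).astype(int)
        c = np.floor(np.asarray(x, float) / self.hr_pitch).astype(int)
        h, w = self.hr_shape
        ok = (r >= 0) & (r < h) & (c >= 0) & (c < w)
        r = np.where(ok, r, -1)
        c = np.where(ok, c, -1)
        return r, c


def accumulate_density(tracks, grid: GridSpec) -> np.ndarray:
    """Per-pixel count of track positions on the high-resolution grid."""
    img = np.zeros(grid.hr_shape, dtype=np.int64)
    for tr in tracks:
        r, c = grid.bin_of(tr.x, tr.y)
        ok = r >= 0
        np.add.at(img, (r[ok], c[ok]), 1)
    return img


def velocity_map(tracks, grid: GridSpec, vmax: float) -> np.ndarray:
    """RGB velocity map: hue = mean flow direction, brightness = speed/vmax.

    Each track step contributes its velocity vector at the step's end
    position; per pixel the mean vector is rendered.  Zero speed is black and
    speeds at or above ``vmax`` reach full brightness.
    """
    if vmax <= 0:
        raise ValueError("vmax must be positive")
    h, w = grid.hr_shape
    sum_vx = np.zeros((h, w))
    sum_vy = np.zeros((h, w))
    count = np.zeros((h, w), dtype=np.int64)
    for tr in tracks:
        if len(tr) < 2:
            continue
        r, c = grid.bin_of(tr.x[1:], tr.y[1:])
        ok = r >= 0
        np.add.at(sum_vx, (r[ok], c[ok]), tr.vx[ok])
        np.add.at(sum_vy, (r[ok], c[ok]), tr.vy[ok])
        np.add.at(count, (r[ok], c[ok]), 1)
    occupied = count > 0
    vx = np.where(occupied, sum_vx, 0.0) / np.maximum(count, 1)
    vy = np.where(occupied, sum_vy, 0.0) / np.maximum(count, 1)
    speed = np.hypot(vx, vy)
    hue = direction_angle_deg(vx, vy) / 360.0
    value = np.clip(speed / vmax, 0.0, 1.0) * occupied
    hsv = np.stack([hue, np.ones_like(hue), value], axis=-1)
    return hsv_to_rgb(hsv)
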