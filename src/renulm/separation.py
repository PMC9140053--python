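"""Arterial/venous bed separation by region mask and flow-direction sector.

Within each renal region a mean arterial flow angle is defined; tracks whose
length-weighted mean direction lies within half the sector span of that
angle are arterial, tracks within the same span of the opposite direction
are venous, and everything else is excluded.  Sector spans follow the study:
125 degrees total width in the cortex (afferent arterioles radiate at varied
angles off the cortical radial arteries) and 90 degrees in the medulla.
The span is read as the TOTAL width of the acceptance sector (half-span on
each side of the mean angle); spans below 180 degrees keep the arterial and
venous sectors disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .core import (
    ARTERIAL_BED,
    LABEL_NAMES,
    REGION_LABELS,
    VENOUS_BED,
    angular_distance_deg,
)


@dataclass
class FlowSector:
    """Angular acceptance sector of one region's arterial flow."""

    region: str
    mean_angle_deg: float
    span_deg: float

    def __post_init__(self) -> None:
        if not 0.0 < self.span_deg < 180.0:
            raise ValueError("span must lie in (0, 180) degrees so the "
                             "arterial and venous sectors are disjoint")
        self.mean_angle_deg = float(self.mean_angle_deg) % 360.0


def circular_mean_deg(angles_deg, weights=None) -> float:
    """Weighted circular mean of angles in degrees, result in [0, 360)."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    if a.size == 0:
        raise ValueError("no angles supplied")
    w = np.ones_like(a) if weights is None else np.asarray(weights, dtype=float)
    s, c = np.sum(w * np.sin(a)), np.sum(w * np.cos(a))
    if np.hypot(s, c) < 1e-15:
        raise ValueError("circular mean undefined (resultant length ~ 0)")
    return float(np.degrees(np.arctan2(s, c)) % 360.0)


def mean_arterial_angle(tracks) -> float:
    """Length-weighted circular mean of per-step flow directions (degrees).

    ``tracks`` is an iterable of :class:`~renulm.core.Track` drawn from a
    region of interest with visually coherent arterial flow.
    """
    angles, weights = [], []
    for tr in tracks:
        if len(tr) < 2:
            continue
        angles.append(tr.step_angles_deg)
        weights.append(tr.step_lengths)
    if not angles:
        raise ValueError("ROI contains no track steps")
    return circular_mean_deg(np.concatenate(angles), np.concatenate(weights))


def classify_track(track, sector: FlowSector, in_region=None) -> str:
    """Classify one track as ``"arterial"``, ``"venous"`` or ``"excluded"``.

    The track direction is the length-weighted circular mean of its steps
    (restricted to steps flagged by the boolean mask ``in_region`` if given).
    """
    if len(track) < 2:
        return "excluded"
    ang = track.step_angles_deg
    wgt = track.step_lengths
    if in_region is not None:
        in_region = np.asarray(in_region, dtype=bool)
        if not in_region.any():
            return "excluded"
        ang, wgt = ang[in_region], wgt[in_region]
    try:
        direction = circular_mean_deg(ang, wgt)
    except ValueError:
        return "excluded"
    half = sector.span_deg / 2.0
    if angular_distance_deg(direction, sector.mean_angle_deg) <= half:
        return "arterial"
    if angular_distance_deg(direction, sector.mean_angle_deg + 180.0) <= half:
        return "venous"
    return "excluded"


def _position_labels(track, label_map: np.ndarray, pixel_pitch: float) -> np.ndarray:
    h, w = label_map.shape
    r = np.clip((track.y / pixel_pitch).astype(int), 0, h - 1)
    c = np.clip((track.x / pixel_pitch).astype(int), 0, w - 1)
    inside = (track.y >= 0) & (track.y < h * pixel_pitch) & \
             (track.x >= 0) & (track.x < w * pixel_pitch)
    labels = label_map[r, c]
    return np.where(inside, labels, REGION_LABELS["background"])


def split_beds(tracks, label_map: np.ndarray, sectors: dict,
               pixel_pitch: float):
    """Assign tracks to the six vascular beds.

    A track's region is the region containing the majority of its positions
    (tracks mostly in background are excluded).  Within that region the track
    is classified against the region's :class:`FlowSector`; arterial maps to
    {cortex_art, om_dvr, im_dvr} and venous to {cortex_ven, om_avr, im_avr}.

    Returns ``(beds, excluded)`` where ``beds`` maps bed name to a track
    list; classified tracks get their ``region``/``bed`` attributes set.
    """
    for region in {LABEL_NAMES[lab] for lab in np.unique(label_map) if lab != 0}:
        if region not in sectors:
            raise ValueError(f"region {region!r} present in labels but has no sector")
    beds: dict[str, list] = {b: [] for b in ARTERIAL_BED.values()}
    beds.update({b: [] for b in VENOUS_BED.values()})
    excluded = []
    for tr in tracks:
        labels = _position_labels(tr, label_map, pixel_pitch)
        counts = np.bincount(labels, minlength=4)
        majority = int(np.argmax(counts))
        if majority == REGION_LABELS["background"]:
            excluded.append(tr)
            continue
        region = LABEL_NAMES[majority]
        # steps whose midpoint lies in the majority region
        step_in = (labels[:-1] == majority) | (labels[1:] == majority)
        cls = classify_track(tr, sectors[region], in_region=step_in)
        if cls == "arterial":
            bed = ARTERIAL_BED[region]
        elif cls == "venous":
            bed = VENOUS_BED[region]
        else:
            excluded.append(tr)
            continue
        tr.region = region
        tr.bed = bed
        beds[bed].append(tr)
    return beds, excluded


class BedClassifier(BaseEstimator):
    """Estimator-style wrapper for region + flow-sector bed assignment.

    Parameters are supplied at ``fit`` time (label map, sectors, pitch);
    ``predict`` returns the bed label (or ``"excluded"``) per track.
    """

    def __init__(self):
        pass

    def fit(self, label_map: np.ndarray, sectors: dict, pixel_pitch: float):
        self.label_map_ = np.asarray(label_map)
        self.sectors_ = dict(sectors)
        self.pixel_pitch_ = float(pixel_pitch)
        return self

    def predict(self, tracks) -> list:
        beds, excluded = split_beds(tracks, self.label_map_, self.sectors_,
                                    self.pixel_pitch_)
        excluded_ids = {id(tr) for tr in excluded}
        return ["excluded" if id(tr) in excluded_ids else tr.bed for tr in tracks]

    def split(self, tracks):
        return split_beds(tracks, self.label_map_, self.sectors_, self.pixel_pitch_)
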