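"""Non-rigid tissue-motion estimation and compensation.

Motion is estimated on the B-mode channel in 3 x 3 mm patches with 80%
overlap (stride 0.6 mm) against a reference frame, by maximizing the
zero-normalized cross-correlation (ZNCC) over integer shifts with parabolic
sub-pixel refinement.  Patch vectors are bilinearly interpolated to a dense
field; microbubble localizations are corrected by subtracting the
interpolated displacement at their position (nearest-in-time field).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.fft import irfft2, next_fast_len, rfft2
from scipy.interpolate import RegularGridInterpolator
from sklearn.base import BaseEstimator

from .core import FrameStack


@dataclass
class DisplacementField:
    """Patch-grid displacement vectors for one frame vs. the reference.

    ``vectors[i, j]`` is the (dx, dy) tissue displacement in mm at patch
    center ``(centers_x[j], centers_y[i])``.  The dense field is the bilinear
    interpolation of the patch grid; queries outside the patch-center
    bounding box are clamped to the nearest border value.
    """

    vectors: np.ndarray      # (gy, gx, 2) mm
    centers_x: np.ndarray    # (gx,) mm
    centers_y: np.ndarray    # (gy,) mm
    confident: np.ndarray    # (gy, gx) bool
    frame_index: int = 0
    patch_mm: float = 3.0
    overlap: float = 0.8

    def displacement_at(self, points) -> np.ndarray:
        """Interpolated (dx, dy) in mm at (x, y) query points (N, 2)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if len(self.centers_y) == 1 and len(self.centers_x) == 1:
            return np.broadcast_to(self.vectors[0, 0], (len(pts), 2)).copy()
        qx = np.clip(pts[:, 0], self.centers_x[0], self.centers_x[-1])
        qy = np.clip(pts[:, 1], self.centers_y[0], self.centers_y[-1])
        out = np.empty((len(pts), 2))
        for a in (0, 1):
            interp = RegularGridInterpolator(
                (self.centers_y, self.centers_x), self.vectors[:, :, a],
                method="linear", bounds_error=False, fill_value=None)
            out[:, a] = interp(np.column_stack([qy, qx]))
        return out

    @property
    def max_displacement(self) -> float:
        return float(np.hypot(self.vectors[..., 0], self.vectors[..., 1]).max())


def _patch_starts(size: int, patch_px: int, stride_px: int, margin: int):
    """Patch top-left offsets keeping the search window inside the frame."""
    lo, hi = margin, size - patch_px - margin
    if hi < lo:
        return np.array([max(0, (size - patch_px) // 2)])
    starts = list(range(lo, hi + 1, stride_px))
    if starts[-1] != hi:
        starts.append(hi)
    return np.asarray(starts)


def _sliding_sums(windows: np.ndarray, th: int, tw: int):
    """Sliding-window sums of each (P, wh, ww) window over a th x tw box."""
    c = np.cumsum(np.cumsum(windows, axis=1), axis=2)
    c = np.pad(c, ((0, 0), (1, 0), (1, 0)))
    return (c[:, th:, tw:] - c[:, :-th, tw:] - c[:, th:, :-tw] + c[:, :-th, :-tw])


class PatchMatcher:
    """ZNCC patch matcher against a fixed reference frame.

    Precomputes the patch grid and template FFTs of the reference once, so
    matching a long B-mode sequence against frame 0 costs one batched FFT
    correlation per frame.  Per patch the integer shift maximizing the
    zero-normalized cross-correlation within ``+/- search_mm`` is refined
    with a 1-D parabolic fit per axis.
    """

    def __init__(self, ref: np.ndarray, pixel_pitch: float,
                 patch_mm: float = 3.0, overlap: float = 0.8,
                 search_mm: float = 0.4):
        ref = np.asarray(ref, dtype=float)
        h, w = ref.shape
        patch_px = min(int(round(patch_mm / pixel_pitch)), min(h, w) - 2)
        if patch_px < 4:
            raise ValueError("patch smaller than 4 pixels; check pixel_pitch")
        stride_px = max(1, int(round(patch_px * (1.0 - overlap))))
        s = max(1, int(round(search_mm / pixel_pitch)))
        s = min(s, max(1, (h - patch_px) // 2), max(1, (w - patch_px) // 2))
        self.shape = (h, w)
        self.pixel_pitch = pixel_pitch
        self.patch_mm = patch_mm
        self.overlap = overlap
        self.patch_px = patch_px
        self.search_px = s
        self.r_starts = _patch_starts(h, patch_px, stride_px, s)
        self.c_starts = _patch_starts(w, patch_px, stride_px, s)
        gy, gx = len(self.r_starts), len(self.c_starts)
        self.grid = (gy, gx)
        win = patch_px + 2 * s
        self.win = win
        self.nfft = next_fast_len(win)

        templates = np.empty((gy * gx, patch_px, patch_px))
        for i, r0 in enumerate(self.r_starts):
            for j, c0 in enumerate(self.c_starts):
                templates[i * gx + j] = ref[r0:r0 + patch_px, c0:c0 + patch_px]
        t0 = templates - templates.mean(axis=(1, 2), keepdims=True)
        self.t_norm = np.sqrt((t0 ** 2).sum(axis=(1, 2)))
        self.flat = self.t_norm < 1e-12
        self.tf_conj = np.conj(rfft2(t0, s=(self.nfft, self.nfft)))
        self.centers_x = (self.c_starts + patch_px / 2.0) * pixel_pitch
        self.centers_y = (self.r_starts + patch_px / 2.0) * pixel_pitch

    def _windows(self, cur: np.ndarray) -> np.ndarray:
        gy, gx = self.grid
        s, p = self.search_px, self.patch_px
        out = np.empty((gy * gx, self.win, self.win))
        for i, r0 in enumerate(self.r_starts):
            for j, c0 in enumerate(self.c_starts):
                out[i * gx + j] = cur[r0 - s:r0 + p + s, c0 - s:c0 + p + s]
        return out

    def match(self, cur: np.ndarray, frame_index: int = 0) -> DisplacementField:
        """Displacement field of ``cur`` relative to the reference frame."""
        cur = np.asarray(cur, dtype=float)
        if cur.shape != self.shape:
            raise ValueError("frames must share a shape")
        gy, gx = self.grid
        s, p = self.search_px, self.patch_px
        m = 2 * s + 1
        windows = self._windows(cur)
        # circular FFT correlation; shifts 0..2s are wrap-free because the
        # templates are zero-padded by at least 2s
        num = irfft2(rfft2(windows, s=(self.nfft, self.nfft)) * self.tf_conj,
                     s=(self.nfft, self.nfft))[:, :m, :m]
        s1 = _sliding_sums(windows, p, p)
        s2 = _sliding_sums(windows ** 2, p, p)
        var = np.maximum(s2 - s1 ** 2 / (p * p), 0.0)
        denom = np.sqrt(var) * self.t_norm[:, None, None]
        with np.errstate(invalid="ignore", divide="ignore"):
            ncc = np.where(denom > 1e-12, num / np.maximum(denom, 1e-12), 0.0)

        vectors = np.zeros((gy, gx, 2))
        confident = np.zeros((gy, gx), dtype=bool)
        for q in range(gy * gx):
            i, j = divmod(q, gx)
            if self.flat[q]:
                continue
            cmap = ncc[q]
            pk = np.unravel_index(np.argmax(cmap), cmap.shape)
            du, dv = float(pk[0]), float(pk[1])
            refine = cmap[pk] < 1.0 - 1e-12  # a perfect match needs no refinement
            for axis, idx in ((0, pk[0]), (1, pk[1])) if refine else ():
                if 0 < idx < m - 1:
                    if axis == 0:
                        c_m, c_0, c_p = cmap[idx - 1, pk[1]], cmap[idx, pk[1]], cmap[idx + 1, pk[1]]
                    else:
                        c_m, c_0, c_p = cmap[pk[0], idx - 1], cmap[pk[0], idx], cmap[pk[0], idx + 1]
                    den = c_m - 2 * c_0 + c_p
                    if den < -1e-12:
                        delta = float(np.clip(0.5 * (c_m - c_p) / den, -0.5, 0.5))
                        if axis == 0:
                            du += delta
                        else:
                            dv += delta
            vectors[i, j, 0] = (dv - s) * self.pixel_pitch  # dx (cols)
            vectors[i, j, 1] = (du - s) * self.pixel_pitch  # dy (rows)
            confident[i, j] = cmap[pk] > 0.2

        return DisplacementField(vectors=vectors, centers_x=self.centers_x,
                                 centers_y=self.centers_y, confident=confident,
                                 frame_index=frame_index, patch_mm=self.patch_mm,
                                 overlap=self.overlap)


def estimate_patch_motion(ref: np.ndarray, cur: np.ndarray, pixel_pitch: float,
                          patch_mm: float = 3.0, overlap: float = 0.8,
                          search_mm: float = 0.4,
                          frame_index: int = 0) -> DisplacementField:
    """Estimate the patch-wise displacement of ``cur`` relative to ``ref``.

    Per patch the displacement maximizing the ZNCC within ``+/- search_mm``
    is found and refined with a 1-D parabolic fit per axis.  Flat
    (zero-variance) patches get zero displacement and a low-confidence flag.
    The patch stride is ``patch_mm * (1 - overlap)`` (0.6 mm by default).
    """
    return PatchMatcher(ref, pixel_pitch, patch_mm=patch_mm, overlap=overlap,
                        search_mm=search_mm).match(cur, frame_index)


def compensate_localizations(locs: pd.DataFrame, fields) -> pd.DataFrame:
    """Subtract the estimated tissue displacement from localizations.

    ``fields`` maps frame indices to :class:`DisplacementField` (dict or
    list); each localization uses the field of the nearest available frame.
    Positions outside the field domain are clamped to the border value.
    """
    if isinstance(fields, dict):
        field_frames = np.array(sorted(fields))
        field_list = [fields[k] for k in field_frames]
    else:
        field_list = list(fields)
        field_frames = np.array([f.frame_index for f in field_list])
        order = np.argsort(field_frames)
        field_frames = field_frames[order]
        field_list = [field_list[i] for i in order]
    if len(field_list) == 0:
        raise ValueError("no displacement fields supplied")
    out = locs.copy()
    if len(out) == 0:
        return out
    idx = np.searchsorted(field_frames, out["frame"].to_numpy())
    idx = np.clip(idx, 0, len(field_frames) - 1)
    left = np.clip(idx - 1, 0, len(field_frames) - 1)
    use_left = (np.abs(out["frame"].to_numpy() - field_frames[left])
                <= np.abs(field_frames[idx] - out["frame"].to_numpy()))
    nearest = np.where(use_left, left, idx)
    xy = out[["x_mm", "y_mm"]].to_numpy()
    corr = np.empty_like(xy)
    for fi in np.unique(nearest):
        sel = nearest == fi
        corr[sel] = field_list[int(fi)].displacement_at(xy[sel])
    out["x_mm"] = xy[:, 0] - corr[:, 0]
    out["y_mm"] = xy[:, 1] - corr[:, 1]
    return out


class MotionCompensator(BaseEstimator):
    """Estimator-style wrapper: fit on a B-mode stack, transform localizations.

    Parameters
    ----------
    patch_mm, overlap : float
        Patch size (mm) and fractional overlap of the estimation grid.
    search_mm : float
        Half-width of the integer-shift search range, mm.
    estimate_every : int
        Estimate a field every n-th B-mode frame; intermediate frames use the
        nearest-in-time field (respiration is slow relative to 54 Hz).
    reference_frame : int
        Index of the motion reference frame (default: first frame).
    """

    def __init__(self, patch_mm: float = 3.0, overlap: float = 0.8,
                 search_mm: float = 0.4, estimate_every: int = 1,
                 reference_frame: int = 0):
        self.patch_mm = patch_mm
        self.overlap = overlap
        self.search_mm = search_mm
        self.estimate_every = estimate_every
        self.reference_frame = reference_frame

    def fit(self, X: FrameStack, y=None):
        """Estimate displacement fields from a B-mode stack."""
        if not isinstance(X, FrameStack):
            raise TypeError("expected a FrameStack")
        matcher = PatchMatcher(X.frames[self.reference_frame], X.pixel_pitch,
                               patch_mm=self.patch_mm, overlap=self.overlap,
                               search_mm=self.search_mm)
        self.fields_ = {}
        for k in range(0, X.n_frames, self.estimate_every):
            self.fields_[k] = matcher.match(X.frames[k], frame_index=k)
        return self

    def transform(self, locs: pd.DataFrame) -> pd.DataFrame:
        """Motion-correct a localization table."""
        return compensate_localizations(locs, self.fields_)
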