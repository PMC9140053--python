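"""Hierarchical Kalman multi-target tracking of microbubble localizations.

Each track carries a constant-velocity Kalman filter (state = position +
velocity).  Per frame, tracks are associated to localizations in tiers —
confirmed tracks before tentative ones, and within each status the
slow-speed gate before the fast one — with a globally optimal one-to-one
assignment (Hungarian algorithm) on squared innovation distance inside the
gate.  Unassigned localizations spawn tentative tracks; tracks are confirmed
after ``confirm_hits`` detections and terminated after ``max_miss``
consecutive misses.  Finished tracks are Rauch-Tung-Striebel smoothed and
per-step velocities taken as finite differences of the smoothed positions;
steps faster than the 0-15 mm/s velocity span break the track.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator

from .core import MAX_SPEED_MM_S, Track


def _cv_matrices(dt: float, q_sd: float):
    """Constant-velocity transition / process-noise matrices for step dt."""
    F = np.array([[1, 0, dt, 0],
                  [0, 1, 0, dt],
                  [0, 0, 1, 0],
                  [0, 0, 0, 1]], dtype=float)
    q = q_sd ** 2
    dt2, dt3, dt4 = dt ** 2, dt ** 3, dt ** 4
    Qb = np.array([[dt4 / 4, dt3 / 2],
                   [dt3 / 2, dt2]]) * q
    Q = np.zeros((4, 4))
    Q[np.ix_([0, 2], [0, 2])] = Qb
    Q[np.ix_([1, 3], [1, 3])] = Qb
    return F, Q


H = np.array([[1.0, 0, 0, 0],
              [0, 1.0, 0, 0]])


def kalman_step(x, P, measurement, dt: float, process_noise_sd: float,
                measurement_noise_sd: float):
    """One predict(+update) cycle of the constant-velocity Kalman filter.

    Returns ``(x, P, innovation)``; with ``measurement=None`` only the
    prediction is applied and the innovation is None.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    F, Q = _cv_matrices(dt, process_noise_sd)
    x = F @ x
    P = F @ P @ F.T + Q
    if measurement is None:
        return x, P, None
    z = np.asarray(measurement, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite measurement")
    R = np.eye(2) * measurement_noise_sd ** 2
    innov = z - H @ x
    S = H @ P @ H.T + R
    K = P @ H.T @ np.linalg.inv(S)
    x = x + K @ innov
    P = (np.eye(4) - K @ H) @ P
    return x, P, innov


@dataclass
class _TrackState:
    """Internal per-track bookkeeping during filtering."""

    id: int
    x: np.ndarray
    P: np.ndarray
    hits: int = 1
    misses: int = 0
    status: str = "tentative"
    # stored filter history for RTS smoothing (measured frames only kept)
    frames: list = field(default_factory=list)
    times: list = field(default_factory=list)
    xs_pred: list = field(default_factory=list)
    Ps_pred: list = field(default_factory=list)
    xs_filt: list = field(default_factory=list)
    Ps_filt: list = field(default_factory=list)
    measured: list = field(default_factory=list)

    @property
    def speed(self) -> float:
        return float(np.hypot(self.x[2], self.x[3]))

    @property
    def predicted_pos(self) -> np.ndarray:
        return self.x[:2]


def _rts_smooth(xs_pred, Ps_pred, xs_filt, Ps_filt, F):
    n = len(xs_filt)
    xs = [None] * n
    xs[-1] = xs_filt[-1]
    Ps_s = Ps_filt[-1]
    for k in range(n - 2, -1, -1):
        C = Ps_filt[k] @ F.T @ np.linalg.inv(Ps_pred[k + 1])
        xs[k] = xs_filt[k] + C @ (xs[k + 1] - xs_pred[k + 1])
        Ps_s = Ps_filt[k] + C @ (Ps_s - Ps_pred[k + 1]) @ C.T
    return np.asarray(xs)


class KalmanTracker(BaseEstimator):
    """Hierarchical constant-velocity Kalman tracker.

    Parameters
    ----------
    process_noise_sd : float
        White-acceleration process noise, mm/s^2.  Renal flow is steady on
        the frame-to-frame scale, so the default is small.
    measurement_noise_sd : float
        Localization noise sd, mm (default: half the 0.05 mm pixel pitch).
    max_speed : float
        Tracker velocity span ceiling, mm/s; also sets the association gate
        ``max_speed * dt + 3 * measurement_noise_sd``.
    confirm_hits : int
        Detections needed to confirm a tentative track.
    max_miss : int
        Consecutive missed frames before termination.
    min_track_length : int
        Minimum number of measured positions of a kept track.
    tier_speed_bounds : tuple of float
        Upper speed bounds of the slow association tiers; tracks faster than
        the last bound use the ``max_speed`` gate.
    """

    def __init__(self, process_noise_sd: float = 1.0,
                 measurement_noise_sd: float = 0.025,
                 max_speed: float = MAX_SPEED_MM_S,
                 confirm_hits: int = 3, max_miss: int = 2,
                 min_track_length: int = 5,
                 tier_speed_bounds: tuple = (5.0,)):
        self.process_noise_sd = process_noise_sd
        self.measurement_noise_sd = measurement_noise_sd
        self.max_speed = max_speed
        self.confirm_hits = confirm_hits
        self.max_miss = max_miss
        self.min_track_length = min_track_length
        self.tier_speed_bounds = tier_speed_bounds

    # -- association ------------------------------------------------------

    def associate(self, tracks, locs: np.ndarray, dt: float):
        """Tiered gated one-to-one assignment of tracks to localizations.

        Returns ``(assignment, unassigned_locs)`` where ``assignment`` maps
        track list indices to localization row indices.
        """
        assignment: dict[int, int] = {}
        if len(locs) == 0:
            return assignment, []
        free = np.ones(len(locs), dtype=bool)
        bounds = tuple(self.tier_speed_bounds) + (self.max_speed,)

        def tier_speed(tr):
            # single-hit tracks have an uninformative velocity estimate and
            # therefore use the widest (max-speed) gate
            return tr.speed if tr.hits > 1 else self.max_speed

        for status in ("confirmed", "tentative"):
            lo = 0.0
            for hi in bounds:
                idx = [i for i, tr in enumerate(tracks)
                       if tr.status == status and lo <= tier_speed(tr) <= hi + 1e-12
                       and i not in assignment]
                lo = hi
                if not idx:
                    continue
                gate = hi * dt + 3.0 * self.measurement_noise_sd
                cand = np.nonzero(free)[0]
                if cand.size == 0:
                    continue
                preds = np.array([tracks[i].predicted_pos for i in idx])
                d2 = ((preds[:, None, :] - locs[cand][None, :, :]) ** 2).sum(-1)
                gate2 = gate * gate
                cost = np.where(d2 <= gate2, d2, 1e12)
                rows, cols = linear_sum_assignment(cost)
                for r, c in zip(rows, cols):
                    if cost[r, c] < 1e12:
                        assignment[idx[r]] = int(cand[c])
                        free[cand[c]] = False
        return assignment, list(np.nonzero(free)[0])

    # -- main loop --------------------------------------------------------

    def fit(self, locs: pd.DataFrame, y=None):
        """Link a localization table (columns frame, t, x_mm, y_mm) into tracks.

        Sets ``tracks_`` (list of :class:`renulm.core.Track`) and
        ``n_tracks_``.
        """
        locs = locs.sort_values("frame", kind="stable")
        frames = locs["frame"].to_numpy()
        tvals = locs["t"].to_numpy()
        xy = locs[["x_mm", "y_mm"]].to_numpy()

        self.tracks_ = []
        active: list[_TrackState] = []
        next_id = 0
        if len(locs) == 0:
            self.n_tracks_ = 0
            return self

        uniq_frames = np.unique(frames)
        k_min, k_max = int(uniq_frames[0]), int(uniq_frames[-1])
        all_t = {}
        for fr, tt in zip(frames, tvals):
            all_t[int(fr)] = tt
        dts = np.diff(sorted(all_t))
        dt_default = float(np.median(np.diff(tvals[np.unique(frames, return_index=True)[1]]))) \
            if len(uniq_frames) > 1 else 1.0
        by_frame = {int(k): np.nonzero(frames == k)[0] for k in uniq_frames}

        prev_t = None
        for k in range(k_min, k_max + 1):
            t = all_t.get(k, None)
            if t is None:
                t = (prev_t + dt_default) if prev_t is not None else 0.0
            dt = (t - prev_t) if prev_t is not None else dt_default
            if dt <= 0:
                dt = dt_default
            prev_t = t

            # predict all active tracks
            for tr in active:
                tr.x, tr.P, _ = kalman_step(tr.x, tr.P, None, dt,
                                            self.process_noise_sd,
                                            self.measurement_noise_sd)
                tr.xs_pred.append(tr.x.copy())
                tr.Ps_pred.append(tr.P.copy())

            rows = by_frame.get(k, np.array([], dtype=int))
            meas = xy[rows] if rows.size else np.zeros((0, 2))
            assignment, unassigned = self.associate(active, meas, dt)

            survivors = []
            for i, tr in enumerate(active):
                if i in assignment:
                    z = meas[assignment[i]]
                    F, _ = _cv_matrices(dt, self.process_noise_sd)
                    R = np.eye(2) * self.measurement_noise_sd ** 2
                    innov = z - H @ tr.x
                    S = H @ tr.P @ H.T + R
                    K = tr.P @ H.T @ np.linalg.inv(S)
                    tr.x = tr.x + K @ innov
                    tr.P = (np.eye(4) - K @ H) @ tr.P
                    tr.hits += 1
                    tr.misses = 0
                    if tr.status == "tentative" and tr.hits >= self.confirm_hits:
                        tr.status = "confirmed"
                    tr.frames.append(k)
                    tr.times.append(t)
                    tr.xs_filt.append(tr.x.copy())
                    tr.Ps_filt.append(tr.P.copy())
                    tr.measured.append(True)
                    survivors.append(tr)
                else:
                    tr.misses += 1
                    if tr.misses > self.max_miss or (tr.status == "tentative"
                                                     and tr.misses >= 1
                                                     and tr.hits < self.confirm_hits):
                        self._finalize(tr)
                    else:
                        tr.frames.append(k)
                        tr.times.append(t)
                        tr.xs_filt.append(tr.x.copy())
                        tr.Ps_filt.append(tr.P.copy())
                        tr.measured.append(False)
                        survivors.append(tr)
            active = survivors

            for j in unassigned:
                z = xy[rows[j]]
                x0 = np.array([z[0], z[1], 0.0, 0.0])
                P0 = np.diag([self.measurement_noise_sd ** 2,
                              self.measurement_noise_sd ** 2,
                              (self.max_speed / 2) ** 2,
                              (self.max_speed / 2) ** 2])
                tr = _TrackState(id=next_id, x=x0, P=P0)
                next_id += 1
                tr.frames.append(k)
                tr.times.append(t)
                tr.xs_pred.append(x0.copy())
                tr.Ps_pred.append(P0.copy())
                tr.xs_filt.append(x0.copy())
                tr.Ps_filt.append(P0.copy())
                tr.measured.append(True)
                active.append(tr)

        for tr in active:
            self._finalize(tr)
        self.n_tracks_ = len(self.tracks_)
        return self

    def _finalize(self, tr: _TrackState) -> None:
        """Smooth a finished track, enforce the speed span, store segments."""
        meas = np.asarray(tr.measured, dtype=bool)
        if meas.sum() < self.min_track_length:
            return
        # drop trailing predicted-only states
        last = int(np.nonzero(meas)[0][-1])
        n = last + 1
        if n < 2:
            return
        dts = np.diff(np.asarray(tr.times[:n]))
        F, _ = _cv_matrices(float(np.median(dts)), self.process_noise_sd)
        xs = _rts_smooth(tr.xs_pred[:n], tr.Ps_pred[:n],
                         tr.xs_filt[:n], tr.Ps_filt[:n], F)
        # keep measured positions only (the track's confirmed detections)
        keep = np.nonzero(meas[:n])[0]
        times = np.asarray(tr.times)[keep]
        frames = np.asarray(tr.frames, dtype=int)[keep]
        x = xs[keep, 0]
        y = xs[keep, 1]
        if len(keep) < self.min_track_length:
            return
        step_dt = np.diff(times)
        speeds = np.hypot(np.diff(x), np.diff(y)) / step_dt
        # break the track where the per-step speed exceeds the span
        breaks = np.nonzero(speeds > self.max_speed)[0]
        seg_bounds = np.concatenate([[0], breaks + 1, [len(x)]]) if breaks.size \
            else np.array([0, len(x)])
        for a, b in zip(seg_bounds[:-1], seg_bounds[1:]):
            if b - a < self.min_track_length:
                continue
            self.tracks_.append(Track(
                id=len(self.tracks_), frames=frames[a:b], times=times[a:b],
                x=x[a:b], y=y[a:b]))

    def fit_predict(self, locs: pd.DataFrame, y=None):
        """Fit and return the track list."""
        return self.fit(locs).tracks_


def build_tracks(locs: pd.DataFrame, **params) -> list:
    """Functional wrapper: link localizations into smoothed tracks."""
    return KalmanTracker(**params).fit_predict(locs)


def associate(tracks, localizations, params: KalmanTracker | None = None,
              dt: float = 1.0 / 54.0):
    """Standalone tiered association (see :meth:`KalmanTracker.associate`)."""
    tracker = params or KalmanTracker()
    return tracker.associate(tracks, np.asarray(localizations, dtype=float), dt)
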