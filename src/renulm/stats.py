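"""Velocity time series, injection-aligned period summaries, and the study's
statistical comparisons.

Speed samples are per track position (timestamped by frame).  Dynamic
responses are displayed as centered 30-s moving averages stepped every
second; scan comparisons use 410-s means aligned to the prazosin injection
(scan 2) or the first 410 s (scans 1 and 3).  Comparisons across the three
scans use a repeated-measures one-way ANOVA with Greenhouse-Geisser
correction and Tukey's multiple-comparisons test on transformed speeds
(natural log in the cortex, square root in the medulla).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import BED_REGION, BEDS


# ---------------------------------------------------------------------------
# Series and windows
# ---------------------------------------------------------------------------

def speed_samples(tracks) -> pd.DataFrame:
    """Time-stamped per-step speed samples (columns ``t``, ``speed``)."""
    ts, vs = [], []
    for tr in tracks:
        if len(tr) < 2:
            continue
        ts.append(tr.step_times)
        vs.append(tr.speeds)
    if not ts:
        return pd.DataFrame({"t": np.zeros(0), "speed": np.zeros(0)})
    return pd.DataFrame({"t": np.concatenate(ts), "speed": np.concatenate(vs)})


def moving_average_series(samples: pd.DataFrame, window: float = 30.0,
                          step: float = 1.0, t_start: float | None = None,
                          t_end: float | None = None) -> pd.DataFrame:
    """Centered moving average of speed samples.

    The value at time ``t`` is the mean of all samples with timestamps in
    ``[t - window/2, t + window/2]``; windows with no samples are NaN.
    Returns a DataFrame with columns ``t``, ``mean``, ``n``.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    t = np.asarray(samples["t"], dtype=float)
    v = np.asarray(samples["speed"], dtype=float)
    if t_start is None:
        t_start = 0.0 if t.size == 0 else np.floor(t.min())
    if t_end is None:
        t_end = t_start if t.size == 0 else np.ceil(t.max())
    grid = np.arange(t_start, t_end + step / 2, step)
    order = np.argsort(t)
    t, v = t[order], v[order]
    csum = np.concatenate([[0.0], np.cumsum(v)])
    lo = np.searchsorted(t, grid - window / 2, side="left")
    hi = np.searchsorted(t, grid + window / 2, side="right")
    n = hi - lo
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, (csum[hi] - csum[lo]) / np.maximum(n, 1), np.nan)
    return pd.DataFrame({"t": grid, "mean": mean, "n": n})


@dataclass
class PeriodWindows:
    """Injection-aligned analysis windows of a three-scan session (seconds).

    ``scan2_span`` is the display span (50 s before to 410 s after
    injection, i.e. 460 s); ``scan2_mean_window`` the post-injection mean
    window; scans 1 and 3 use their first ``post_s`` seconds.
    """

    t_inj: float
    pre_s: float = 50.0
    post_s: float = 410.0

    @property
    def scan2_span(self) -> tuple[float, float]:
        return (self.t_inj - self.pre_s, self.t_inj + self.post_s)

    @property
    def scan2_mean_window(self) -> tuple[float, float]:
        return (self.t_inj, self.t_inj + self.post_s)

    @property
    def scan13_window(self) -> tuple[float, float]:
        return (0.0, self.post_s)

    @property
    def span_length(self) -> float:
        return self.pre_s + self.post_s


def align_to_injection(t_inj: float, scan2_duration: float,
                       pre_s: float = 50.0, post_s: float = 410.0) -> PeriodWindows:
    """Build the aligned analysis windows; reject sessions too short to align."""
    if t_inj < 0:
        raise ValueError("t_inj must be non-negative")
    if t_inj + post_s > scan2_duration + 1e-9:
        raise ValueError(
            f"scan 2 too short: t_inj + {post_s} s = {t_inj + post_s} s exceeds "
            f"the {scan2_duration} s acquisition")
    return PeriodWindows(t_inj=t_inj, pre_s=pre_s, post_s=post_s)


def lowest_map_window(t, values, t_inj: float, width: float = 30.0,
                      search_end: float | None = None) -> float:
    """Start time of the contiguous post-injection window minimizing mean MAP.

    Ties resolve to the earliest window.  ``search_end`` bounds the window
    end (defaults to the end of the trace).
    """
    t = np.asarray(t, dtype=float)
    values = np.asarray(values, dtype=float)
    if search_end is None:
        search_end = t[-1]
    starts = t[(t >= t_inj - 1e-9) & (t + width <= search_end + 1e-9)]
    if starts.size == 0:
        raise ValueError("trace does not cover a full window after injection")
    best_t, best_m = starts[0], np.inf
    for s in starts:
        sel = (t >= s - 1e-9) & (t <= s + width + 1e-9)
        m = values[sel].mean()
        if m < best_m - 1e-12:
            best_m, best_t = m, s
    return float(best_t)


def window_mean(samples: pd.DataFrame, lo: float, hi: float) -> float:
    sel = (samples["t"] >= lo - 1e-9) & (samples["t"] <= hi + 1e-9)
    vals = samples.loc[sel, "speed"]
    return float(vals.mean()) if len(vals) else np.nan


def seconds_with_estimates(samples: pd.DataFrame, lo: float, hi: float) -> int:
    """Number of distinct 1-s bins in [lo, hi) containing >= 1 speed sample."""
    sel = (samples["t"] >= lo - 1e-9) & (samples["t"] < hi - 1e-9)
    if not sel.any():
        return 0
    return int(np.unique(np.floor(samples.loc[sel, "t"] - lo).astype(int)).size)


# ---------------------------------------------------------------------------
# Session summaries
# ---------------------------------------------------------------------------

@dataclass
class ScanSession:
    """A three-scan session: per-scan bed track sets, MAP traces, t_inj."""

    tracks_by_bed: list                  # [scan1, scan2, scan3] dicts bed -> tracks
    t_inj: float                         # s on the scan-2 clock
    scan_duration: float
    map_traces: list | None = None       # [(t, mmHg)] per scan, optional
    pre_s: float = 50.0
    post_s: float = 410.0
    subject: int | None = None

    def windows(self) -> PeriodWindows:
        return align_to_injection(self.t_inj, self.scan_duration,
                                  self.pre_s, self.post_s)


def bed_summaries(session: ScanSession) -> pd.DataFrame:
    """Per bed/scan mean speed and coverage over the aligned windows.

    Columns: bed, scan, mean, sd, n_samples, seconds_with_estimates,
    samples_per_second.  Empty beds yield NaN means.
    """
    win = session.windows()
    rows = []
    for scan in (1, 2, 3):
        lo, hi = win.scan2_mean_window if scan == 2 else win.scan13_window
        for bed in BEDS:
            tracks = session.tracks_by_bed[scan - 1].get(bed, [])
            samples = speed_samples(tracks)
            sel = (samples["t"] >= lo - 1e-9) & (samples["t"] <= hi + 1e-9)
            vals = samples.loc[sel, "speed"].to_numpy()
            secs = seconds_with_estimates(samples, lo, hi)
            rows.append({
                "bed": bed, "scan": scan,
                "mean": float(vals.mean()) if vals.size else np.nan,
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
                "n_samples": int(vals.size),
                "seconds_with_estimates": secs,
                "samples_per_second": vals.size / (hi - lo),
            })
    return pd.DataFrame(rows)


def scan2_subperiods(session: ScanSession, width: float = 30.0) -> pd.DataFrame:
    """Scan-2 sub-period means per bed: baseline (first ``width`` s of the
    scan), lowest-MAP window, and recovery (last ``width`` s of the aligned
    post-injection window)."""
    win = session.windows()
    if session.map_traces is None:
        raise ValueError("sub-period analysis requires a scan-2 MAP trace")
    t_map, v_map = session.map_traces[1]
    low_start = lowest_map_window(t_map, v_map, session.t_inj, width,
                                  search_end=win.scan2_mean_window[1])
    periods = {
        "baseline": (0.0, width),
        "lowest_map": (low_start, low_start + width),
        "recovery": (win.scan2_mean_window[1] - width, win.scan2_mean_window[1]),
    }
    rows = []
    for bed in BEDS:
        samples = speed_samples(session.tracks_by_bed[1].get(bed, []))
        for name, (lo, hi) in periods.items():
            rows.append({"bed": bed, "period": name,
                         "mean": window_mean(samples, lo, hi)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Transforms and tests
# ---------------------------------------------------------------------------

def transform_speeds(speeds, region: str) -> np.ndarray:
    """Normalizing transform: natural log (cortex) or square root (medulla)."""
    v = np.asarray(speeds, dtype=float)
    if region == "cortex":
        if np.any(v <= 0):
            raise ValueError("log transform requires positive cortical speeds")
        return np.log(v)
    if region in ("outer_medulla", "inner_medulla", "medulla"):
        if np.any(v < 0):
            raise ValueError("square-root transform requires non-negative speeds")
        return np.sqrt(v)
    raise ValueError(f"unknown region {region!r}")


def transform_for_bed(speeds, bed: str) -> np.ndarray:
    return transform_speeds(speeds, BED_REGION[bed])


@dataclass
class TestResult:
    statistic: float
    df: tuple
    p: float
    degenerate: bool = False
    extra: dict = field(default_factory=dict)


def paired_t(x, y) -> TestResult:
    """Two-sided paired t-test; df = n - 1.

    Zero-variance differences with a nonzero mean are flagged degenerate and
    reported with p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("paired_t requires two equal-length vectors, n >= 2")
    d = x - y
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return TestResult(0.0, (n - 1,), 1.0)
        return TestResult(np.inf if d.mean() > 0 else -np.inf, (n - 1,), 0.0,
                          degenerate=True)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * sps.t.sf(abs(t), n - 1)
    return TestResult(float(t), (n - 1,), float(p))


def gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon of an (n subjects x k conditions) matrix.

    Computed from the eigenvalues of the double-centered condition covariance
    matrix: ``eps = (sum lam)^2 / ((k - 1) * sum lam^2)``; bounded in
    ``[1/(k-1), 1]``.
    """
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    S = np.cov(data, rowvar=False, ddof=1)
    Hc = np.eye(k) - np.ones((k, k)) / k
    Sc = Hc @ S @ Hc
    lam = np.linalg.eigvalsh(Sc)
    lam = np.clip(lam, 0.0, None)
    denom = (k - 1) * np.sum(lam ** 2)
    if denom <= 0:
        return 1.0
    eps = np.sum(lam) ** 2 / denom
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def rm_anova_gg(data) -> TestResult:
    """One-way repeated-measures ANOVA with Greenhouse-Geisser correction.

    ``data`` is (n subjects x k conditions), complete.  Returns F, the
    GG-corrected degrees of freedom ``(eps*(k-1), eps*(k-1)*(n-1))``, the
    corrected p-value, and ``extra={'epsilon', 'df_uncorrected'}``.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("rm_anova_gg requires an (n >= 2) x (k >= 2) matrix")
    if not np.all(np.isfinite(data)):
        raise ValueError("rm_anova_gg requires complete data")
    n, k = data.shape
    grand = data.mean()
    cond_means = data.mean(axis=0)
    subj_means = data.mean(axis=1)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_tot = np.sum((data - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_err = ss_err / df2
    if ms_err <= 0:
        return TestResult(np.nan, (df1, df2), np.nan, degenerate=True,
                          extra={"epsilon": 1.0, "df_uncorrected": (df1, df2)})
    F = (ss_cond / df1) / ms_err
    eps = gg_epsilon(data)
    df1c, df2c = eps * df1, eps * df2
    p = float(sps.f.sf(F, df1c, df2c))
    return TestResult(float(F), (df1c, df2c), p,
                      extra={"epsilon": eps, "df_uncorrected": (df1, df2),
                             "ms_error": ms_err})


def tukey_hsd(data, pairs=None) -> pd.DataFrame:
    """Tukey multiple comparisons for within-subject condition means.

    Uses the RM-ANOVA within-subject error term:
    ``q = |m_i - m_j| / sqrt(MS_error / n)`` referred to the studentized
    range distribution with ``k`` groups and ``(k-1)(n-1)`` df.  Returns a
    DataFrame with columns ``i, j, diff, q, p_adj``.
    """
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    res = rm_anova_gg(data)
    if res.degenerate:
        raise ValueError("within-subject error is zero; Tukey undefined")
    ms_err = res.extra["ms_error"]
    df_err = (k - 1) * (n - 1)
    means = data.mean(axis=0)
    se = np.sqrt(ms_err / n)
    if pairs is None:
        pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    rows = []
    for i, j in pairs:
        diff = means[i] - means[j]
        q = abs(diff) / se
        p = float(sps.studentized_range.sf(q, k, df_err))
        rows.append({"i": i, "j": j, "diff": float(diff), "q": float(q),
                     "p_adj": min(1.0, p)})
    return pd.DataFrame(rows)


def pearson_log(map_values, log_speeds) -> TestResult:
    """Squared Pearson correlation of log-speed vs MAP with two-sided p."""
    x = np.asarray(map_values, dtype=float)
    y = np.asarray(log_speeds, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("pearson_log requires >= 3 pairs")
    if x.std() == 0 or y.std() == 0:
        return TestResult(np.nan, (len(x) - 2,), np.nan, degenerate=True)
    r, p = sps.pearsonr(x, y)
    return TestResult(float(r ** 2), (len(x) - 2,), float(p),
                      extra={"r": float(r)})
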