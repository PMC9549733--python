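"""Per-track motility feature battery.

Implements the displacement-statistics features used to build a motility
state space from single-cell tracks: path/speed metrics, track linearity,
the mean-squared-displacement (MSD) log-log slope, the rescaled-range Hurst
exponent, the non-Gaussian parameter α₂, random-walk-baseline deltas,
movement occupancy, directional autocorrelation, and TrackMate-style
summary metrics.  Turning-angle features are deliberately not included.

Features that are undefined for a given track (stationary tracks,
zero-variance series) are returned as NaN — never silently zero — and
``feature_table`` reports per-feature missing counts.
"""

from __future__ import annotations

import logging
import math
import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .io import Track, TrackSet, fill_gaps, track_steps

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureParams:
    """Tunables of the feature battery.

    msd_lag_max caps the MSD fit range (the effective maximum lag is
    ``min(msd_lag_max, L // 4)`` for a track of length L); move_thresholds
    are speeds in μm/min above which a step counts as "moving";
    subtrack_len is the sub-track window in frames used for occupancy and
    the random-walk kurtosis delta; autocorr_lags are step lags in frames.
    """

    msd_lag_max: int = 20
    rw_n_sim: int = 100
    rw_seed: int = 1234
    move_thresholds: tuple[float, ...] = (0.5, 1.0, 2.0, 5.0)
    subtrack_len: int = 20
    autocorr_lags: tuple[int, ...] = (1, 2, 5)
    hurst_min_window: int = 8

    def __post_init__(self) -> None:
        if self.msd_lag_max < 1 or self.rw_n_sim < 1 or self.subtrack_len < 2:
            raise ValueError("counts must be positive (subtrack_len ≥ 2)")
        if any(th < 0 for th in self.move_thresholds):
            raise ValueError("move thresholds must be ≥ 0")


def path_metrics(t: Track) -> dict[str, float]:
    """Total path length, net displacement, progressivity, and speed extrema.

    progressivity = net / total (the straightness index): 1 for a perfectly
    directed path, 0 for a closed loop; defined as 0 for a stationary track.
    """
    steps, speeds = track_steps(t)
    total = float(np.linalg.norm(steps, axis=1).sum())
    net = float(np.linalg.norm(t.positions[-1] - t.positions[0]))
    return {
        "total_distance": total,
        "net_distance": net,
        "progressivity": net / total if total > 0 else 0.0,
        "max_speed": float(speeds.max()),
        "min_speed": float(speeds.min()),
        "avg_speed": float(speeds.mean()),
    }


def _planar_coords(t: Track) -> tuple[np.ndarray, np.ndarray]:
    """x, y for 2D tracks; the two largest-variance axes for 3D tracks."""
    if t.ndim == 2:
        return t.positions[:, 0], t.positions[:, 1]
    order = np.argsort(t.positions.var(axis=0))[::-1][:2]
    order.sort()  # keep axis order stable
    return t.positions[:, order[0]], t.positions[:, order[1]]


def linearity_metrics(t: Track) -> dict[str, float]:
    """Squared Pearson (linearity) and squared Spearman (spearmanrsq)
    correlation of the planar coordinates.

    A track moving along a coordinate axis has one constant coordinate and
    undefined correlations; such perfectly straight tracks map to 1.
    """
    if len(t) < 3:
        raise ValueError("linearity needs at least 3 points")
    x, y = _planar_coords(t)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"linearity": 1.0, "spearmanrsq": 1.0}
    r = stats.pearsonr(x, y).statistic
    rho = stats.spearmanr(x, y).statistic
    return {"linearity": float(r**2), "spearmanrsq": float(rho**2)}


def msd_profile(t: Track, lag_max: int = 20) -> tuple[np.ndarray, np.ndarray, float]:
    """Time-averaged MSD curve and its log-log slope.

    MSD(τ) averages |x(i+τ) − x(i)|² over all overlapping origin pairs; the
    slope is the least-squares fit of log MSD against log τ over lags
    1..min(lag_max, L//4).  Requires a gap-free track.  Returns
    (lags, msd, slope); slope is NaN when any fitted-lag MSD is zero
    (stationary track).
    """
    if t.has_gaps:
        raise ValueError("msd_profile requires a gap-free track")
    L = len(t)
    kmax = max(min(lag_max, L // 4), 2)
    lags = np.arange(1, kmax + 1)
    msd = np.empty(len(lags))
    for j, k in enumerate(lags):
        d = t.positions[k:] - t.positions[:-k]
        msd[j] = np.mean(np.sum(d**2, axis=1))
    if np.any(msd <= 0):
        return lags, msd, float("nan")
    slope = np.polyfit(np.log(lags), np.log(msd), 1)[0]
    return lags, msd, float(slope)


def _expected_rs_white_noise(n: int) -> float:
    # Anis–Lloyd expectation of R/S (population-SD convention) for
    # uncorrelated Gaussian increments; exact gamma form at small n,
    # asymptotic beyond (the two agree to <0.1% by n ≈ 340).
    i = np.arange(1, n)
    s = np.sum(np.sqrt((n - i) / i))
    if n <= 340:
        return math.exp(
            gammaln((n - 1) / 2) - 0.5 * math.log(math.pi) - gammaln(n / 2)
        ) * s
    return s / math.sqrt(n * math.pi / 2)


def hurst_rs(t: Track, min_window: int = 8) -> float:
    """Rescaled-range (R/S) Hurst exponent of the per-axis increment series.

    H ≈ 0.5 for memoryless (Brownian) motion, > 0.5 for persistent and
    < 0.5 for anti-persistent motion.  Window sizes double from
    ``min_window``; R/S is averaged over non-overlapping windows per size,
    and the raw log-log slope is debiased against the Anis–Lloyd expectation
    of R/S under uncorrelated increments (the plain slope is badly biased
    upward at the short series lengths of a time-lapse assay).  The result
    is the mean of per-axis estimates, clipped to [0, 1]; NaN when the
    increments have zero variance.
    """
    if t.has_gaps:
        raise ValueError("hurst_rs requires a gap-free track")
    if len(t) < 16:
        raise ValueError("hurst_rs needs at least 16 points")
    inc = np.diff(t.positions, axis=0)
    n = inc.shape[0]
    sizes = []
    w = min_window
    while w <= n // 2 or (not sizes and w <= n):
        sizes.append(w)
        w *= 2
    while len(sizes) < 2 and sizes[0] >= 8:
        sizes.insert(0, sizes[0] // 2)
    if len(sizes) < 2:
        return float("nan")

    h_per_axis = []
    for ax in range(t.ndim):
        series = inc[:, ax]
        log_rs, log_w = [], []
        for w in sizes:
            m = n // w
            chunks = series[: m * w].reshape(m, w)
            dev = chunks - chunks.mean(axis=1, keepdims=True)
            z = np.cumsum(dev, axis=1)
            r = z.max(axis=1) - z.min(axis=1)
            s = chunks.std(axis=1)
            ok = s > 0
            if not ok.any():
                continue
            rs = np.mean(r[ok] / s[ok])
            log_rs.append(np.log2(rs) - np.log2(_expected_rs_white_noise(w)))
            log_w.append(np.log2(w))
        if len(log_w) < 2:
            continue
        slope = np.polyfit(log_w, log_rs, 1)[0]
        h_per_axis.append(0.5 + slope)
    if not h_per_axis:
        return float("nan")
    return float(np.clip(np.mean(h_per_axis), 0.0, 1.0))


def nongauss_alpha2(t: Track, lag: int = 1) -> float:
    """Non-Gaussian parameter α₂ of lag-τ displacements, averaged over axes.

    Per axis, α₂ = ⟨Δx⁴⟩ / (3 ⟨Δx²⟩²) − 1; zero for Gaussian displacements,
    negative for platykurtic and positive for heavy-tailed step statistics.
    """
    if t.has_gaps:
        raise ValueError("nongauss_alpha2 requires a gap-free track")
    d = t.positions[lag:] - t.positions[:-lag]
    if d.shape[0] < 8:
        raise ValueError("need at least 8 displacements at the requested lag")
    m2 = np.mean(d**2, axis=0)
    if np.any(m2 == 0):
        return float("nan")
    m4 = np.mean(d**4, axis=0)
    return float(np.mean(m4 / (3.0 * m2**2) - 1.0))


def _subtrack_kurtosis(magnitudes: np.ndarray, subtrack_len: int) -> np.ndarray:
    """Mean excess kurtosis of a magnitude series over non-overlapping
    sub-tracks of ``subtrack_len`` samples (whole series if shorter).
    Works on 1D (n,) or batched 2D (n_sim, n) input; returns per-row means."""
    arr = np.atleast_2d(magnitudes)
    n = arr.shape[1]
    m = n // subtrack_len
    with warnings.catch_warnings():
        # constant-speed sub-tracks have no defined kurtosis; scipy warns
        # before returning the NaN we propagate
        warnings.simplefilter("ignore", RuntimeWarning)
        if m == 0:
            return stats.kurtosis(arr, axis=1, fisher=True, bias=True)
        chunks = arr[:, : m * subtrack_len].reshape(arr.shape[0], m, subtrack_len)
        return stats.kurtosis(chunks, axis=2, fisher=True, bias=True).mean(axis=1)


def _batch_pearson_r2(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    out = np.full(x.shape[0], 1.0)  # straight axis-aligned walks → 1, cf. linearity policy
    ok = den > 0
    out[ok] = (num[ok] / den[ok]) ** 2
    return out


def random_walk_deltas(
    t: Track,
    n_sim: int = 100,
    seed: int = 1234,
    subtrack_len: int = 20,
) -> dict[str, float]:
    """Observed feature minus its mean over matched isotropic random walks.

    The null walks keep the track's step count and resample its observed
    step lengths with replacement, drawing fresh isotropic directions, so
    each delta asks "how does this cell differ from a memoryless walker
    with the same speed distribution?".  Deterministic given ``seed``.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be ≥ 1")
    if len(t) < 3:
        raise ValueError("random_walk_deltas needs at least 3 points")
    steps, _ = track_steps(t)
    lengths = np.linalg.norm(steps, axis=1)
    n_steps, d = steps.shape

    rng = np.random.default_rng(np.random.SeedSequence([seed, _track_hash(t)]))
    sim_len = rng.choice(lengths, size=(n_sim, n_steps), replace=True)
    dirs = rng.standard_normal((n_sim, n_steps, d))
    dirs /= np.maximum(np.linalg.norm(dirs, axis=2, keepdims=True), 1e-300)
    sim_steps = sim_len[:, :, None] * dirs
    sim_pos = np.concatenate(
        [np.zeros((n_sim, 1, d)), np.cumsum(sim_steps, axis=1)], axis=1
    )

    sim_lin = _batch_pearson_r2(sim_pos[:, :, 0], sim_pos[:, :, 1])
    sim_net = np.linalg.norm(sim_pos[:, -1, :], axis=1)
    sim_kurt = _subtrack_kurtosis(sim_len, subtrack_len)

    obs_lin = linearity_metrics(t)["linearity"]
    obs_net = float(np.linalg.norm(t.positions[-1] - t.positions[0]))
    obs_kurt = float(_subtrack_kurtosis(lengths, subtrack_len)[0])

    finite = sim_kurt[np.isfinite(sim_kurt)]
    rw_kurt = obs_kurt - float(finite.mean()) if finite.size else float("nan")
    return {
        "rw_linearity": obs_lin - float(sim_lin.mean()),
        "rw_netdist": obs_net - float(sim_net.mean()),
        "rw_kurtosis": rw_kurt,
    }


def _track_hash(t: Track) -> int:
    # stable per-track stream key so deltas don't depend on table order
    # (zlib.crc32 is process-independent, unlike builtin hash())
    return zlib.crc32(t.track_id.encode()) % (2**31)


def movement_occupancy(
    t: Track, thresholds: tuple[float, ...] = (0.5, 1.0, 2.0, 5.0), subtrack_len: int = 20
) -> dict[str, float]:
    """Fraction of time moving and mean moving speed, per speed threshold.

    The track is split into non-overlapping sub-tracks of ``subtrack_len``
    frames; within each, a step is "moving" when its speed exceeds the
    threshold.  Reported values are across-sub-track means;
    avg_moving_speed is 0 when no step moves.
    """
    if subtrack_len > len(t):
        raise ValueError("subtrack_len exceeds track length")
    _, speeds = track_steps(t)
    n_windows = max(len(t) // subtrack_len, 1)
    out: dict[str, float] = {}
    for th in thresholds:
        fracs, mov_speeds = [], []
        for w in range(n_windows):
            sl = speeds[w * subtrack_len : (w + 1) * subtrack_len - 1] if n_windows > 1 \
                else speeds
            if len(sl) == 0:
                continue
            moving = sl > th
            fracs.append(moving.mean())
            mov_speeds.append(sl[moving].mean() if moving.any() else 0.0)
        key = _fmt_threshold(th)
        out[f"time_moving_{key}"] = float(np.mean(fracs))
        out[f"avg_moving_speed_{key}"] = float(np.mean(mov_speeds))
    return out


def _fmt_threshold(th: float) -> str:
    return f"{th:g}".replace(".", "p")


def displacement_autocorr(
    t: Track, lags: tuple[int, ...] = (1, 2, 5)
) -> dict[str, float]:
    """Directional autocorrelation of the step series per lag.

    ``autocorr_lag{τ}`` is the mean cosine between step vectors τ frames
    apart: 1 for constant-velocity motion, 0 for memoryless steps, −1 for
    strictly alternating (anti-persistent) steps.  The Pearson correlation
    of the step-magnitude series at the same lags is emitted as a
    diagnostic (``autocorr_mag_lag{τ}``); it is NaN for constant-speed
    tracks.  Zero-length steps are excluded pairwise; all-stationary
    tracks give NaN.
    """
    if t.has_gaps:
        raise ValueError("displacement_autocorr requires a gap-free track")
    steps, _ = track_steps(t)
    mags = np.linalg.norm(steps, axis=1)
    out: dict[str, float] = {}
    for lag in lags:
        if lag >= len(steps):
            raise ValueError(f"lag {lag} too large for {len(steps)} steps")
        a, b = steps[:-lag], steps[lag:]
        na, nb = mags[:-lag], mags[lag:]
        ok = (na > 0) & (nb > 0)
        if ok.any():
            cosines = np.sum(a[ok] * b[ok], axis=1) / (na[ok] * nb[ok])
            out[f"autocorr_lag{lag}"] = float(np.clip(cosines.mean(), -1.0, 1.0))
        else:
            out[f"autocorr_lag{lag}"] = float("nan")
        if np.ptp(na) > 0 and np.ptp(nb) > 0:
            out[f"autocorr_mag_lag{lag}"] = float(stats.pearsonr(na, nb).statistic)
        else:
            out[f"autocorr_mag_lag{lag}"] = float("nan")
    return out


def trackmate_summary(t: Track) -> dict[str, float]:
    """TrackMate-style track statistics: total distance (μm), total
    displacement (μm), mean straight-line speed (μm/min) and velocity
    (mean step speed, μm/min)."""
    steps, speeds = track_steps(t)
    net = float(np.linalg.norm(t.positions[-1] - t.positions[0]))
    return {
        "tm_total_distance": float(np.linalg.norm(steps, axis=1).sum()),
        "tm_total_displacement": net,
        "tm_mean_straight_line_speed": net / t.duration,
        "tm_velocity": float(speeds.mean()),
    }


def track_features(t: Track, params: FeatureParams = FeatureParams()) -> dict[str, float]:
    """All features of one gap-free track as a flat name → value mapping.

    Lags or sub-track windows longer than the track itself yield NaN (or a
    whole-track window) rather than an error, so short tracks outside the
    filtered pipeline still produce a row.
    """
    feats: dict[str, float] = {}
    feats.update(path_metrics(t))
    feats.update(linearity_metrics(t))
    _, _, slope = msd_profile(t, params.msd_lag_max)
    feats["msd_slope"] = slope
    feats["hurst_rs"] = hurst_rs(t, params.hurst_min_window) if len(t) >= 16 else float("nan")
    try:
        feats["nongauss"] = nongauss_alpha2(t)
    except ValueError:
        feats["nongauss"] = float("nan")
    sub_len = min(params.subtrack_len, len(t))
    feats.update(random_walk_deltas(t, params.rw_n_sim, params.rw_seed, sub_len))
    feats.update(movement_occupancy(t, params.move_thresholds, sub_len))
    n_steps = len(t) - 1
    ok_lags = tuple(l for l in params.autocorr_lags if l < n_steps)
    feats.update(displacement_autocorr(t, ok_lags))
    for l in params.autocorr_lags:
        if l >= n_steps:
            feats[f"autocorr_lag{l}"] = float("nan")
            feats[f"autocorr_mag_lag{l}"] = float("nan")
    feats.update(trackmate_summary(t))
    return feats


def feature_table(ts: TrackSet, params: FeatureParams = FeatureParams()) -> pd.DataFrame:
    """One row of features per track, with the condition label.

    Tracks with frame gaps are linearly interpolated when every gap is ≤ 2
    frames and excluded (logged) otherwise; undefined features are NaN and
    per-feature missing counts are stored in ``df.attrs["n_missing"]``.
    """
    if len(ts) == 0:
        raise ValueError("cannot build a feature table from an empty TrackSet")
    rows, index, conditions = [], [], []
    n_gap_excluded = 0
    for t in ts:
        filled = fill_gaps(t)
        if filled is None:
            logger.info("track %s excluded: frame gap > 2", t.track_id)
            n_gap_excluded += 1
            continue
        rows.append(track_features(filled, params))
        index.append(t.track_id)
        conditions.append(t.condition)
    if not rows:
        raise ValueError("no gap-free track survived ingestion")
    df = pd.DataFrame(rows, index=pd.Index(index, name="track_id"))
    df.insert(0, "condition", conditions)
    df.attrs["n_missing"] = df.isna().sum().to_dict()
    df.attrs["n_gap_excluded"] = n_gap_excluded
    return df


def feature_columns(df: pd.DataFrame) -> list[str]:
    """Numeric feature columns of a feature table (everything but labels)."""
    return [c for c in df.columns if c != "condition"]
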