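"""The 13 FHR features: FIGO morphology, time/frequency statistics and
non-linear dynamics.

Feature families
----------------
* Morphological (FIGO/NICE): real baseline (RBL), acceleration and
  deceleration counts, short- and long-term variability (STV, LTV).
* Time series: root mean square (RMS) and sample entropy (SampEn).
* Frequency domain: dominant spectral peak (FPeak) of the Welch PSD.
* Non-linear: Poincare plot dispersions SD1/SD2 and their combination
  SDRatio, box-counting fractal dimension, and the detrended fluctuation
  analysis (DFA) scaling exponent.

Conventions used throughout: standard deviations are population (1/N)
unless noted; signals are assumed preprocessed (gapless, finite);
thresholds on accelerations/decelerations are closed (>= +15 bpm,
<= -15 bpm, duration >= 15 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy.spatial import cKDTree

from .records import FHRRecord, ValidationError

__all__ = [
    "BaselineResult",
    "EpisodeResult",
    "VariabilityResult",
    "SampEnConfig",
    "SpectralResult",
    "PoincareResult",
    "FractalResult",
    "FeatureVector",
    "FEATURE_NAMES",
    "compute_baseline",
    "detect_episodes",
    "compute_stv",
    "compute_ltv",
    "compute_rms",
    "compute_sampen",
    "compute_fpeak",
    "compute_poincare",
    "compute_box_dimension",
    "compute_dfa",
    "extract_features",
]

#: fixed feature order for tables and models
FEATURE_NAMES = (
    "rbl", "acc", "dec", "stv", "ltv", "rms", "sampen",
    "fpeak", "sd1", "sd2", "sd_ratio", "box_dim", "dfa_alpha",
)


class DegenerateInputError(ValidationError):
    """The quantity is undefined for this input (e.g. zero-variance signal)."""


def _pop_std(x: np.ndarray) -> float:
    return float(np.std(x))  # ddof=0: population convention


# ---------------------------------------------------------------------------
# Morphological (FIGO) features
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BaselineResult:
    """Virtual baseline mean, real baseline and the clipped signal.

    The virtual baseline mean (VBM) is the plain arithmetic mean. Samples
    further than +-10 bpm from it — acceleration/deceleration excursions —
    are clipped to the +-10 band, and the real baseline (RBL) is the mean
    of the clipped series.
    """

    vbm: float
    rbl: float
    clipped_signal: np.ndarray


def compute_baseline(signal: np.ndarray) -> BaselineResult:
    x = np.asarray(signal, dtype=float)
    if x.size < 1:
        raise ValidationError("empty signal")
    if not np.isfinite(x).all():
        raise ValidationError("signal contains non-finite samples; preprocess first")
    vbm = float(np.mean(x))
    clipped = np.clip(x, vbm - 10.0, vbm + 10.0)
    return BaselineResult(vbm=vbm, rbl=float(np.mean(clipped)), clipped_signal=clipped)


@dataclass(frozen=True)
class EpisodeResult:
    """Counts and index spans of accelerations/decelerations."""

    acc_total: int
    dec_total: int
    episodes: list  # (start_index, end_index_exclusive, kind)


def _runs(mask: np.ndarray):
    """Maximal contiguous True runs as (start, stop) index pairs."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def detect_episodes(signal: np.ndarray, rbl: float, fs: float) -> EpisodeResult:
    """Count accelerations (runs >= RBL+15 bpm) and decelerations
    (runs <= RBL-15 bpm) lasting at least 15 s. Thresholds and the
    duration bound are closed (ties count)."""
    x = np.asarray(signal, dtype=float)
    if fs <= 0:
        raise ValidationError("fs must be positive")
    if not np.isfinite(rbl):
        raise ValidationError("rbl must be finite")
    min_samples = 15.0 * fs
    episodes = []
    for kind, mask in (("acc", x >= rbl + 15.0), ("dec", x <= rbl - 15.0)):
        for start, stop in _runs(mask):
            if stop - start >= min_samples:
                episodes.append((int(start), int(stop), kind))
    episodes.sort()
    return EpisodeResult(
        acc_total=sum(1 for e in episodes if e[2] == "acc"),
        dec_total=sum(1 for e in episodes if e[2] == "dec"),
        episodes=episodes,
    )


@dataclass(frozen=True)
class VariabilityResult:
    stv: float
    ltv: float
    per_minute_stv: list


def compute_stv(signal: np.ndarray, fs: float = 4.0) -> VariabilityResult:
    """Short-term variability: per whole minute, the mean absolute
    difference of successive 2.5-s subinterval means; STV is the average
    over minutes. The trailing partial minute is discarded.

    Also returns LTV (see :func:`compute_ltv`) so both per-minute measures
    share one result object when convenient.
    """
    x = np.asarray(signal, dtype=float)
    spm = int(round(60.0 * fs))          # samples per minute
    sub = int(round(2.5 * fs))           # samples per 2.5-s subinterval
    n_min = x.size // spm
    if n_min < 1:
        raise ValidationError("signal shorter than one minute")
    per_minute = []
    h = spm // sub                       # subintervals per minute
    for t in range(n_min):
        block = x[t * spm : (t + 1) * spm]
        means = block[: h * sub].reshape(h, sub).mean(axis=1)
        per_minute.append(float(np.mean(np.abs(np.diff(means)))))
    ltv = compute_ltv(x, fs)
    return VariabilityResult(stv=float(np.mean(per_minute)), ltv=ltv, per_minute_stv=per_minute)


def compute_ltv(signal: np.ndarray, fs: float = 4.0) -> float:
    """Long-term variability: mean over non-overlapping 60-s blocks of the
    block's max-min range; trailing partial block discarded."""
    x = np.asarray(signal, dtype=float)
    b = int(round(60.0 * fs))
    n_blocks = x.size // b
    if n_blocks < 1:
        raise ValidationError("signal shorter than one minute")
    blocks = x[: n_blocks * b].reshape(n_blocks, b)
    return float(np.mean(blocks.max(axis=1) - blocks.min(axis=1)))


# ---------------------------------------------------------------------------
# Time-series features
# ---------------------------------------------------------------------------

def compute_rms(signal: np.ndarray) -> float:
    x = np.asarray(signal, dtype=float)
    if x.size < 1:
        raise ValidationError("empty signal")
    return float(np.sqrt(np.mean(x ** 2)))


@dataclass(frozen=True)
class SampEnConfig:
    """Sample entropy parameters: template length ``m`` and tolerance
    ``r = r_factor * SD(signal)`` (field-standard m=2, r=0.2*SD)."""

    m: int = 2
    r_factor: float = 0.2

    def validate(self) -> None:
        if self.m < 1:
            raise ValidationError(f"m must be >= 1, got {self.m}")
        if self.r_factor <= 0:
            raise ValidationError(f"r_factor must be positive, got {self.r_factor}")


def compute_sampen(signal: np.ndarray, cfg: SampEnConfig | None = None) -> float:
    """Sample entropy: -ln(A/B) where B (resp. A) counts template pairs of
    length m (resp. m+1) within Chebyshev distance r, self-matches
    excluded. A constant signal has entropy 0 by convention; B = 0 (no
    length-m matches at all) is a degenerate input.

    Pair counting uses a k-d tree, so full-length 4 Hz records are
    tractable; the per-template normalisations cancel in the ratio.
    """
    cfg = cfg or SampEnConfig()
    cfg.validate()
    x = np.asarray(signal, dtype=float)
    m = cfg.m
    if x.size <= m + 1:
        raise ValidationError(f"need more than m+1={m + 1} samples, got {x.size}")
    sd = _pop_std(x)
    if sd == 0.0:
        return 0.0
    r = cfg.r_factor * sd

    def pair_count(k: int) -> int:
        # templates y_i = (x_i, ..., x_{i+k-1}); count unordered pairs within r
        templates = np.lib.stride_tricks.sliding_window_view(x, k)[: x.size - m]
        tree = cKDTree(templates)
        total = tree.count_neighbors(tree, r, p=np.inf)
        return int(total - len(templates)) // 2  # drop self-pairs, unorder

    b = pair_count(m)
    a = pair_count(m + 1)
    if b == 0:
        raise DegenerateInputError("no length-m template matches; SampEn undefined")
    if a == 0:
        raise DegenerateInputError("no length-(m+1) template matches; SampEn infinite")
    return float(-np.log(a / b))


# ---------------------------------------------------------------------------
# Frequency-domain feature
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectralResult:
    frequencies: np.ndarray
    psd: np.ndarray
    fpeak: float


@dataclass(frozen=True)
class WelchConfig:
    """Welch PSD settings: Hamming window, 64-s segments at 4 Hz, 50%
    overlap, mean removed so the peak search excludes DC."""

    nperseg: int = 256
    overlap: float = 0.5
    window: str = "hamming"


def compute_fpeak(
    signal: np.ndarray, fs: float = 4.0, welch_config: WelchConfig | None = None
) -> SpectralResult:
    cfg = welch_config or WelchConfig()
    x = np.asarray(signal, dtype=float)
    if x.size < cfg.nperseg:
        raise ValidationError(
            f"signal ({x.size} samples) shorter than one Welch segment ({cfg.nperseg})"
        )
    f, pxx = sps.welch(
        x - np.mean(x),
        fs=fs,
        window=cfg.window,
        nperseg=cfg.nperseg,
        noverlap=int(cfg.nperseg * cfg.overlap),
        detrend="constant",
    )
    # exclude the DC bin from the peak search
    idx = 1 + int(np.argmax(pxx[1:]))
    return SpectralResult(frequencies=f, psd=pxx, fpeak=float(f[idx]))


# ---------------------------------------------------------------------------
# Non-linear features
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PoincareResult:
    """Poincare plot dispersions of the beat-interval series.

    SD1 is the spread perpendicular to the identity line (short-term,
    beat-to-beat variability); SD2 the spread along it (long-term).
    ``sd_ratio`` is the printed combination pi*SD1*SD2 (an ellipse area);
    the plain SD1/SD2 quotient is exposed separately as ``sd_quotient``.
    """

    sd1: float
    sd2: float
    sd_ratio: float
    sdnn: float
    sdsd: float
    sd_quotient: float


def compute_poincare(signal: np.ndarray, mode: str = "nn") -> PoincareResult:
    """Poincare dispersions. ``mode="nn"`` (default) converts FHR in bpm to
    beat intervals NN = 60/FHR seconds; ``mode="raw"`` treats the samples
    themselves as the interval series. Population SDs throughout.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 3:
        raise ValidationError("need >= 3 samples")
    if mode == "nn":
        if np.any(x <= 0):
            raise ValidationError("FHR must be positive to derive beat intervals")
        nn = 60.0 / x
    elif mode == "raw":
        nn = x
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    if np.ptp(nn) == 0.0:  # constant series: exact zeros, not float dust
        return PoincareResult(sd1=0.0, sd2=0.0, sd_ratio=0.0, sdnn=0.0, sdsd=0.0,
                              sd_quotient=0.0)
    d = np.diff(nn)
    sdsd = _pop_std(d)
    sdnn = _pop_std(nn)
    sd1 = float(np.sqrt(0.5) * sdsd)
    sd2_sq = 2.0 * sdnn ** 2 - 0.5 * sdsd ** 2
    sd2 = float(np.sqrt(max(sd2_sq, 0.0)))
    quotient = sd1 / sd2 if sd2 > 0 else float("nan") if sd1 > 0 else 0.0
    return PoincareResult(
        sd1=sd1,
        sd2=sd2,
        sd_ratio=float(np.pi * sd1 * sd2),
        sdnn=sdnn,
        sdsd=sdsd,
        sd_quotient=quotient,
    )


def poincare_autocovariance(signal: np.ndarray, mode: str = "nn") -> tuple[float, float]:
    """Lag-0 and lag-1 autocovariance of the interval series, computed over
    the N-1 Poincare pairs so that SD1^2 = Y(0) - Y(1) holds exactly:
    Y(0) = (var(a) + var(b)) / 2 and Y(1) = cov(a, b) with a, b the first
    and second coordinates of the pairs (population convention)."""
    x = np.asarray(signal, dtype=float)
    nn = 60.0 / x if mode == "nn" else x
    a, b = nn[:-1], nn[1:]
    y0 = 0.5 * (np.var(a) + np.var(b))
    y1 = float(np.mean((a - a.mean()) * (b - b.mean())))
    return float(y0), y1


@dataclass(frozen=True)
class FractalResult:
    box_dim: float
    dfa_alpha: float
    fit_points: list  # (scale, measure) pairs of the log-log fit


def compute_box_dimension(signal: np.ndarray, return_fit: bool = False,
                          min_samples_per_column: int = 32):
    """Box-counting dimension of the signal graph.

    The graph is normalised to the unit square and covered with dyadic
    grids of side r = 2^-k for k = 1..K; in each column of width r the
    boxes spanned by the sample range are counted, and D is the
    least-squares slope of log N(r) against log(1/r). The finest grid is
    capped so every column keeps at least ``min_samples_per_column``
    samples: below the sampling resolution the sampled polyline is
    trivially one-dimensional and the slope is biased toward 1. A
    constant signal is a line, D = 1, by convention.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 16 * min_samples_per_column:
        raise ValidationError(
            f"need >= {16 * min_samples_per_column} samples for a box-counting estimate"
        )
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        return (1.0, []) if return_fit else 1.0
    y = (x - lo) / (hi - lo)
    t = np.linspace(0.0, 1.0, x.size)
    k_max = int(np.floor(np.log2(x.size / min_samples_per_column)))
    fit = []
    for k in range(1, k_max + 1):
        n_cols = 2 ** k
        r = 1.0 / n_cols
        col = np.minimum((t * n_cols).astype(int), n_cols - 1)
        # columns are contiguous sample ranges (uniform time grid), and
        # K <= log2(N) - 2 guarantees every column is non-empty
        starts = np.searchsorted(col, np.arange(n_cols), side="left")
        col_min = np.minimum.reduceat(y, starts)
        col_max = np.maximum.reduceat(y, starts)
        lo_box = np.floor(col_min / r).astype(int)
        hi_box = np.minimum(np.floor(col_max / r).astype(int), n_cols - 1)
        fit.append((r, int(np.sum(hi_box - lo_box + 1))))
    logs = np.log([1.0 / r for r, _ in fit])
    logn = np.log([n for _, n in fit])
    slope = float(np.polyfit(logs, logn, 1)[0])
    return (slope, fit) if return_fit else slope


def default_dfa_scales(n: int, n_scales: int = 10) -> np.ndarray:
    """Log-spaced integer window sizes in [4, n/4]."""
    hi = n // 4
    if hi < 4:
        raise ValidationError("signal too short for DFA")
    scales = np.unique(np.round(np.geomspace(4, hi, n_scales)).astype(int))
    return scales


def compute_dfa(signal: np.ndarray, scales: Sequence[int] | None = None,
                return_fit: bool = False):
    """DFA scaling exponent alpha.

    The mean-removed signal is integrated; for each window size n the
    integrated profile is split into non-overlapping windows, a linear
    trend is removed per window, and F(n) is the RMS residual. Alpha is
    the least-squares slope of log F(n) vs log n (white noise ~0.5, 1/f
    ~1.0, Brownian ~1.5).
    """
    x = np.asarray(signal, dtype=float)
    scales = np.asarray(scales if scales is not None else default_dfa_scales(x.size), dtype=int)
    if scales.size < 4:
        raise ValidationError("need >= 4 DFA scales")
    if scales.min() < 4 or scales.max() > x.size // 4:
        raise ValidationError("DFA scales must lie in [4, N/4]")
    y = np.cumsum(x - np.mean(x))
    fit = []
    for n in scales:
        n_win = y.size // n
        segs = y[: n_win * n].reshape(n_win, n)
        t = np.arange(n, dtype=float)
        # vectorised per-window linear detrend
        t_mean = t.mean()
        t_var = np.mean((t - t_mean) ** 2)
        seg_mean = segs.mean(axis=1, keepdims=True)
        slope = ((segs - seg_mean) * (t - t_mean)).mean(axis=1, keepdims=True) / t_var
        resid = segs - seg_mean - slope * (t - t_mean)
        fit.append((int(n), float(np.sqrt(np.mean(resid ** 2)))))
    if all(f == 0.0 for _, f in fit):
        raise DegenerateInputError("zero fluctuation at every scale; DFA undefined")
    logn = np.log([n for n, _ in fit])
    logf = np.log([max(f, 1e-300) for _, f in fit])
    alpha = float(np.polyfit(logn, logf, 1)[0])
    return (alpha, fit) if return_fit else alpha


# ---------------------------------------------------------------------------
# The assembled 13-feature vector
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureVector:
    """The 13 features of one record, in fixed order (:data:`FEATURE_NAMES`)."""

    rbl: float
    acc: float
    dec: float
    stv: float
    ltv: float
    rms: float
    sampen: float
    fpeak: float
    sd1: float
    sd2: float
    sd_ratio: float
    box_dim: float
    dfa_alpha: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)

    def to_dict(self) -> dict:
        return {name: float(getattr(self, name)) for name in FEATURE_NAMES}


@dataclass(frozen=True)
class FeatureConfig:
    """Per-feature settings used by :func:`extract_features`."""

    sampen: SampEnConfig = field(default_factory=SampEnConfig)
    welch: WelchConfig = field(default_factory=WelchConfig)
    poincare_mode: str = "nn"
    dfa_scales: tuple | None = None


def extract_features(record: FHRRecord, config: FeatureConfig | None = None) -> FeatureVector:
    """All 13 features from a preprocessed record. Deterministic; raises a
    validation error naming the feature if any value comes out non-finite."""
    cfg = config or FeatureConfig()
    x = record.signal
    if not np.isfinite(x).all():
        raise ValidationError(
            f"record {record.record_id}: signal has missing samples; preprocess first"
        )
    baseline = compute_baseline(x)
    episodes = detect_episodes(x, baseline.rbl, record.fs)
    variability = compute_stv(x, record.fs)
    poincare = compute_poincare(x, mode=cfg.poincare_mode)
    vec = FeatureVector(
        rbl=baseline.rbl,
        acc=float(episodes.acc_total),
        dec=float(episodes.dec_total),
        stv=variability.stv,
        ltv=variability.ltv,
        rms=compute_rms(x),
        sampen=compute_sampen(x, cfg.sampen),
        fpeak=compute_fpeak(x, record.fs, cfg.welch).fpeak,
        sd1=poincare.sd1,
        sd2=poincare.sd2,
        sd_ratio=poincare.sd_ratio,
        box_dim=compute_box_dimension(x),
        dfa_alpha=compute_dfa(x, cfg.dfa_scales),
    )
    for name in FEATURE_NAMES:
        if not np.isfinite(getattr(vec, name)):
            raise ValidationError(f"record {record.record_id}: feature {name!r} is non-finite")
    return vec
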