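"""ECG preprocessing: denoising, heartbeat relocation, and rasterization.

A raw single-channel ECG excerpt is cleaned (50 Hz notch + 0.5-50 Hz
band-pass, both zero-phase), z-scored, and then *relocated*: the excerpt is
re-cut so that it starts at the midpoint between the first detected R wave
and the R wave preceding it, and ends at the midpoint between the last R
wave and the one following it.  The inter-beat distances ``T1`` and ``T2``
at the two boundaries are estimated from the short-term autocorrelation of
the 2 s of signal adjacent to the boundary R wave, center-clipped with
thresholds ``alpha`` / ``beta`` so that only harmonic peaks survive.  The
relocated heartbeat segment is finally drawn as a fixed-size grayscale
image (amplitude vs. time) that downstream 2D networks consume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .errors import (
    ContextTooShort,
    DegenerateInput,
    EmptyResult,
    InvalidConfiguration,
    PeriodNotFound,
)

__all__ = [
    "ECGRecord",
    "RPeakList",
    "AutocorrResult",
    "HeartbeatSegment",
    "ECGImage",
    "apply_notch",
    "apply_bandpass",
    "standardize",
    "detect_r_peaks",
    "short_time_autocorr",
    "clip_autocorr",
    "estimate_rr_interval",
    "relocate_heartbeat",
    "render_ecg_image",
    "preprocess_ecg",
    "read_ecg_csv",
]

#: Default image geometry fed to the 2D network (width x height).
DEFAULT_IMAGE_WIDTH = 307
DEFAULT_IMAGE_HEIGHT = 230

#: Autocorrelation window adjacent to a boundary R wave, seconds.
ACF_WINDOW_S = 2.0

#: Center-clipping thresholds applied to the normalized autocorrelation.
CLIP_ALPHA = 0.1
CLIP_BETA = -0.1


@dataclass(frozen=True)
class ECGRecord:
    """A single-channel ECG series with its sampling rate."""

    samples: np.ndarray
    fs: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise InvalidConfiguration(f"sampling rate must be positive, got {self.fs}")
        if samples.ndim != 1:
            raise InvalidConfiguration("ECG record must be a 1-D series")
        if not np.all(np.isfinite(samples)):
            raise DegenerateInput("ECG record contains non-finite samples")

    def __len__(self) -> int:
        return self.samples.size

    def replace_samples(self, samples: np.ndarray) -> "ECGRecord":
        return ECGRecord(samples=samples, fs=self.fs, sample_id=self.sample_id)


@dataclass(frozen=True)
class RPeakList:
    """Detected R-wave sample positions, strictly increasing."""

    indices: np.ndarray
    threshold_used: float

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        object.__setattr__(self, "indices", idx)
        if idx.size and np.any(np.diff(idx) <= 0):
            raise InvalidConfiguration("R-peak indices must be strictly increasing")

    def __len__(self) -> int:
        return self.indices.size


@dataclass(frozen=True)
class AutocorrResult:
    """Normalized short-term autocorrelation, its clipped form and period."""

    acf: np.ndarray
    clipped: np.ndarray
    period_samples: int


@dataclass(frozen=True)
class HeartbeatSegment:
    """A relocated excerpt of a parent :class:`ECGRecord`."""

    samples: np.ndarray
    start_index: int
    end_index: int
    fs: float
    sample_id: str = ""
    r_peaks: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class ECGImage:
    """Grayscale rasterization of a heartbeat segment, intensities in [0, 1]."""

    pixels: np.ndarray  # (height, width)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


# ---------------------------------------------------------------------------
# Denoising
# ---------------------------------------------------------------------------

def apply_notch(record: ECGRecord, f0: float = 50.0, q: float = 30.0) -> ECGRecord:
    """Remove mains interference with a zero-phase IIR notch at ``f0`` Hz."""
    if record.fs <= 2 * f0:
        raise InvalidConfiguration(
            f"notch frequency {f0} Hz requires fs > {2 * f0} Hz, got {record.fs}"
        )
    b, a = signal.iirnotch(f0, q, fs=record.fs)
    out = signal.filtfilt(b, a, record.samples)
    return record.replace_samples(out)


def apply_bandpass(
    record: ECGRecord, low: float = 0.5, high: float = 50.0, order: int = 4
) -> ECGRecord:
    """Zero-phase Butterworth band-pass; default band 0.5-50 Hz suppresses
    baseline wander, electrode drift and muscle noise."""
    if not (0 < low < high < record.fs / 2):
        raise InvalidConfiguration(
            f"band ({low}, {high}) Hz invalid for fs={record.fs} Hz"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=record.fs, output="sos")
    out = signal.sosfiltfilt(sos, record.samples)
    return record.replace_samples(out)


def standardize(record: ECGRecord) -> ECGRecord:
    """Z-score the series (mean 0, sd 1) to remove amplitude scaling."""
    x = record.samples
    sd = float(np.std(x))
    if sd == 0.0:
        raise DegenerateInput("cannot standardize a constant series")
    return record.replace_samples((x - np.mean(x)) / sd)


# ---------------------------------------------------------------------------
# R-peak detection
# ---------------------------------------------------------------------------

def detect_r_peaks(
    record: ECGRecord,
    window_s: float = 0.6,
    threshold_frac: float = 0.5,
    refractory_s: float = 0.25,
) -> RPeakList:
    """Locate R waves as local maxima above a global-relative threshold.

    A sample is an R peak when it is the maximum within a centered
    ``window_s`` window and exceeds ``threshold_frac`` times the global
    maximum.  Peaks closer than ``refractory_s`` (physiologically
    impossible double beats) are deduplicated keeping the larger one.
    """
    x = record.samples
    if x.size == 0:
        raise EmptyResult("empty record")
    threshold = threshold_frac * float(np.max(x))
    win = max(3, int(round(window_s * record.fs)) | 1)  # odd-sized window
    local_max = ndimage.maximum_filter1d(x, size=win, mode="nearest")
    candidates = np.flatnonzero((x >= local_max) & (x > threshold))
    if candidates.size == 0:
        raise EmptyResult(
            f"no sample exceeded threshold {threshold:.4g} "
            f"(threshold_frac={threshold_frac}, max={np.max(x):.4g})"
        )
    # plateau handling: collapse runs of equal maxima to their first sample
    keep = np.ones(candidates.size, dtype=bool)
    keep[1:] = np.diff(candidates) > 1
    candidates = candidates[keep]
    # refractory deduplication, greedy by amplitude
    refractory = int(round(refractory_s * record.fs))
    order = np.argsort(-x[candidates], kind="stable")
    accepted: list[int] = []
    for i in order:
        c = int(candidates[i])
        if all(abs(c - a) > refractory for a in accepted):
            accepted.append(c)
    accepted.sort()
    return RPeakList(indices=np.asarray(accepted, dtype=int), threshold_used=threshold)


# ---------------------------------------------------------------------------
# Short-term autocorrelation and period estimation
# ---------------------------------------------------------------------------

def short_time_autocorr(segment: np.ndarray, max_lag: int) -> np.ndarray:
    """Normalized short-term autocorrelation over lags ``0..max_lag``.

    ``acf[k] = sum_n x[n] x[n+k]`` over the window, divided by ``acf[0]``
    so the clipping thresholds are scale-free.
    """
    x = np.asarray(segment, dtype=float)
    if max_lag >= x.size:
        raise InvalidConfiguration(
            f"max_lag {max_lag} must be smaller than segment length {x.size}"
        )
    full = signal.correlate(x, x, mode="full")
    acf = full[x.size - 1 : x.size + max_lag]
    if acf[0] == 0.0:
        raise DegenerateInput("zero-energy segment has no autocorrelation")
    return acf / acf[0]


def clip_autocorr(
    acf: np.ndarray, alpha: float = CLIP_ALPHA, beta: float = CLIP_BETA
) -> np.ndarray:
    """Center-clip: shrink values above ``alpha`` by ``alpha``, below
    ``beta`` by ``beta``, zero everything in between."""
    if alpha <= beta:
        raise InvalidConfiguration(f"alpha ({alpha}) must exceed beta ({beta})")
    x = np.asarray(acf, dtype=float)
    out = np.zeros_like(x)
    hi = x > alpha
    lo = x < beta
    out[hi] = x[hi] - alpha
    out[lo] = x[lo] - beta
    return out


def estimate_rr_interval(acres: AutocorrResult | np.ndarray) -> int:
    """Lag of the maximum of the first harmonic of the clipped ACF.

    The zero-lag run (the clipped ACF is 1 - alpha at lag 0) is skipped;
    among the surviving lags, the global maximum marks the first
    harmonic.  (For a periodic signal the short-term ACF decays with
    lag, so the fundamental peak dominates its own multiples; satellite
    runs from intra-beat morphology — P and T waves cross-correlating
    with the R spike — survive clipping but stay well below the
    beat-to-beat peak, which is why the first *surviving run* is not a
    reliable reading of "first harmonic".)
    """
    clipped = acres.clipped if isinstance(acres, AutocorrResult) else np.asarray(acres)
    nonzero = clipped != 0.0
    k = 0
    while k < nonzero.size and nonzero[k]:  # skip the lag-0 run
        k += 1
    if k >= nonzero.size or not np.any(nonzero[k:]):
        raise PeriodNotFound("no nonzero harmonic after lag 0 in clipped ACF")
    period = k + int(np.argmax(clipped[k:]))
    return period


def _boundary_period(
    record: ECGRecord, peak: int, side: str, window_s: float = ACF_WINDOW_S
) -> tuple[int, AutocorrResult]:
    """Inter-beat period at a boundary R wave from its adjacent window."""
    n = int(round(window_s * record.fs))
    if side == "leading":
        if peak - n < 0:
            raise ContextTooShort(
                f"need {n} samples before R wave at {peak}, have {peak}"
            )
        window = record.samples[peak - n : peak + 1][::-1]
    elif side == "trailing":
        if peak + n >= len(record):
            raise ContextTooShort(
                f"need {n} samples after R wave at {peak}, have {len(record) - peak - 1}"
            )
        window = record.samples[peak : peak + n + 1]
    else:  # pragma: no cover - internal
        raise ValueError(side)
    acf = short_time_autocorr(window, max_lag=n - 1)
    clipped = clip_autocorr(acf)
    period = estimate_rr_interval(clipped)
    return period, AutocorrResult(acf=acf, clipped=clipped, period_samples=period)


def relocate_heartbeat(
    record: ECGRecord, peaks: RPeakList, window_s: float = ACF_WINDOW_S
) -> HeartbeatSegment:
    """Re-cut the record at inter-beat midpoints around the detected peaks.

    ``start = R_1 - T1 // 2`` with ``T1`` estimated from the reversed
    ``window_s`` of signal preceding ``R_1``; ``end = R_N + T2 // 2`` with
    ``T2`` from the window following ``R_N``.  Midpoints are floored.
    """
    if len(peaks) == 0:
        raise EmptyResult("no R peaks to relocate around")
    r1 = int(peaks.indices[0])
    rn = int(peaks.indices[-1])
    t1, _ = _boundary_period(record, r1, "leading", window_s)
    t2, _ = _boundary_period(record, rn, "trailing", window_s)
    start = r1 - t1 // 2
    end = rn + t2 // 2
    start = max(start, 0)
    end = min(end, len(record) - 1)
    return HeartbeatSegment(
        samples=record.samples[start : end + 1],
        start_index=start,
        end_index=end,
        fs=record.fs,
        sample_id=record.sample_id,
        r_peaks=peaks.indices.copy(),
    )


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def render_ecg_image(
    segment: HeartbeatSegment | np.ndarray,
    width: int = DEFAULT_IMAGE_WIDTH,
    height: int = DEFAULT_IMAGE_HEIGHT,
) -> ECGImage:
    """Draw the amplitude-vs-time trace into an (height, width) matrix.

    Deterministic column-span rendering: every pair of adjacent samples
    fills the vertical pixel span it covers, so the trace is gap-free.
    Amplitude is min-max scaled per segment; a constant segment maps to
    the middle row.  Row 0 is the image top (largest amplitude).
    """
    x = segment.samples if isinstance(segment, HeartbeatSegment) else np.asarray(segment)
    if x.size == 0:
        raise DegenerateInput("cannot render an empty segment")
    if width < 2 or height < 2:
        raise InvalidConfiguration("image must be at least 2x2")
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi > lo:
        rows = (height - 1) - np.round((x - lo) / (hi - lo) * (height - 1)).astype(int)
    else:
        rows = np.full(x.size, (height - 1) // 2, dtype=int)
    if x.size == 1:
        cols = np.zeros(1, dtype=int)
    else:
        cols = np.round(np.arange(x.size) / (x.size - 1) * (width - 1)).astype(int)
    pixels = np.zeros((height, width))
    # per-column extremes of the trace, then bridge adjacent columns
    top = np.full(width, height, dtype=int)
    bot = np.full(width, -1, dtype=int)
    np.minimum.at(top, cols, rows)
    np.maximum.at(bot, cols, rows)
    # bridge column boundaries so steep strokes leave no gaps
    boundary = np.flatnonzero(np.diff(cols) > 0)
    for i in boundary:
        lo_r = min(rows[i], rows[i + 1])
        hi_r = max(rows[i], rows[i + 1])
        for c in range(cols[i], cols[i + 1] + 1):
            top[c] = min(top[c], lo_r)
            bot[c] = max(bot[c], hi_r)
    for c in range(width):
        if bot[c] >= 0:
            pixels[top[c] : bot[c] + 1, c] = 1.0
    return ECGImage(pixels=pixels)


# ---------------------------------------------------------------------------
# Pipeline + I/O
# ---------------------------------------------------------------------------

def preprocess_ecg(
    record: ECGRecord,
    notch_hz: float = 50.0,
    band: tuple[float, float] = (0.5, 50.0),
    width: int = DEFAULT_IMAGE_WIDTH,
    height: int = DEFAULT_IMAGE_HEIGHT,
    threshold_frac: float = 0.5,
) -> tuple[ECGImage, HeartbeatSegment]:
    """Full chain: denoise, standardize, detect R peaks, relocate, render.

    Relocation needs 2 s of recording on each side of the boundary R
    waves, so the excerpt is cut around the first and last detected
    peaks that have that context; peaks outside it still belong to the
    surrounding recording, mirroring acquisition from a continuous
    signal.
    """
    rec = apply_notch(record, notch_hz)
    rec = apply_bandpass(rec, *band)
    rec = standardize(rec)
    peaks = detect_r_peaks(rec, threshold_frac=threshold_frac)
    margin = int(round(ACF_WINDOW_S * rec.fs))
    inside = peaks.indices[(peaks.indices >= margin) & (peaks.indices < len(rec) - margin)]
    if inside.size == 0:
        raise ContextTooShort(
            "no detected R wave has 2 s of context on both sides of the record"
        )
    peaks = RPeakList(indices=inside, threshold_used=peaks.threshold_used)
    segment = relocate_heartbeat(rec, peaks)
    image = render_ecg_image(segment, width=width, height=height)
    return image, segment


def read_ecg_csv(path: str | Path, fs: float | None = None) -> ECGRecord:
    """Read a one-column CSV of samples.  The column header may carry the
    sampling rate as ``fs=<Hz>``; an explicit ``fs`` argument overrides it."""
    path = Path(path)
    df = pd.read_csv(path)
    col = df.columns[0]
    if fs is None:
        if "fs=" in col:
            fs = float(col.split("fs=")[1])
        else:
            raise InvalidConfiguration(
                f"{path}: no fs= in header and no explicit sampling rate"
            )
    return ECGRecord(samples=df[col].to_numpy(float), fs=fs, sample_id=path.stem)


def write_segment_meta(segment: HeartbeatSegment, path: str | Path) -> None:
    meta = {
        "sample_id": segment.sample_id,
        "start_index": int(segment.start_index),
        "end_index": int(segment.end_index),
        "fs": float(segment.fs),
        "r_peaks": [int(p) for p in segment.r_peaks],
    }
    Path(path).write_text(json.dumps(meta, indent=2))
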