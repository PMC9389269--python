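"""Voice preprocessing: pre-emphasis, Hamming framing, STFT, Mel spectrogram.

The voice channel enters the classifier as a log-Mel spectrogram image.
The chain is the classical one: first-order pre-emphasis to lift the
spectral tilt, 30 ms Hamming frames with a 15 ms hop, per-frame power
spectrum via the STFT, projection through a triangular Mel filter bank
spanning [0, fs/2], log compression, and min-max rasterization to the
fixed image size the 2D network expects.

All input audio is resampled to 16 kHz so the frame geometry (480-sample
window, 240-sample hop) and the Mel bank are fixed regardless of the
source sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal
from scipy.io import wavfile
from skimage.transform import resize

from .errors import DegenerateInput, InvalidConfiguration

__all__ = [
    "AudioClip",
    "MelSpectrogram",
    "load_wav",
    "resample",
    "pre_emphasize",
    "frame_signal",
    "hz_to_mel",
    "mel_to_hz",
    "mel_filter_bank",
    "band_center_frequencies",
    "compute_mel_spectrogram",
    "render_spectrogram_image",
    "preprocess_voice",
]

TARGET_FS = 16_000
FRAME_MS = 30.0
HOP_MS = 15.0
DEFAULT_N_MELS = 64
LOG_EPS = 1e-10


@dataclass(frozen=True)
class AudioClip:
    """Mono audio in [-1, 1] with its sampling rate."""

    samples: np.ndarray
    fs: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        x = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", x)
        if self.fs <= 0:
            raise InvalidConfiguration("sampling rate must be positive")
        if x.size == 0:
            raise DegenerateInput("empty audio clip")
        if not np.all(np.isfinite(x)):
            raise DegenerateInput("audio clip contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def replace_samples(self, samples: np.ndarray, fs: int | None = None) -> "AudioClip":
        return AudioClip(samples, self.fs if fs is None else fs, self.sample_id)


@dataclass(frozen=True)
class MelSpectrogram:
    """Log-compressed Mel energies, shape (n_frames, n_mels)."""

    energies: np.ndarray
    fs: int
    n_mels: int
    frame_length_ms: float = FRAME_MS
    hop_ms: float = HOP_MS

    @property
    def n_frames(self) -> int:
        return self.energies.shape[0]


def load_wav(path: str | Path, target_fs: int | None = TARGET_FS) -> AudioClip:
    """Read a PCM or float WAV, scale to [-1, 1], average multi-channel to
    mono, and optionally resample."""
    path = Path(path)
    fs, data = wavfile.read(path)
    x = np.asarray(data)
    if x.ndim == 2:
        x = x.mean(axis=1)
    if np.issubdtype(x.dtype, np.integer):
        x = x / float(np.iinfo(data.dtype).max)
    else:
        x = x.astype(float)
    clip = AudioClip(samples=x, fs=int(fs), sample_id=path.stem)
    if target_fs is not None and clip.fs != target_fs:
        clip = resample(clip, target_fs)
    return clip


def save_wav(clip: AudioClip, path: str | Path) -> None:
    x = np.clip(clip.samples, -1.0, 1.0)
    wavfile.write(Path(path), clip.fs, (x * 32767).astype(np.int16))


def resample(clip: AudioClip, target_fs: int) -> AudioClip:
    """Polyphase resampling to ``target_fs``."""
    if target_fs <= 0:
        raise InvalidConfiguration("target sampling rate must be positive")
    if target_fs == clip.fs:
        return clip
    from math import gcd

    g = gcd(target_fs, clip.fs)
    out = signal.resample_poly(clip.samples, target_fs // g, clip.fs // g)
    return clip.replace_samples(out, fs=target_fs)


def pre_emphasize(clip: AudioClip, coeff: float = 0.97) -> AudioClip:
    """First-order high-pass: ``y[n] = x[n] - coeff * x[n-1]``, ``y[0] = x[0]``."""
    if not (0.0 <= coeff < 1.0):
        raise InvalidConfiguration(f"pre-emphasis coefficient must be in [0, 1), got {coeff}")
    x = clip.samples
    y = np.empty_like(x)
    y[0] = x[0]
    y[1:] = x[1:] - coeff * x[:-1]
    return clip.replace_samples(y)


def _frame_geometry(fs: int) -> tuple[int, int]:
    return int(round(FRAME_MS / 1000.0 * fs)), int(round(HOP_MS / 1000.0 * fs))


def frame_signal(clip: AudioClip) -> np.ndarray:
    """Split into 30 ms Hamming-windowed frames with a 15 ms hop.

    Returns an (n_frames, frame_len) matrix; the last partial frame is
    dropped, so ``n_frames = (len - frame_len) // hop + 1``.
    """
    flen, hop = _frame_geometry(clip.fs)
    x = clip.samples
    if x.size < flen:
        raise DegenerateInput(
            f"clip of {x.size} samples is shorter than one {flen}-sample frame"
        )
    n_frames = (x.size - flen) // hop + 1
    idx = np.arange(flen)[None, :] + hop * np.arange(n_frames)[:, None]
    window = np.hamming(flen)
    return x[idx] * window[None, :]


def hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    """HTK convention: ``m = 2595 log10(1 + f / 700)``."""
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filter_bank(fs: int, n_fft: int, n_mels: int) -> np.ndarray:
    """Triangular Mel filters over [0, fs/2], shape (n_mels, n_fft//2 + 1)."""
    if n_mels < 2:
        raise InvalidConfiguration("need at least 2 Mel bands")
    n_bins = n_fft // 2 + 1
    fft_freqs = np.arange(n_bins) * fs / n_fft
    mel_edges = np.linspace(hz_to_mel(0.0), hz_to_mel(fs / 2.0), n_mels + 2)
    hz_edges = np.asarray(mel_to_hz(mel_edges))
    bank = np.zeros((n_mels, n_bins))
    for m in range(n_mels):
        left, center, right = hz_edges[m : m + 3]
        up = (fft_freqs - left) / max(center - left, 1e-12)
        down = (right - fft_freqs) / max(right - center, 1e-12)
        bank[m] = np.clip(np.minimum(up, down), 0.0, None)
    return bank


def band_center_frequencies(fs: int, n_mels: int) -> np.ndarray:
    """Center frequency (Hz) of each Mel band."""
    mel_edges = np.linspace(hz_to_mel(0.0), hz_to_mel(fs / 2.0), n_mels + 2)
    return np.asarray(mel_to_hz(mel_edges))[1:-1]


def compute_mel_spectrogram(
    clip: AudioClip,
    n_mels: int = DEFAULT_N_MELS,
    pre_emphasis: float = 0.97,
) -> MelSpectrogram:
    """Pre-emphasize, frame, take per-frame power spectra and project them
    through the Mel bank; log-compress with ``log(1 + E / eps)``."""
    if n_mels < 2:
        raise InvalidConfiguration("need at least 2 Mel bands")
    emphasized = pre_emphasize(clip, pre_emphasis) if pre_emphasis > 0 else clip
    frames = frame_signal(emphasized)
    flen = frames.shape[1]
    spectra = np.abs(np.fft.rfft(frames, axis=1)) ** 2
    bank = mel_filter_bank(clip.fs, flen, n_mels)
    mel_power = spectra @ bank.T
    energies = np.log1p(mel_power / LOG_EPS)
    return MelSpectrogram(energies=energies, fs=clip.fs, n_mels=n_mels)


def render_spectrogram_image(
    ms: MelSpectrogram, width: int = 307, height: int = 230
) -> np.ndarray:
    """Min-max scale and resize to an (height, width) intensity image.

    Time runs left to right; the lowest Mel band is the bottom row.
    """
    e = ms.energies
    if e.size == 0:
        raise DegenerateInput("empty spectrogram")
    lo, hi = float(e.min()), float(e.max())
    scaled = (e - lo) / (hi - lo) if hi > lo else np.zeros_like(e)
    img = np.flipud(scaled.T)  # (n_mels, n_frames), band 0 at the bottom
    out = resize(img, (height, width), order=1, mode="edge", anti_aliasing=False)
    return np.clip(out, 0.0, 1.0)


def preprocess_voice(
    clip: AudioClip,
    n_mels: int = DEFAULT_N_MELS,
    width: int = 307,
    height: int = 230,
) -> tuple[np.ndarray, MelSpectrogram]:
    """Full chain from audio clip to spectrogram image."""
    if clip.fs != TARGET_FS:
        clip = resample(clip, TARGET_FS)
    ms = compute_mel_spectrogram(clip, n_mels=n_mels)
    return render_spectrogram_image(ms, width=width, height=height), ms
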