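"""Seeded synthetic multimodal samples with class-dependent structure.

The study conditions this generator emulates are the physiological
signatures of acute stress: heart rate rises and beat-to-beat
variability grows (ECG), vocal pitch rises and energy shifts to higher
frequency bands (voice), and facial dynamics speed up (video).  Three
stage labels are produced — calm, plus the two stress-inducing stages
(control, experimental) that share stress physiology but differ
slightly — mirroring a label-then-collapse evaluation where both stress
stages count as the positive class.

Every generated sample carries exact ground truth (R-peak positions,
mean R-R interval, fundamental frequency, face boxes), so detector and
estimator accuracy can be scored against construction rather than
against another estimate.  All generators are pure functions of
(config, label, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ecg import ECGRecord
from .errors import InvalidConfiguration
from .faces import StubFaceDetector, VideoClip
from .voice import AudioClip

__all__ = ["SynthConfig", "SynthSample", "gen_ecg", "gen_audio", "gen_video", "gen_dataset"]

CLASSES = ("calm", "control", "experimental")

#: Default class mix mirroring a 531:740 calm:stress study ratio, the two
#: stress stages splitting their share evenly.
DEFAULT_CLASS_PROPORTIONS = {"calm": 531 / 1271, "control": 370 / 1271, "experimental": 370 / 1271}


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters; defaults are the study conditions.

    Heart-rate ranges keep the stress classes strictly above calm; R-R
    jitter is larger under stress; voice fundamentals and high-band tilt
    rise with stress; facial motion frequency rises with stress.
    """

    seed: int = 0
    # --- ECG ---
    ecg_fs: int = 2000
    ecg_duration_s: float = 10.0
    hr_bpm: dict = field(
        default_factory=lambda: {
            "calm": (60.0, 75.0),
            "control": (90.0, 110.0),
            "experimental": (100.0, 120.0),
        }
    )
    rr_jitter_ms: dict = field(
        default_factory=lambda: {"calm": 15.0, "control": 40.0, "experimental": 50.0}
    )
    ecg_snr_db: float = 20.0
    mains_amplitude: float = 0.0  # optional 50 Hz hum, relative to R amplitude
    # --- voice ---
    audio_fs: int = 16_000
    audio_duration_s: float = 2.0
    f0_hz: dict = field(
        default_factory=lambda: {"calm": 120.0, "control": 190.0, "experimental": 230.0}
    )
    energy_tilt: dict = field(
        default_factory=lambda: {"calm": -1.2, "control": -0.6, "experimental": -0.4}
    )
    audio_noise_rms: float = 0.01
    # --- video ---
    video_fps: float = 30.0
    video_frames: int = 90
    frame_size: int = 64
    face_box_frac: float = 0.5
    motion_hz: dict = field(
        default_factory=lambda: {"calm": 0.5, "control": 2.0, "experimental": 3.0}
    )

    def __post_init__(self) -> None:
        calm_hi = self.hr_bpm["calm"][1]
        for cls in ("control", "experimental"):
            lo, hi = self.hr_bpm[cls]
            if lo <= calm_hi:
                raise InvalidConfiguration(
                    f"stress heart-rate range {cls}={self.hr_bpm[cls]} must lie "
                    f"strictly above the calm range {self.hr_bpm['calm']}"
                )
        for cls in CLASSES:
            lo, hi = self.hr_bpm[cls]
            if not (0 < lo <= hi):
                raise InvalidConfiguration(f"empty heart-rate range for {cls}")


@dataclass(frozen=True)
class SynthSample:
    ecg: ECGRecord
    audio: AudioClip
    video: VideoClip
    boxes: np.ndarray  # (n_frames, 4) ground-truth face boxes
    eyes: np.ndarray  # (n_frames, 2, 2) ground-truth eye landmarks (x, y)
    label: str
    truth: dict

    @property
    def binary_label(self) -> str:
        return "calm" if self.label == "calm" else "stress"

    def stub_detector(self, miss_every: int = 0) -> StubFaceDetector:
        eyes = [((le[0], le[1]), (re[0], re[1])) for le, re in self.eyes]
        return StubFaceDetector(
            boxes=[tuple(b) for b in self.boxes], eyes=eyes, miss_every=miss_every
        )


def _beat_template(fs: int) -> tuple[np.ndarray, int]:
    """One synthetic heartbeat: Gaussian R spike flanked by P and T bumps.

    Returns the template and the offset of the R maximum within it.
    """
    t = np.arange(int(0.50 * fs)) / fs  # 500 ms support
    center = 0.25
    r = np.exp(-0.5 * ((t - center) / 0.012) ** 2)
    p = 0.15 * np.exp(-0.5 * ((t - (center - 0.16)) / 0.025) ** 2)
    tw = 0.30 * np.exp(-0.5 * ((t - (center + 0.18)) / 0.040) ** 2)
    template = r + p + tw
    return template, int(round(center * fs))


def gen_ecg(cfg: SynthConfig, label: str, seed: int) -> tuple[ECGRecord, dict]:
    """Synthetic single-channel ECG with exact R-peak ground truth."""
    rng = np.random.default_rng([cfg.seed, seed, 0xEC6])
    fs = cfg.ecg_fs
    n = int(cfg.ecg_duration_s * fs)
    lo, hi = cfg.hr_bpm[label]
    hr = rng.uniform(lo, hi)
    rr_mean = 60.0 / hr * fs  # samples
    jitter_sd = cfg.rr_jitter_ms[label] / 1000.0 * fs
    template, r_offset = _beat_template(fs)
    x = np.zeros(n + 2 * template.size)
    peaks = []
    pos = float(rng.uniform(0.2, 0.8) * rr_mean) + template.size
    while pos < n + template.size:
        start = int(round(pos)) - r_offset
        x[start : start + template.size] += template
        peaks.append(int(round(pos)) - template.size)
        step = rr_mean + rng.normal(0.0, jitter_sd)
        pos += max(step, 0.3 * rr_mean)
    x = x[template.size : template.size + n]
    peaks_arr = np.asarray([p for p in peaks if 0 <= p < n], dtype=int)
    signal_power = float(np.mean(x**2))
    noise_sd = np.sqrt(signal_power / (10 ** (cfg.ecg_snr_db / 10.0)))
    x = x + rng.normal(0.0, noise_sd, size=n)
    if cfg.mains_amplitude > 0:
        x = x + cfg.mains_amplitude * np.sin(2 * np.pi * 50.0 * np.arange(n) / fs)
    record = ECGRecord(samples=x, fs=fs, sample_id=f"ecg-{label}-{seed}")
    truth = {
        "r_peaks": peaks_arr,
        "rr_ms": float(rr_mean / fs * 1000.0),
        "hr_bpm": float(hr),
        "noise_sd": float(noise_sd),
    }
    return record, truth


def gen_audio(cfg: SynthConfig, label: str, seed: int) -> tuple[AudioClip, dict]:
    """Harmonic tone with class-dependent pitch and spectral tilt."""
    rng = np.random.default_rng([cfg.seed, seed, 0xA0D10])
    fs = cfg.audio_fs
    n = int(cfg.audio_duration_s * fs)
    t = np.arange(n) / fs
    f0 = cfg.f0_hz[label] * rng.uniform(0.95, 1.05)
    tilt = cfg.energy_tilt[label]
    x = np.zeros(n)
    k = 1
    while k * f0 < fs / 2 * 0.9 and k <= 20:
        amp = k**tilt
        phase = rng.uniform(0, 2 * np.pi)
        x += amp * np.sin(2 * np.pi * k * f0 * t + phase)
        k += 1
    # syllable-like amplitude modulation
    am = 0.6 + 0.4 * np.sin(2 * np.pi * rng.uniform(2.0, 4.0) * t + rng.uniform(0, 2 * np.pi))
    x *= am
    x /= np.max(np.abs(x))
    x += rng.normal(0.0, cfg.audio_noise_rms, size=n)
    x = np.clip(x / max(1.0, np.max(np.abs(x))), -1.0, 1.0)
    clip = AudioClip(samples=x, fs=fs, sample_id=f"audio-{label}-{seed}")
    return clip, {"f0": float(f0), "tilt": float(tilt)}


def gen_video(cfg: SynthConfig, label: str, seed: int) -> tuple[VideoClip, np.ndarray, np.ndarray, dict]:
    """Frames with a textured face patch oscillating at a class frequency.

    Returns the clip, per-frame boxes, per-frame eye landmarks, and truth.
    """
    rng = np.random.default_rng([cfg.seed, seed, 0x71DE0])
    size = cfg.frame_size
    n = cfg.video_frames
    box_side = int(cfg.face_box_frac * size)
    x0 = int(rng.integers(2, size - box_side - 2))
    y0 = int(rng.integers(2, size - box_side - 2))
    freq = cfg.motion_hz[label]
    background = rng.uniform(0.1, 0.3, size=(size, size, 3))
    yy, xx = np.meshgrid(np.arange(box_side), np.arange(box_side), indexing="ij")
    texture = 0.5 + 0.2 * np.sin(2 * np.pi * xx / 8.0) * np.cos(2 * np.pi * yy / 8.0)
    frames = np.empty((n, size, size, 3))
    phases = 2 * np.pi * freq * np.arange(n) / cfg.video_fps
    phase0 = rng.uniform(0, 2 * np.pi)
    for i in range(n):
        frame = background.copy()
        osc = 0.25 * np.sin(phases[i] + phase0)
        patch = np.clip(texture * (1.0 + osc), 0.0, 1.0)
        frame[y0 : y0 + box_side, x0 : x0 + box_side, :] = patch[..., None]
        frames[i] = frame
    boxes = np.tile([x0, y0, x0 + box_side, y0 + box_side], (n, 1)).astype(float)
    eye_y = y0 + 0.38 * box_side
    eyes = np.tile(
        [[x0 + 0.35 * box_side, eye_y], [x0 + 0.65 * box_side, eye_y]], (n, 1, 1)
    ).astype(float)
    clip = VideoClip(frames=frames, fps=cfg.video_fps, sample_id=f"video-{label}-{seed}")
    return clip, boxes, eyes, {"motion_hz": float(freq), "box": [x0, y0, x0 + box_side, y0 + box_side]}


def gen_sample(cfg: SynthConfig, label: str, seed: int) -> SynthSample:
    ecg, ecg_truth = gen_ecg(cfg, label, seed)
    audio, audio_truth = gen_audio(cfg, label, seed)
    video, boxes, eyes, video_truth = gen_video(cfg, label, seed)
    return SynthSample(
        ecg=ecg,
        audio=audio,
        video=video,
        boxes=boxes,
        eyes=eyes,
        label=label,
        truth={**ecg_truth, **audio_truth, **video_truth},
    )


def class_counts(n_total: int, proportions: dict | None = None) -> dict[str, int]:
    """Integer class counts approximating the default study mix."""
    props = proportions or DEFAULT_CLASS_PROPORTIONS
    counts = {c: int(round(n_total * props[c])) for c in CLASSES}
    drift = n_total - sum(counts.values())
    counts["calm"] += drift
    return counts


def gen_dataset(
    cfg: SynthConfig,
    n_per_class: dict[str, int] | int,
    out_dir: str | Path | None = None,
) -> list[SynthSample]:
    """Generate a labeled multimodal dataset, optionally written to disk.

    ``n_per_class`` may be a per-class mapping or a total count split by
    the default study proportions.  When ``out_dir`` is given, each
    sample is written in the standard formats the preprocessing modules
    read (one-column CSV ECG, 16-bit WAV, PNG frame directory) along
    with ``manifest.csv`` and ``truth.json``.
    """
    if isinstance(n_per_class, int):
        n_per_class = class_counts(n_per_class)
    samples: list[SynthSample] = []
    sample_seed = 0
    for label in CLASSES:
        for _ in range(int(n_per_class.get(label, 0))):
            samples.append(gen_sample(cfg, label, sample_seed))
            sample_seed += 1
    if out_dir is not None:
        _write_dataset(samples, Path(out_dir))
    return samples


def _write_dataset(samples: list[SynthSample], out_dir: Path) -> None:
    import imageio.v3 as iio

    from .voice import save_wav

    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    truth: dict[str, dict] = {}
    for i, s in enumerate(samples):
        sid = f"sample{i:04d}"
        sdir = out_dir / sid
        sdir.mkdir(exist_ok=True)
        pd.DataFrame({f"ecg_mv fs={s.ecg.fs}": s.ecg.samples}).to_csv(
            sdir / "ecg.csv", index=False
        )
        save_wav(s.audio, sdir / "audio.wav")
        frame_dir = sdir / "frames"
        frame_dir.mkdir(exist_ok=True)
        for j, frame in enumerate(s.video.frames):
            iio.imwrite(frame_dir / f"frame{j:04d}.png", (frame * 255).astype(np.uint8))
        rows.append({"sample_id": sid, "label": s.label, "binary": s.binary_label})
        truth[sid] = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in s.truth.items()
        }
    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
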