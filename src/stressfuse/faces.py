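"""Face-frame extraction, alignment, sampling, and geometric augmentation.

Video enters the 3D network as a fixed-length clip of aligned face crops.
Face detection itself is prior art and is kept behind a small interface:
any detector returning a bounding box (and optionally eye landmarks) per
frame can be plugged in, and a deterministic stub detector serves the
synthetic data.  Alignment is a 2-point similarity transform mapping the
eye landmarks onto a fixed canonical template; when only a box is
available the box is cropped and resized instead.

Sampling follows the train/eval split used for video classifiers: a
seeded random contiguous window of ``T`` frames at training time, the
central window at evaluation time; clips shorter than ``T`` are looped
cyclically.  Augmentation rescales every frame to 224x270, crops a
224x224 window shared by all frames (random offset at training, centered
at evaluation), and flips horizontally with probability 1/2 at training
time only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
from skimage.transform import SimilarityTransform, resize, warp

from .errors import DegenerateInput, NoFaceFound

__all__ = [
    "VideoClip",
    "Detection",
    "FaceDetector",
    "StubFaceDetector",
    "FaceClip",
    "extract_faces",
    "sample_training_clip",
    "sample_eval_clip",
    "geometric_augment",
    "load_frame_dir",
]

CLIP_LENGTH = 64
CROP_SIZE = 224
RESCALE_SHAPE = (224, 270)  # (height, width) before the 224x224 crop
CANONICAL_SIZE = 256
# canonical eye positions in the aligned crop, (x, y)
TEMPLATE_LEFT_EYE = (0.35 * CANONICAL_SIZE, 0.38 * CANONICAL_SIZE)
TEMPLATE_RIGHT_EYE = (0.65 * CANONICAL_SIZE, 0.38 * CANONICAL_SIZE)


@dataclass(frozen=True)
class VideoClip:
    """An ordered stack of frames, shape (n, H, W, 3), float in [0, 1]."""

    frames: np.ndarray
    fps: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        f = np.asarray(self.frames, dtype=float)
        object.__setattr__(self, "frames", f)
        if f.ndim != 4 or f.shape[0] < 1 or f.shape[3] != 3:
            raise DegenerateInput(f"expected (n, H, W, 3) frames, got {f.shape}")

    def __len__(self) -> int:
        return self.frames.shape[0]


@dataclass(frozen=True)
class Detection:
    """One face detection: a box within image bounds, optional eye landmarks."""

    box: tuple[float, float, float, float]  # (x0, y0, x1, y1)
    left_eye: tuple[float, float] | None = None
    right_eye: tuple[float, float] | None = None


class FaceDetector(Protocol):
    """Contract for pluggable detectors (e.g. an external MTCNN adapter)."""

    def detect(self, image: np.ndarray) -> Detection | None:
        """Return the dominant face in the frame, or None."""
        ...


@dataclass
class StubFaceDetector:
    """Deterministic detector backed by per-frame ground-truth boxes.

    Used with synthetic videos whose face geometry is known exactly; the
    optional ``miss_every`` drops every k-th detection to exercise the
    fill-forward rule.
    """

    boxes: Sequence[tuple[float, float, float, float]]
    eyes: Sequence[tuple[tuple[float, float], tuple[float, float]]] | None = None
    miss_every: int = 0
    _calls: int = field(default=0, repr=False)

    def detect(self, image: np.ndarray) -> Detection | None:
        i = self._calls % len(self.boxes)
        self._calls += 1
        if self.miss_every and (i + 1) % self.miss_every == 0:
            return None
        box = tuple(self.boxes[i])
        if self.eyes is not None:
            le, re_ = self.eyes[i]
            return Detection(box=box, left_eye=tuple(le), right_eye=tuple(re_))
        return Detection(box=box)


@dataclass(frozen=True)
class FaceClip:
    """A fixed-length stack of aligned face crops, (T, H, W, 3) in [0, 1]."""

    faces: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        f = np.asarray(self.faces, dtype=float)
        object.__setattr__(self, "faces", f)

    def __len__(self) -> int:
        return self.faces.shape[0]


def _align_with_eyes(frame: np.ndarray, det: Detection, size: int) -> np.ndarray:
    src = np.asarray([det.left_eye, det.right_eye], dtype=float)
    dst = np.asarray([TEMPLATE_LEFT_EYE, TEMPLATE_RIGHT_EYE], dtype=float) * (
        size / CANONICAL_SIZE
    )
    tform = SimilarityTransform.from_estimate(dst, src)  # output coords -> input coords
    out = warp(frame, tform, output_shape=(size, size, 3), mode="edge", order=1)
    return out


def _crop_box(frame: np.ndarray, det: Detection, size: int) -> np.ndarray:
    h, w = frame.shape[:2]
    x0, y0, x1, y1 = det.box
    x0, x1 = int(max(0, round(x0))), int(min(w, round(x1)))
    y0, y1 = int(max(0, round(y0))), int(min(h, round(y1)))
    crop = frame[y0:y1, x0:x1]
    if crop.size == 0:
        raise DegenerateInput(f"detection box {det.box} is empty")
    if crop.shape[:2] == (size, size):
        return crop.astype(float)
    return resize(crop, (size, size, 3), order=1, mode="edge", anti_aliasing=False)


def extract_faces(
    clip: VideoClip, detector: FaceDetector, size: int = CANONICAL_SIZE
) -> FaceClip:
    """Detect + align a face crop for every frame.

    Frames with no detection reuse the nearest detected frame's geometry,
    so the output always has one crop per input frame.
    """
    detections: list[Detection | None] = [detector.detect(f) for f in clip.frames]
    detected_idx = [i for i, d in enumerate(detections) if d is not None]
    if not detected_idx:
        raise NoFaceFound(f"no face detected in any of {len(clip)} frames")
    detected_arr = np.asarray(detected_idx)
    crops = np.empty((len(clip), size, size, 3))
    for i, frame in enumerate(clip.frames):
        det = detections[i]
        if det is None:
            nearest = detected_idx[int(np.argmin(np.abs(detected_arr - i)))]
            det = detections[nearest]
        if det.left_eye is not None and det.right_eye is not None:
            crops[i] = _align_with_eyes(frame, det, size)
        else:
            crops[i] = _crop_box(frame, det, size)
    return FaceClip(faces=crops, sample_id=clip.sample_id)


def sample_training_clip(
    faces: FaceClip, T: int = CLIP_LENGTH, seed: int | np.random.Generator = 0
) -> FaceClip:
    """A contiguous T-frame window at a seeded random offset; sequences
    shorter than T are looped cyclically from a random start frame."""
    n = len(faces)
    if n == 0:
        raise DegenerateInput("empty face sequence")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    offset = int(rng.integers(0, n - T + 1)) if n >= T else int(rng.integers(0, n))
    idx = (offset + np.arange(T)) % n
    return FaceClip(faces=faces.faces[idx], sample_id=faces.sample_id)


def sample_eval_clip(faces: FaceClip, T: int = CLIP_LENGTH) -> FaceClip:
    """The central contiguous T-frame window; deterministic."""
    n = len(faces)
    if n == 0:
        raise DegenerateInput("empty face sequence")
    offset = (n - T) // 2 if n >= T else 0
    idx = (offset + np.arange(T)) % n
    return FaceClip(faces=faces.faces[idx], sample_id=faces.sample_id)


def geometric_augment(
    clip: FaceClip,
    mode: str = "eval",
    seed: int | np.random.Generator = 0,
    crop_size: int = CROP_SIZE,
    rescale_shape: tuple[int, int] = RESCALE_SHAPE,
) -> FaceClip:
    """Rescale to ``rescale_shape`` then take a ``crop_size`` square crop.

    Train mode: the crop offset is seeded-random and a horizontal flip is
    applied with probability 1/2; both the crop window and the flip are
    shared by all T frames.  Eval mode: center crop, no flip.
    """
    if mode not in ("train", "eval"):
        raise ValueError(f"mode must be 'train' or 'eval', got {mode!r}")
    rh, rw = rescale_shape
    T = len(clip)
    rescaled = np.empty((T, rh, rw, 3))
    for t in range(T):
        rescaled[t] = resize(
            clip.faces[t], (rh, rw, 3), order=1, mode="edge", anti_aliasing=False
        )
    max_dy, max_dx = rh - crop_size, rw - crop_size
    if mode == "train":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        dy = int(rng.integers(0, max_dy + 1))
        dx = int(rng.integers(0, max_dx + 1))
        flip = bool(rng.integers(0, 2))
    else:
        dy, dx, flip = max_dy // 2, max_dx // 2, False
    out = rescaled[:, dy : dy + crop_size, dx : dx + crop_size, :]
    if flip:
        out = out[:, :, ::-1, :]
    return FaceClip(faces=np.ascontiguousarray(out), sample_id=clip.sample_id)


def load_frame_dir(path: str | Path, fps: float = 30.0) -> VideoClip:
    """Read an ordered directory of PNG/JPEG frames as a video clip."""
    import imageio.v3 as iio

    path = Path(path)
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".png", ".jpg", ".jpeg"))
    if not files:
        raise DegenerateInput(f"no frames found in {path}")
    frames = np.stack([np.asarray(iio.imread(p), dtype=float) / 255.0 for p in files])
    if frames.ndim == 3:  # grayscale frames -> replicate channels
        frames = np.repeat(frames[..., None], 3, axis=3)
    return VideoClip(frames=frames, fps=fps, sample_id=path.name)
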