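"""Eigenvector-weighted late fusion of the three modality posteriors.

Each classifier emits a posterior over the three task stages
(calm, control, experimental).  The three posteriors are stacked as the
columns of the 3x3 *stress information matrix*

    M = (V_voice, V_face, V_ecg),   rows = (calm, control, experimental).

M is nonnegative with unit column sums, so by Perron-Frobenius its
largest-magnitude eigenvalue is 1 and the corresponding eigenvector can
be chosen entrywise nonnegative.  That eigenvector, L1-normalized, is
the stage weight vector w; the diagonal matrix diag(w) left-multiplies M
and the fused decision is the stage whose weighted row sum has the
largest absolute value.  Ties break toward the earlier stage in
(calm, control, experimental) order.  For the binary task, calm maps to
"calm" and both stress-inducing stages map to "stress".
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import InvalidPosterior, StressFuseError

__all__ = [
    "STAGES",
    "StressInfoMatrix",
    "FusionWeights",
    "FusionResult",
    "build_matrix",
    "principal_eigen_weights",
    "weighted_matrix",
    "decide",
    "fuse",
    "collapse_binary",
]

STAGES = ("calm", "control", "experimental")
MODALITIES = ("voice", "face", "ecg")
SIMPLEX_TOL = 1e-6


def _check_posterior(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (3,):
        raise InvalidPosterior(f"{name}: expected 3 stage probabilities, got shape {p.shape}")
    if np.any(p < -SIMPLEX_TOL) or np.any(p > 1 + SIMPLEX_TOL):
        raise InvalidPosterior(f"{name}: probabilities outside [0, 1]: {p}")
    if abs(p.sum() - 1.0) > SIMPLEX_TOL:
        raise InvalidPosterior(f"{name}: probabilities sum to {p.sum():.8f}, not 1")
    return np.clip(p, 0.0, 1.0)


@dataclass(frozen=True)
class StressInfoMatrix:
    """3x3 matrix of per-modality stage posteriors (columns voice, face, ECG)."""

    M: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "M", np.asarray(self.M, dtype=float))


@dataclass(frozen=True)
class FusionWeights:
    """Nonnegative stage weights summing to 1, from the Perron eigenvector."""

    w: np.ndarray
    eigenvalue: float

    @property
    def w_calm(self) -> float:
        return float(self.w[0])

    @property
    def w_control(self) -> float:
        return float(self.w[1])

    @property
    def w_experimental(self) -> float:
        return float(self.w[2])


@dataclass(frozen=True)
class FusionResult:
    W_global: np.ndarray
    row_scores: np.ndarray
    weights: FusionWeights
    decision: str
    binary: str


def build_matrix(voice, face, ecg) -> StressInfoMatrix:
    """Stack the three posteriors as columns in (voice, face, ecg) order."""
    cols = [
        _check_posterior(voice, "voice"),
        _check_posterior(face, "face"),
        _check_posterior(ecg, "ecg"),
    ]
    return StressInfoMatrix(M=np.column_stack(cols))


def _power_iteration(M: np.ndarray, steps: int = 500) -> np.ndarray:
    v = np.full(3, 1.0 / 3.0)
    for _ in range(steps):
        v = M @ v
        s = v.sum()
        if s <= 0:
            raise StressFuseError("power iteration collapsed to a nonpositive vector")
        v = v / s
    return v


def principal_eigen_weights(M: StressInfoMatrix | np.ndarray) -> FusionWeights:
    """Eigenvector of the largest-magnitude eigenvalue, L1-normalized.

    The input must be nonnegative and column-stochastic (each column a
    posterior); the selected eigenvalue is then 1 up to roundoff.  When
    the top eigenvalue is (numerically) repeated — e.g. all columns equal
    the uniform vector — the eigenvector is not unique, and power
    iteration from the uniform vector picks the symmetric fixed point.
    """
    A = M.M if isinstance(M, StressInfoMatrix) else np.asarray(M, dtype=float)
    if A.shape != (3, 3):
        raise InvalidPosterior(f"expected a 3x3 matrix, got {A.shape}")
    if np.any(A < -SIMPLEX_TOL):
        raise InvalidPosterior("stress information matrix must be nonnegative")
    if np.any(np.abs(A.sum(axis=0) - 1.0) > 1e-3):
        raise InvalidPosterior("columns must each sum to 1 (posterior vectors)")
    vals, vecs = np.linalg.eig(A)
    order = np.argsort(-np.abs(vals))
    top = order[0]
    lam = vals[top]
    degenerate = len(order) > 1 and abs(abs(vals[top]) - abs(vals[order[1]])) < 1e-9
    if degenerate:
        w = _power_iteration(A)
        lam = np.real_if_close(w @ A @ w / (w @ w))
    else:
        v = vecs[:, top]
        v = np.real_if_close(v)
        if np.iscomplexobj(v):  # pragma: no cover - excluded by Perron-Frobenius
            raise StressFuseError(f"complex principal eigenvector for eigenvalue {lam}")
        if v.sum() < 0:
            v = -v
        w = np.clip(v.real, 0.0, None)
        total = w.sum()
        if total <= 0:
            raise StressFuseError("principal eigenvector has no nonnegative direction")
        w = w / total
    return FusionWeights(w=w, eigenvalue=float(np.real(lam)))


def weighted_matrix(M: StressInfoMatrix | np.ndarray, weights: FusionWeights | np.ndarray) -> np.ndarray:
    """W_global = diag(w) @ M: row i of M scaled by w_i."""
    A = M.M if isinstance(M, StressInfoMatrix) else np.asarray(M, dtype=float)
    w = weights.w if isinstance(weights, FusionWeights) else np.asarray(weights, dtype=float)
    return w[:, None] * A


def decide(W_global: np.ndarray, weights: FusionWeights | None = None) -> FusionResult:
    """Stage with the largest absolute weighted row sum; ties to the
    earlier stage."""
    Wg = np.asarray(W_global, dtype=float)
    row_scores = Wg.sum(axis=1)
    decision_idx = int(np.argmax(np.abs(row_scores)))  # argmax takes the first maximum
    decision = STAGES[decision_idx]
    if weights is None:
        weights = FusionWeights(w=np.full(3, np.nan), eigenvalue=np.nan)
    return FusionResult(
        W_global=Wg,
        row_scores=row_scores,
        weights=weights,
        decision=decision,
        binary=collapse_binary(decision),
    )


def collapse_binary(stage: str) -> str:
    """Both stress-inducing stages count as acute stress."""
    if stage not in STAGES:
        raise StressFuseError(f"unknown stage {stage!r}")
    return "calm" if stage == "calm" else "stress"


def fuse(voice, face, ecg) -> FusionResult:
    """Full fusion chain from three posteriors to the stage decision."""
    M = build_matrix(voice, face, ecg)
    weights = principal_eigen_weights(M)
    Wg = weighted_matrix(M, weights)
    return decide(Wg, weights)


def fuse_from_json(path: str | Path) -> dict:
    """Fuse a JSON file {sample_id, voice: [3], face: [3], ecg: [3]}."""
    data = json.loads(Path(path).read_text())
    result = fuse(data["voice"], data["face"], data["ecg"])
    return {
        "sample_id": data.get("sample_id", ""),
        "weights": [float(x) for x in result.weights.w],
        "eigenvalue": result.weights.eigenvalue,
        "row_scores": [float(x) for x in result.row_scores],
        "decision": result.decision,
        "binary": result.binary,
    }
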