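"""Frame-by-frame network inputs: magnitudes and their first two derivatives.

Each 20 ms frame of the six conditioned channel magnitudes is expanded to an
18-element feature vector — six magnitudes, six first derivatives and six
second derivatives — the regression inputs for every virtual-force and
moving-coordinate network.  The derivative terms carry velocity and
acceleration information that suppresses abrupt estimation jumps.

Derivatives are backward (causal) finite differences so the pipeline adds no
latency in streaming use; the derivative slots that have no history yet
(first frame for d1, first two frames for d2) are zero-filled so feature and
reference streams stay aligned 1:1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_conditioning import AREA_LABELS

#: Fixed feature order: m_A..m_F, d1_A..d1_F, d2_A..d2_F.
FEATURE_COLUMNS = tuple(
    [f"m{a}" for a in AREA_LABELS]
    + [f"d1{a}" for a in AREA_LABELS]
    + [f"d2{a}" for a in AREA_LABELS]
)

N_FEATURES = len(FEATURE_COLUMNS)


@dataclass(frozen=True)
class FeatureVector:
    """The 18 network inputs for one frame."""

    t: float
    m: tuple[float, ...]
    d1: tuple[float, ...]
    d2: tuple[float, ...]

    def __post_init__(self) -> None:
        for name in ("m", "d1", "d2"):
            v = tuple(float(x) for x in getattr(self, name))
            if len(v) != 6:
                raise ValueError(f"{name} must have 6 entries, got {len(v)}")
            if not all(np.isfinite(v)):
                raise ValueError(f"{name} contains non-finite values")
            object.__setattr__(self, name, v)

    def to_array(self) -> np.ndarray:
        return np.array(self.m + self.d1 + self.d2, dtype=float)

    @classmethod
    def from_row(cls, t: float, row: np.ndarray) -> "FeatureVector":
        row = np.asarray(row, dtype=float)
        if row.shape != (N_FEATURES,):
            raise ValueError(f"expected {N_FEATURES} features, got {row.shape}")
        return cls(t=float(t), m=tuple(row[:6]), d1=tuple(row[6:12]), d2=tuple(row[12:]))


def build_feature_matrix(channels: np.ndarray, dt: float) -> np.ndarray:
    """Expand a (n, 6) magnitude series to the (n, 18) feature matrix.

    d1[i] = (m[i] - m[i-1]) / dt and d2[i] = (m[i] - 2 m[i-1] + m[i-2]) / dt²;
    undefined warm-up slots are zero.  Output length equals input length.
    """
    channels = np.asarray(channels, dtype=float)
    if channels.ndim != 2 or channels.shape[1] != 6:
        raise ValueError(f"expected (n, 6) channel array, got {channels.shape}")
    n = channels.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 frames for second derivatives, got {n}")
    if not (dt > 0):
        raise ValueError("dt must be positive")
    if not np.all(np.isfinite(channels)):
        raise ValueError("channel series contains non-finite values")
    d1 = np.zeros_like(channels)
    d2 = np.zeros_like(channels)
    d1[1:] = (channels[1:] - channels[:-1]) / dt
    d2[2:] = (channels[2:] - 2.0 * channels[1:-1] + channels[:-2]) / dt**2
    return np.hstack([channels, d1, d2])


def build_features(
    t: np.ndarray, channels: np.ndarray, dt: float | None = None
) -> list[FeatureVector]:
    """Frame-level view of :func:`build_feature_matrix`."""
    t = np.asarray(t, dtype=float)
    if dt is None:
        if t.size < 2:
            raise ValueError("cannot infer dt from fewer than 2 frames")
        dt = float(t[1] - t[0])
    X = build_feature_matrix(channels, dt)
    return [FeatureVector.from_row(ti, row) for ti, row in zip(t, X)]
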