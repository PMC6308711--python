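"""Virtual-force estimation core.

The insole is divided into six anatomical areas, each represented by a
*virtual force* (the total vertical force over the whole area, which exceeds
what the small FSR patch inside it measures) and a *moving coordinate* (the
centroid of pressure within the area, free to move instead of being pinned
to the sensor position).  Eighteen shallow regressors — one per virtual
force and one per coordinate component — map the 18-element feature vector
(channel magnitudes and their first two derivatives) to these quantities.

The combiners are:

    GRF   = sum of the six virtual forces
    CoP   = force-weighted mean of the moving coordinates
            (areas with zero force contribute nothing; if all six forces
            are zero the CoP is undefined)

and the fixed-coordinate weighted-mean baseline (WMA) uses raw channel
values as weights on the fixed sensor positions — provably confined to the
convex hull of the sensor positions, which is the limitation the moving
coordinates remove.

Each regressor is a single-hidden-layer network with hyperbolic-tangent
(tangent-sigmoid) activations on both the hidden and the output layer.
Inputs are affinely scaled per feature to [-1, 1] and targets to
[-0.9, 0.9] on the training split (a bounded output layer cannot express
unscaled newton-range targets).  Training is batch nonlinear least squares
with early stopping on a validation split: Levenberg–Marquardt (damped
Gauss–Newton with an analytic Jacobian) when the parameter count permits
dense normal equations, chunked L-BFGS otherwise.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize

from .feature_builder import N_FEATURES, FeatureVector
from .signal_conditioning import AREA_LABELS, ConditioningConfig

__all__ = [
    "AREA_SUBSCRIPTS",
    "AreaGeometry",
    "VirtualForceState",
    "RegressorSpec",
    "TrainedRegressor",
    "train_regressor",
    "predict_state",
    "grf",
    "wma_cop",
    "wma_cop_series",
    "fixed_wma_cop",
    "fixed_wma_cop_series",
    "LinearCoeffs",
    "linear_force_estimate",
    "fit_linear_diagnostic",
    "proportional_rates",
    "CopUndefinedError",
    "VfaModel",
]

#: Field subscripts of the six virtual forces, in fixed A-F channel order:
#: A=ET (medial toe), B=ER (medial metatarsal), C=EL (lateral metatarsal),
#: D=EH (forefoot tip), E=EC (arch), F=ELT (heel).
AREA_SUBSCRIPTS = ("ET", "ER", "EL", "EH", "EC", "ELT")

BUNDLE_FORMAT = "vfinsole-bundle-1"


class CopUndefinedError(ValueError):
    """Signals that the centre of pressure is undefined (no load anywhere)."""


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


def _default_sensor_xy() -> np.ndarray:
    # cm, insole frame: origin at the posterior-medial corner, x anterior,
    # y lateral; US8 insole envelope 28 x 11 cm.  The fixed x row matches
    # the published sensor-coordinate convention for this layout.
    return np.array(
        [
            [7.0, 4.0],  # A: medial toe
            [12.0, 7.5],  # B: medial metatarsal
            [12.0, 3.0],  # C: lateral metatarsal
            [25.5, 6.5],  # D: forefoot tip
            [9.25, 8.0],  # E: arch
            [3.5, 5.5],  # F: heel
        ]
    )


def _default_bounds() -> np.ndarray:
    # (x0, x1, y0, y1) per area; the rectangles tile the insole envelope so
    # the synthetic pressure kernel can be integrated area-by-area without
    # losing mass.
    return np.array(
        [
            [6.0, 11.0, 0.0, 5.5],  # A
            [11.0, 17.0, 5.5, 11.0],  # B
            [11.0, 17.0, 0.0, 5.5],  # C
            [17.0, 28.0, 0.0, 11.0],  # D
            [6.0, 11.0, 5.5, 11.0],  # E
            [0.0, 6.0, 0.0, 11.0],  # F
        ]
    )


@dataclass
class AreaGeometry:
    """The six insole areas: labels, fixed sensor positions, bounds.

    ``bounds`` rows are (x0, x1, y0, y1) rectangles (cm) containing the
    corresponding sensor; moving coordinates are clamped into them.
    """

    labels: tuple[str, ...] = AREA_LABELS
    subscripts: tuple[str, ...] = AREA_SUBSCRIPTS
    sensor_xy: np.ndarray = field(default_factory=_default_sensor_xy)
    bounds: np.ndarray = field(default_factory=_default_bounds)
    envelope: tuple[float, float] = (28.0, 11.0)

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.subscripts = tuple(self.subscripts)
        self.sensor_xy = np.asarray(self.sensor_xy, dtype=float)
        self.bounds = np.asarray(self.bounds, dtype=float)
        if len(self.labels) != 6 or len(set(self.labels)) != 6:
            raise ValueError("exactly six distinct area labels required")
        if self.sensor_xy.shape != (6, 2) or self.bounds.shape != (6, 4):
            raise ValueError("sensor_xy must be (6, 2) and bounds (6, 4)")
        ex, ey = self.envelope
        for i, lab in enumerate(self.labels):
            x0, x1, y0, y1 = self.bounds[i]
            if not (0.0 <= x0 < x1 <= ex and 0.0 <= y0 < y1 <= ey):
                raise ValueError(f"bounds of area {lab} leave the insole envelope")
            sx, sy = self.sensor_xy[i]
            if not (x0 <= sx <= x1 and y0 <= sy <= y1):
                raise ValueError(f"sensor {lab} lies outside its area bounds")

    def clamp(self, area: int, xy: np.ndarray) -> np.ndarray:
        x0, x1, y0, y1 = self.bounds[area]
        return np.array(
            [min(max(float(xy[0]), x0), x1), min(max(float(xy[1]), y0), y1)]
        )

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "subscripts": list(self.subscripts),
            "sensor_xy": self.sensor_xy.tolist(),
            "bounds": self.bounds.tolist(),
            "envelope": list(self.envelope),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AreaGeometry":
        allowed = {"labels", "subscripts", "sensor_xy", "bounds", "envelope"}
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"unknown geometry key {sorted(unknown)[0]!r}")
        kwargs = dict(d)
        if "envelope" in kwargs:
            kwargs["envelope"] = tuple(kwargs["envelope"])
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# State
# ---------------------------------------------------------------------------


@dataclass
class VirtualForceState:
    """Six virtual forces (N) and their moving coordinates (cm) at time t.

    A coordinate is undefined (NaN) if and only if its force is zero — the
    coordinate of an unloaded area is not estimated.
    """

    t: float
    F: np.ndarray  # (6,)
    xy: np.ndarray  # (6, 2); NaN rows where the force is zero

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.F.shape != (6,) or self.xy.shape != (6, 2):
            raise ValueError("F must be (6,) and xy (6, 2)")
        if not np.all(np.isfinite(self.F)) or np.any(self.F < 0):
            raise ValueError("forces must be finite and non-negative")

    @property
    def defined(self) -> np.ndarray:
        """Boolean mask of areas whose coordinate is defined."""
        return np.all(np.isfinite(self.xy), axis=1)


def validate_state(state: VirtualForceState, geom: AreaGeometry, atol: float = 1e-9) -> None:
    """Check the force/coordinate invariants against a geometry."""
    defined = state.defined
    if np.any(defined & (state.F == 0.0)):
        raise ValueError("zero-force area has a defined coordinate")
    if np.any(~defined & (state.F > 0.0)):
        raise ValueError("positive-force area has an undefined coordinate")
    for i in np.flatnonzero(defined):
        x0, x1, y0, y1 = geom.bounds[i]
        x, y = state.xy[i]
        if not (x0 - atol <= x <= x1 + atol and y0 - atol <= y <= y1 + atol):
            raise ValueError(
                f"coordinate of area {geom.labels[i]} lies outside its bounds"
            )


# ---------------------------------------------------------------------------
# Shallow tanh regressor
# ---------------------------------------------------------------------------


@dataclass
class RegressorSpec:
    """Architecture and training settings for one shallow regressor.

    ``n_hidden`` defaults differ by role: 10 for virtual-force nets, 200
    for moving-coordinate nets.  ``max_epochs`` caps optimizer iterations;
    early stopping monitors the validation split with ``patience``
    consecutive non-improving checks.  ``algorithm`` is "lm", "lbfgs" or
    "auto" (LM when the parameter count is at most ``lm_param_limit``).
    """

    n_hidden: int = 10
    input_dim: int = N_FEATURES
    split: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0
    patience: int = 6
    max_epochs: int = 1000
    algorithm: str = "auto"
    target_span: float = 0.9
    check_interval: int = 25
    lm_param_limit: int = 1500

    def __post_init__(self) -> None:
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.algorithm not in ("auto", "lm", "lbfgs"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")

    @property
    def n_params(self) -> int:
        h, d = self.n_hidden, self.input_dim
        return h * d + h + h + 1

    def to_dict(self) -> dict:
        return {
            "n_hidden": self.n_hidden,
            "input_dim": self.input_dim,
            "split": list(self.split),
            "seed": self.seed,
            "patience": self.patience,
            "max_epochs": self.max_epochs,
            "algorithm": self.algorithm,
            "target_span": self.target_span,
            "check_interval": self.check_interval,
            "lm_param_limit": self.lm_param_limit,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegressorSpec":
        kwargs = dict(d)
        if "split" in kwargs:
            kwargs["split"] = tuple(kwargs["split"])
        return cls(**kwargs)


def _unpack(theta: np.ndarray, d: int, h: int):
    W1 = theta[: h * d].reshape(h, d)
    b1 = theta[h * d : h * d + h]
    w2 = theta[h * d + h : h * d + 2 * h]
    b2 = theta[-1]
    return W1, b1, w2, b2


def _forward(theta: np.ndarray, X: np.ndarray, d: int, h: int):
    W1, b1, w2, b2 = _unpack(theta, d, h)
    A = np.tanh(X @ W1.T + b1)
    out = np.tanh(A @ w2 + b2)
    return out, A, w2


def _loss_grad(theta: np.ndarray, X: np.ndarray, y: np.ndarray, d: int, h: int):
    out, A, w2 = _forward(theta, X, d, h)
    r = out - y
    n = y.size
    loss = 0.5 * float(r @ r) / n
    gu = r * (1.0 - out * out) / n  # dL/d(pre-output)
    gb2 = float(gu.sum())
    gw2 = A.T @ gu
    GH = (gu[:, None] * w2[None, :]) * (1.0 - A * A)  # (n, h)
    gW1 = GH.T @ X
    gb1 = GH.sum(axis=0)
    grad = np.concatenate([gW1.ravel(), gb1, gw2, [gb2]])
    return loss, grad


def _jacobian(theta: np.ndarray, X: np.ndarray, d: int, h: int):
    """Residuals and the analytic Jacobian d r_i / d theta_j."""
    out, A, w2 = _forward(theta, X, d, h)
    s = 1.0 - out * out  # (n,)
    H = (s[:, None] * w2[None, :]) * (1.0 - A * A)  # (n, h)
    JW1 = H[:, :, None] * X[:, None, :]  # (n, h, d)
    J = np.concatenate(
        [JW1.reshape(X.shape[0], h * d), H, s[:, None] * A, s[:, None]], axis=1
    )
    return out, J


@dataclass
class TrainedRegressor:
    """A trained (pure, deterministic) shallow tanh regressor."""

    spec: RegressorSpec
    theta: np.ndarray | None
    x_lo: np.ndarray
    x_hi: np.ndarray
    y_lo: float
    y_hi: float
    constant: float | None = None  # set when targets were constant
    train_rmse: float = float("nan")
    val_rmse: float = float("nan")
    test_rmse: float = float("nan")
    n_split: tuple[int, int, int] = (0, 0, 0)

    def _scale_x(self, X: np.ndarray) -> np.ndarray:
        span = self.x_hi - self.x_lo
        gain = np.where(span > 0, 2.0 / np.where(span > 0, span, 1.0), 0.0)
        return (X - self.x_lo) * gain - np.where(span > 0, 1.0, 0.0)

    def _unscale_y(self, ys: np.ndarray) -> np.ndarray:
        span = self.y_hi - self.y_lo
        if span == 0:
            return np.full_like(ys, self.y_lo)
        s = self.spec.target_span
        return self.y_lo + (ys + s) * span / (2.0 * s)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict targets for an (n, d) or (d,) feature array."""
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        if single:
            X = X[None, :]
        if X.shape[1] != self.spec.input_dim:
            raise ValueError(
                f"expected {self.spec.input_dim} features, got {X.shape[1]}"
            )
        if not np.all(np.isfinite(X)):
            raise ValueError("features contain non-finite values")
        if self.constant is not None:
            y = np.full(X.shape[0], self.constant)
        else:
            out, _, _ = _forward(
                self.theta, self._scale_x(X), self.spec.input_dim, self.spec.n_hidden
            )
            y = self._unscale_y(out)
        return float(y[0]) if single else y

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "theta": None if self.theta is None else self.theta.tolist(),
            "x_lo": self.x_lo.tolist(),
            "x_hi": self.x_hi.tolist(),
            "y_lo": self.y_lo,
            "y_hi": self.y_hi,
            "constant": self.constant,
            "train_rmse": self.train_rmse,
            "val_rmse": self.val_rmse,
            "test_rmse": self.test_rmse,
            "n_split": list(self.n_split),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedRegressor":
        return cls(
            spec=RegressorSpec.from_dict(d["spec"]),
            theta=None if d["theta"] is None else np.array(d["theta"], dtype=float),
            x_lo=np.array(d["x_lo"], dtype=float),
            x_hi=np.array(d["x_hi"], dtype=float),
            y_lo=float(d["y_lo"]),
            y_hi=float(d["y_hi"]),
            constant=d.get("constant"),
            train_rmse=float(d["train_rmse"]),
            val_rmse=float(d["val_rmse"]),
            test_rmse=float(d["test_rmse"]),
            n_split=tuple(d["n_split"]),
        )


class _EarlyStopper:
    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.best_theta: np.ndarray | None = None
        self.bad = 0

    def check(self, val_sse: float, theta: np.ndarray) -> bool:
        """Record a validation check; True means stop."""
        if val_sse < self.best - 1e-15:
            self.best = val_sse
            self.best_theta = theta.copy()
            self.bad = 0
            return False
        self.bad += 1
        return self.bad >= self.patience


def _fit_lm(theta, Xtr, ytr, Xval, yval, spec):
    d, h = spec.input_dim, spec.n_hidden
    stop = _EarlyStopper(spec.patience)

    def val_sse(th):
        if yval.size == 0:
            out, _, _ = _forward(th, Xtr, d, h)
            return float(np.sum((out - ytr) ** 2))
        out, _, _ = _forward(th, Xval, d, h)
        return float(np.sum((out - yval) ** 2))

    stop.check(val_sse(theta), theta)
    r, J = _jacobian(theta, Xtr, d, h)
    r = r - ytr
    sse = float(r @ r)
    lam = 1e-2
    eye = np.eye(theta.size)
    for _ in range(spec.max_epochs):
        JtJ = J.T @ J
        Jtr_ = J.T @ r
        accepted = False
        for _try in range(12):
            Amat = JtJ + lam * np.diag(np.diag(JtJ)) + 1e-12 * eye
            try:
                delta = np.linalg.solve(Amat, -Jtr_)
            except np.linalg.LinAlgError:
                delta = np.linalg.lstsq(Amat, -Jtr_, rcond=None)[0]
            cand = theta + delta
            out, _, _ = _forward(cand, Xtr, d, h)
            new_sse = float(np.sum((out - ytr) ** 2))
            if np.isfinite(new_sse) and new_sse < sse:
                theta = cand
                lam = max(lam / 3.0, 1e-12)
                accepted = True
                break
            lam *= 3.0
        if not accepted:
            break
        if stop.check(val_sse(theta), theta):
            break
        r, J = _jacobian(theta, Xtr, d, h)
        r = r - ytr
        prev, sse = sse, float(r @ r)
        if prev - sse < 1e-12 * max(prev, 1e-30):
            break
    return stop.best_theta if stop.best_theta is not None else theta


def _fit_lbfgs(theta, Xtr, ytr, Xval, yval, spec):
    d, h = spec.input_dim, spec.n_hidden
    stop = _EarlyStopper(spec.patience)

    def val_sse(th):
        Xv, yv = (Xval, yval) if yval.size else (Xtr, ytr)
        out, _, _ = _forward(th, Xv, d, h)
        return float(np.sum((out - yv) ** 2))

    stop.check(val_sse(theta), theta)
    remaining = spec.max_epochs
    while remaining > 0:
        res = minimize(
            _loss_grad,
            theta,
            args=(Xtr, ytr, d, h),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": min(spec.check_interval, remaining)},
        )
        theta = res.x
        remaining -= min(spec.check_interval, remaining)
        if stop.check(val_sse(theta), theta):
            break
        if res.success and res.nit < spec.check_interval:
            break  # converged before exhausting the chunk
    return stop.best_theta if stop.best_theta is not None else theta


def train_regressor(
    features: np.ndarray, targets: np.ndarray, spec: RegressorSpec
) -> TrainedRegressor:
    """Train one shallow tanh regressor on (features, targets).

    The data are split at frame level into train/validation/test fractions
    with the spec's seed; input/target scaling is fitted on the training
    split only.  Returns a pure deterministic predictor carrying the
    train/val/test RMSEs in original target units.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float).ravel()
    if X.ndim != 2 or X.shape[1] != spec.input_dim:
        raise ValueError(f"features must be (n, {spec.input_dim})")
    if X.shape[0] != y.size:
        raise ValueError("features and targets must have equal length")
    if X.shape[0] < 100:
        raise ValueError(f"need at least 100 frames to train, got {X.shape[0]}")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("training data contain NaN or infinite values")

    rng = np.random.default_rng(spec.seed)
    n = X.shape[0]
    perm = rng.permutation(n)
    n_tr = int(round(spec.split[0] * n))
    n_val = int(round(spec.split[1] * n))
    idx_tr, idx_val, idx_te = (
        perm[:n_tr],
        perm[n_tr : n_tr + n_val],
        perm[n_tr + n_val :],
    )
    Xtr_raw, ytr_raw = X[idx_tr], y[idx_tr]

    x_lo = Xtr_raw.min(axis=0)
    x_hi = Xtr_raw.max(axis=0)
    y_lo = float(ytr_raw.min())
    y_hi = float(ytr_raw.max())

    reg = TrainedRegressor(
        spec=spec, theta=None, x_lo=x_lo, x_hi=x_hi, y_lo=y_lo, y_hi=y_hi
    )
    reg.n_split = (idx_tr.size, idx_val.size, idx_te.size)

    if y_hi == y_lo:
        warnings.warn(
            "targets are constant; returning the constant predictor", stacklevel=2
        )
        reg.constant = y_lo
    else:
        span = spec.target_span

        def scale_y(v):
            return (v - y_lo) / (y_hi - y_lo) * (2.0 * span) - span

        Xtr = reg._scale_x(Xtr_raw)
        ytr = scale_y(ytr_raw)
        Xval = reg._scale_x(X[idx_val])
        yval = scale_y(y[idx_val])

        d, h = spec.input_dim, spec.n_hidden
        theta0 = np.concatenate(
            [
                rng.standard_normal(h * d) / math.sqrt(d),
                rng.standard_normal(h) * 0.1,
                rng.standard_normal(h) / math.sqrt(h),
                [0.0],
            ]
        )
        algo = spec.algorithm
        if algo == "auto":
            algo = "lm" if spec.n_params <= spec.lm_param_limit else "lbfgs"
        fit = _fit_lm if algo == "lm" else _fit_lbfgs
        reg.theta = fit(theta0, Xtr, ytr, Xval, yval, spec)

    def rmse_on(idx):
        if idx.size == 0:
            return float("nan")
        pred = reg.predict(X[idx])
        return float(np.sqrt(np.mean((pred - y[idx]) ** 2)))

    reg.train_rmse = rmse_on(idx_tr)
    reg.val_rmse = rmse_on(idx_val)
    reg.test_rmse = rmse_on(idx_te)
    return reg


# ---------------------------------------------------------------------------
# Combiners
# ---------------------------------------------------------------------------


def grf(state: VirtualForceState) -> float:
    """Total vertical ground reaction force: the sum of the six forces."""
    return math.fsum(state.F)


def wma_cop(state: VirtualForceState) -> tuple[float, float]:
    """Centre of pressure: force-weighted mean of the moving coordinates.

    Zero-force areas contribute nothing.  Raises
    :class:`CopUndefinedError` when all forces are zero, and ``ValueError``
    when a positive force has an undefined coordinate (invariant violation).
    """
    F = state.F
    defined = state.defined
    if np.any((F > 0) & ~defined):
        raise ValueError("positive force with undefined coordinate")
    active = F > 0
    if not np.any(active):
        raise CopUndefinedError("all virtual forces are zero; CoP undefined")
    total = math.fsum(F[active])
    x = math.fsum(F[i] * state.xy[i, 0] for i in np.flatnonzero(active)) / total
    y = math.fsum(F[i] * state.xy[i, 1] for i in np.flatnonzero(active)) / total
    return (x, y)


def wma_cop_series(F: np.ndarray, xy: np.ndarray) -> np.ndarray:
    """Vectorized CoP over a series: (n, 6) forces, (n, 6, 2) coordinates.

    Rows with zero total force get NaN.  Coordinates of zero-force areas
    may be NaN; they are masked out before the weighted mean.
    """
    F = np.asarray(F, dtype=float)
    xy = np.asarray(xy, dtype=float)
    w = np.where(F > 0, F, 0.0)
    coords = np.where(np.isfinite(xy), xy, 0.0)
    total = w.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cop = np.einsum("ni,nij->nj", w, coords) / total[:, None]
    cop[total <= 0] = np.nan
    return cop


def fixed_wma_cop(frame, geom: AreaGeometry) -> tuple[float, float]:
    """Fixed-coordinate weighted-mean baseline (WMA).

    Channel values weight the *fixed* sensor coordinates; the result is a
    convex combination of the six sensor positions and therefore can never
    leave their convex hull.  ``frame`` is an :class:`FsrFrame` or any
    six-element channel array.
    """
    channels = np.asarray(getattr(frame, "channels", frame), dtype=float)
    if channels.shape != (6,):
        raise ValueError("expected six channel values")
    if np.any(channels < 0):
        raise ValueError("channel values must be non-negative")
    total = math.fsum(channels)
    if total <= 0:
        raise CopUndefinedError("zero channel sum; CoP undefined")
    x = math.fsum(channels[i] * geom.sensor_xy[i, 0] for i in range(6)) / total
    y = math.fsum(channels[i] * geom.sensor_xy[i, 1] for i in range(6)) / total
    return (x, y)


def fixed_wma_cop_series(channels: np.ndarray, geom: AreaGeometry) -> np.ndarray:
    """Vectorized WMA baseline over an (n, 6) channel series; NaN when unloaded."""
    channels = np.asarray(channels, dtype=float)
    total = channels.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cop = (channels @ geom.sensor_xy) / total[:, None]
    cop[total <= 0] = np.nan
    return cop


def proportional_rates(values: np.ndarray, ref: int = 0) -> np.ndarray:
    """Values expressed relative to the reference entry (diagnostic ratio).

    Used to compare how much larger the estimated virtual forces are than
    the raw channel readings across areas within one frame.
    """
    values = np.asarray(values, dtype=float)
    if values[ref] <= 0:
        raise ValueError("reference entry must be positive")
    return values / values[ref]


# ---------------------------------------------------------------------------
# Linear diagnostic
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LinearCoeffs:
    """Seven constants of the one-neuron linear diagnostic.

    ``a[0]`` is the intercept (N); ``a[1:]`` are slopes (N per channel
    unit) for the six channels in A-F order.
    """

    a: tuple[float, ...]

    def __post_init__(self) -> None:
        v = tuple(float(x) for x in self.a)
        if len(v) != 7:
            raise ValueError(f"expected 7 coefficients, got {len(v)}")
        if not all(np.isfinite(v)):
            raise ValueError("coefficients must be finite")
        object.__setattr__(self, "a", v)


def linear_force_estimate(frame, coeffs: LinearCoeffs) -> float:
    """Evaluate the linear multiple-regression force estimate (no clipping).

    A single-neuron view of virtual-force estimation: the force over one
    area as an affine function of all six channel readings.
    """
    channels = np.asarray(getattr(frame, "channels", frame), dtype=float)
    if channels.shape != (6,):
        raise ValueError("expected six channel values")
    a = coeffs.a
    return a[0] + math.fsum(a[i + 1] * channels[i] for i in range(6))


def fit_linear_diagnostic(channels: np.ndarray, target: np.ndarray) -> LinearCoeffs:
    """Ordinary least squares fit of the linear diagnostic.

    ``channels`` is (n, 6); ``target`` the force series to explain.  Raises
    on a rank-deficient design, naming the dependent columns.
    """
    X = np.asarray(channels, dtype=float)
    y = np.asarray(target, dtype=float).ravel()
    if X.ndim != 2 or X.shape[1] != 6:
        raise ValueError("channels must be (n, 6)")
    if X.shape[0] != y.size:
        raise ValueError("channels and target must have equal length")
    if X.shape[0] < 7:
        raise ValueError("need at least 7 frames for the 7-parameter fit")
    design = np.column_stack([np.ones(X.shape[0]), X])
    rank = np.linalg.matrix_rank(design)
    if rank < 7:
        # pivoted QR exposes which columns are linearly dependent
        from scipy.linalg import qr

        _, _, piv = qr(design, pivoting=True)
        names = ["intercept"] + [f"ch{a}" for a in AREA_LABELS]
        dep = [names[j] for j in sorted(piv[rank:])]
        raise ValueError(f"rank-deficient design; dependent column(s): {dep}")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return LinearCoeffs(a=tuple(coef))


# ---------------------------------------------------------------------------
# Prediction and the 18-net model bundle
# ---------------------------------------------------------------------------

DEFAULT_DEAD_BAND_N = 0.5


def predict_state(
    fv,
    force_nets,
    coord_nets,
    geom: AreaGeometry,
    dead_band: float = DEFAULT_DEAD_BAND_N,
    t: float = 0.0,
) -> VirtualForceState:
    """Estimate the virtual-force state for one feature vector.

    ``force_nets`` are the six force regressors (A-F order); ``coord_nets``
    the twelve coordinate regressors ordered x_A..x_F then y_A..y_F.
    Forces are clipped at zero; a force below ``dead_band`` is treated as
    no pressure (force 0, coordinate undefined); defined coordinates are
    clamped to their area bounds.
    """
    if isinstance(fv, FeatureVector):
        t = fv.t
        fv = fv.to_array()
    row = np.asarray(fv, dtype=float)
    nets = list(force_nets) + list(coord_nets)
    if len(nets) != 18 or any(n is None for n in nets):
        raise ValueError("need 6 trained force nets and 12 trained coordinate nets")
    dims = {n.spec.input_dim for n in nets}
    if dims != {row.size}:
        raise ValueError("regressor input scaling dimension mismatch")
    F = np.array([max(net.predict(row), 0.0) for net in force_nets])
    xy = np.full((6, 2), np.nan)
    for i in range(6):
        if F[i] < dead_band:
            F[i] = 0.0
            continue
        x = coord_nets[i].predict(row)
        y = coord_nets[6 + i].predict(row)
        xy[i] = geom.clamp(i, np.array([x, y]))
    return VirtualForceState(t=t, F=F, xy=xy)


@dataclass
class VfaModel:
    """The trained virtual-force model: 18 regressors plus plumbing.

    Bundles the conditioning configuration, geometry, the six force nets
    and twelve coordinate nets, and the dead-band threshold, and offers
    series-level prediction from raw channels to GRF and CoP.
    """

    geometry: AreaGeometry
    conditioning: ConditioningConfig
    force_nets: list
    coord_x_nets: list
    coord_y_nets: list
    dead_band: float = DEFAULT_DEAD_BAND_N
    report: dict | None = None

    # -- training -----------------------------------------------------------

    @classmethod
    def train(
        cls,
        X: np.ndarray,
        Y: np.ndarray,
        geometry: AreaGeometry | None = None,
        conditioning: ConditioningConfig | None = None,
        force_spec: RegressorSpec | None = None,
        coord_spec: RegressorSpec | None = None,
        dead_band: float = DEFAULT_DEAD_BAND_N,
    ) -> "VfaModel":
        """Train all 18 regressors from a training matrix.

        ``X`` is (n, 18) features; ``Y`` is (n, 18) targets ordered
        F_A..F_F, x_A..x_F, y_A..y_F, with NaN coordinates on frames where
        the reference area force is zero.  Coordinate nets are trained only
        on frames where their area is loaded.
        """
        geometry = geometry or AreaGeometry()
        conditioning = conditioning or ConditioningConfig()
        force_spec = force_spec or RegressorSpec(n_hidden=10)
        coord_spec = coord_spec or RegressorSpec(
            n_hidden=200, max_epochs=300, algorithm="auto"
        )
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.shape != (X.shape[0], 18):
            raise ValueError("Y must be (n, 18): six forces, six x, six y")

        report: dict = {"force": {}, "coord": {}}
        force_nets, cx_nets, cy_nets = [], [], []
        for i, label in enumerate(AREA_LABELS):
            spec_i = RegressorSpec.from_dict(
                {**force_spec.to_dict(), "seed": force_spec.seed + i}
            )
            net = train_regressor(X, Y[:, i], spec_i)
            force_nets.append(net)
            report["force"][label] = {
                "train_rmse": net.train_rmse,
                "val_rmse": net.val_rmse,
                "test_rmse": net.test_rmse,
                "n_split": list(net.n_split),
            }
        for i, label in enumerate(AREA_LABELS):
            loaded = Y[:, i] > 0
            for k, (axis, store, col) in enumerate(
                (("x", cx_nets, 6 + i), ("y", cy_nets, 12 + i))
            ):
                tgt = Y[:, col]
                mask = loaded & np.isfinite(tgt)
                spec_i = RegressorSpec.from_dict(
                    {**coord_spec.to_dict(), "seed": coord_spec.seed + 100 + 2 * i + k}
                )
                net = train_regressor(X[mask], tgt[mask], spec_i)
                store.append(net)
                report["coord"][f"{axis}_{label}"] = {
                    "train_rmse": net.train_rmse,
                    "val_rmse": net.val_rmse,
                    "test_rmse": net.test_rmse,
                    "n_frames": int(mask.sum()),
                }
        return cls(
            geometry=geometry,
            conditioning=conditioning,
            force_nets=force_nets,
            coord_x_nets=cx_nets,
            coord_y_nets=cy_nets,
            dead_band=dead_band,
            report=report,
        )

    # -- prediction ---------------------------------------------------------

    def predict_frame(self, fv) -> VirtualForceState:
        return predict_state(
            fv,
            self.force_nets,
            self.coord_x_nets + self.coord_y_nets,
            self.geometry,
            dead_band=self.dead_band,
        )

    def predict_series(self, X: np.ndarray) -> dict:
        """Vectorized prediction over an (n, 18) feature matrix.

        Returns arrays: forces (n, 6), coordinates (n, 6, 2) with NaN for
        undefined, grf (n,), cop (n, 2) with NaN rows when unloaded.
        """
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        F = np.column_stack([np.maximum(net.predict(X), 0.0) for net in self.force_nets])
        below = F < self.dead_band
        F[below] = 0.0
        xy = np.full((n, 6, 2), np.nan)
        for i in range(6):
            active = ~below[:, i]
            if not np.any(active):
                continue
            x0, x1, y0, y1 = self.geometry.bounds[i]
            xy[active, i, 0] = np.clip(self.coord_x_nets[i].predict(X[active]), x0, x1)
            xy[active, i, 1] = np.clip(self.coord_y_nets[i].predict(X[active]), y0, y1)
        return {
            "F": F,
            "xy": xy,
            "grf": F.sum(axis=1),
            "cop": wma_cop_series(F, xy),
        }

    def predict_raw(self, t: np.ndarray, channels: np.ndarray) -> dict:
        """Condition raw channels, build features and predict, end to end."""
        from .feature_builder import build_feature_matrix

        t = np.asarray(t, dtype=float)
        cond = self.conditioning.condition(t, channels)
        dt = float(t[1] - t[0])
        X = build_feature_matrix(cond, dt)
        out = self.predict_series(X)
        out["t"] = t
        out["conditioned"] = cond
        return out

    # -- serialization ------------------------------------------------------

    def save(self, path) -> None:
        """Write the model bundle: JSON metadata plus one file per net."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        meta = {
            "format": BUNDLE_FORMAT,
            "geometry": self.geometry.to_dict(),
            "conditioning": self.conditioning.to_dict(),
            "dead_band": self.dead_band,
            "report": self.report,
        }
        (path / "metadata.json").write_text(json.dumps(meta, indent=1))
        for group, nets in (
            ("force", self.force_nets),
            ("coord_x", self.coord_x_nets),
            ("coord_y", self.coord_y_nets),
        ):
            for label, net in zip(AREA_LABELS, nets):
                (path / f"{group}_{label}.json").write_text(
                    json.dumps(net.to_dict())
                )

    @classmethod
    def load(cls, path) -> "VfaModel":
        path = Path(path)
        meta = json.loads((path / "metadata.json").read_text())
        if meta.get("format") != BUNDLE_FORMAT:
            raise ValueError(f"unsupported bundle format {meta.get('format')!r}")
        nets = {}
        for group in ("force", "coord_x", "coord_y"):
            nets[group] = [
                TrainedRegressor.from_dict(
                    json.loads((path / f"{group}_{label}.json").read_text())
                )
                for label in AREA_LABELS
            ]
        return cls(
            geometry=AreaGeometry.from_dict(meta["geometry"]),
            conditioning=ConditioningConfig.from_dict(meta["conditioning"]),
            force_nets=nets["force"],
            coord_x_nets=nets["coord_x"],
            coord_y_nets=nets["coord_y"],
            dead_band=float(meta["dead_band"]),
            report=meta.get("report"),
        )
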