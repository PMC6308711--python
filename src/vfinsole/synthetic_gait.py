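"""Synthetic plantar-pressure trials with known ground truth.

Stands in for a high-resolution in-shoe pressure reference system: each
trial carries a *truth* stream (per-area forces, per-area pressure
centroids, total GRF and CoP) and a degraded *sensed* stream (what six
small FSR patches would read), so the whole estimation pipeline can be
trained and scored without hardware.

The pressure distribution is an isotropic 2-D Gaussian kernel whose centre
and total load follow task-specific profiles:

* ``scan``  — double-support standing, centre of mass swept counter-
  clockwise around the insole plus an anterior-posterior back-and-forth,
  at constant load (half body weight on the instrumented foot).
* ``gait1`` / ``gait2`` — periodic gait at 1 / 2 km/h: stance phases with
  the classic two-peak vertical GRF (weight-acceptance and push-off peaks
  ~1.1x body weight, mid-stance valley ~0.75x), heel-to-toe CoP
  progression, zero force in swing.
* ``squat`` — slow load modulation with a posterior CoP shift at depth.
* ``sts``  — sit-to-stand cycles: light seated load, a rising-phase force
  peak, posterior-to-anterior CoP shift.

Truth area forces are the kernel mass integrated over each area rectangle
(the six rectangles tile the insole envelope), rescaled so they sum to the
instantaneous load; truth area coordinates are the kernel centroids
truncated to each rectangle.  Stored GRF and CoP are recomputed from the
stored area forces and coordinates, so the trial is self-consistent with
the estimation combiners by construction.

The sensed stream degrades the truth three ways: (1) sensing-area
truncation — the kernel is integrated over the small sensor patch only, so
each channel underestimates its area force; (2) a first-order hysteresis
lag with a loading/unloading time-constant asymmetry; (3) additive Gaussian
noise, clipped at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as _dc_fields

import numpy as np
from scipy.interpolate import PchipInterpolator

from .feature_builder import build_feature_matrix
from .signal_conditioning import AREA_LABELS, ConditioningConfig
from .vfa_core import AreaGeometry, wma_cop_series

TASKS = ("scan", "gait1", "gait2", "squat", "sts")

#: Maximum half-side (cm) of the square sensing patch of each FSR, centred
#: on the sensor position — matching the ~20 cm² sensing area of the real
#: thin-film sensor it emulates.  Each patch is clipped to stay inside its
#: area rectangle, which is what makes the sensed channel a strict
#: underestimate of the area force.
PATCH_HALF_CM = 2.25


@dataclass
class SimulatorParams:
    """Physical and degradation parameters of the simulator."""

    body_weight: float = 700.0  # N, ~72 kg subject
    kernel_sigma: float = 2.5  # cm, pressure kernel spread
    noise_frac: float = 0.01  # channel noise sigma as fraction of body weight
    lag_tau: float = 0.08  # s, first-order hysteresis time constant (loading)
    lag_asym: float = 1.1  # unloading time constant multiplier
    force_floor: float = 0.05  # N, area forces below this count as unloaded
    fs: float = 50.0  # Hz
    stance_fraction: float = 0.62
    cycle_s: dict = field(
        default_factory=lambda: {"gait1": 2.0, "gait2": 1.4, "squat": 6.0, "sts": 8.0}
    )

    def to_dict(self) -> dict:
        return {
            "body_weight": self.body_weight,
            "kernel_sigma": self.kernel_sigma,
            "noise_frac": self.noise_frac,
            "lag_tau": self.lag_tau,
            "lag_asym": self.lag_asym,
            "force_floor": self.force_floor,
            "fs": self.fs,
            "stance_fraction": self.stance_fraction,
            "cycle_s": dict(self.cycle_s),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulatorParams":
        allowed = {f.name for f in _dc_fields(cls)}
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"unknown simulator key {sorted(unknown)[0]!r}")
        return cls(**d)


@dataclass
class SyntheticTrial:
    """Paired truth and sensed streams for one task."""

    task: str
    fs: float
    t: np.ndarray  # (n,)
    truth_F: np.ndarray  # (n, 6) area forces, N
    truth_xy: np.ndarray  # (n, 6, 2) area centroids, cm; NaN where unloaded
    truth_grf: np.ndarray  # (n,)
    truth_cop: np.ndarray  # (n, 2); NaN rows when unloaded
    sensed: np.ndarray  # (n, 6) degraded channels (truncation + lag + noise)
    sensed_clean: np.ndarray  # (n, 6) truncation stage only (pre-lag, pre-noise)
    body_weight: float
    seed: int
    params: SimulatorParams

    @property
    def n_frames(self) -> int:
        return self.t.size


# ---------------------------------------------------------------------------
# Gaussian kernel integrals over rectangles
# ---------------------------------------------------------------------------

_SQRT2 = math.sqrt(2.0)
_SQRT2PI = math.sqrt(2.0 * math.pi)


def _phi(z):
    return np.exp(-0.5 * z * z) / _SQRT2PI


def _Phi(z):
    from scipy.special import erf

    return 0.5 * (1.0 + erf(z / _SQRT2))


def _axis_mass_centroid(c: np.ndarray, lo: float, hi: float, sigma: float):
    """Mass fraction and centroid of N(c, sigma) truncated to [lo, hi]."""
    a = (lo - c) / sigma
    b = (hi - c) / sigma
    mass = _Phi(b) - _Phi(a)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = c + sigma * (_phi(a) - _phi(b)) / mass
    # degenerate (kernel far away): centroid falls back to the nearest edge
    mean = np.where(mass > 1e-300, mean, np.clip(c, lo, hi))
    return mass, np.clip(mean, lo, hi)


def _rect_mass_centroid(centers: np.ndarray, rect, sigma: float):
    """Kernel mass and 2-D centroid over a rectangle, per frame."""
    x0, x1, y0, y1 = rect
    mx, cx = _axis_mass_centroid(centers[:, 0], x0, x1, sigma)
    my, cy = _axis_mass_centroid(centers[:, 1], y0, y1, sigma)
    return mx * my, np.column_stack([cx, cy])


# ---------------------------------------------------------------------------
# Task profiles: total load (N) and kernel centre (cm) per frame
# ---------------------------------------------------------------------------

# Two-peak vertical GRF over normalized stance time (fraction of the load
# share); a monotone-piecewise interpolation of these knots has exactly two
# local maxima, at weight acceptance and push-off.
_GAIT_GRF_KNOTS = ([0.0, 0.08, 0.25, 0.50, 0.75, 0.92, 1.0],
                   [0.0, 0.55, 1.10, 0.75, 1.10, 0.55, 0.0])
# Heel-strike to toe-off CoP progression along the insole.
_GAIT_COPX_KNOTS = ([0.0, 0.15, 0.50, 0.85, 1.0], [3.0, 5.0, 13.0, 23.0, 26.0])
_GAIT_COPY_KNOTS = ([0.0, 0.30, 0.70, 1.0], [5.8, 4.8, 6.3, 5.2])

# Sit-to-stand cycle: share multiplier and anterior CoP shift on rising.
_STS_LOAD_KNOTS = ([0.0, 0.30, 0.45, 0.55, 0.80, 0.90, 1.0],
                   [0.30, 0.32, 1.15, 1.00, 1.00, 0.40, 0.30])
_STS_COPX_KNOTS = ([0.0, 0.30, 0.50, 0.65, 0.80, 1.0],
                   [7.0, 7.5, 15.0, 12.5, 12.5, 7.5])


def _pchip(knots):
    return PchipInterpolator(np.asarray(knots[0]), np.asarray(knots[1]))


def _profile(task: str, t: np.ndarray, p: SimulatorParams):
    """Return (load (n,), centre (n, 2), share) for a task."""
    bw = p.body_weight
    if task == "scan":
        share = 0.5 * bw
        theta = 2.0 * np.pi * t / 10.0  # one counter-clockwise loop per 10 s
        cx = 14.0 + 10.0 * np.cos(theta) + 1.5 * np.sin(2.0 * np.pi * t / 3.7)
        cy = 5.5 + 4.2 * np.sin(theta)
        load = np.full_like(t, share)
        return load, np.column_stack([cx, cy]), share
    if task in ("gait1", "gait2"):
        share = bw  # single support carries the whole body weight
        cycle = p.cycle_s[task]
        phase = (t / cycle) % 1.0
        stance = phase < p.stance_fraction
        s = np.where(stance, phase / p.stance_fraction, 0.0)
        load = np.where(stance, share * _pchip(_GAIT_GRF_KNOTS)(s), 0.0)
        cx = _pchip(_GAIT_COPX_KNOTS)(s)
        cy = _pchip(_GAIT_COPY_KNOTS)(s)
        return load, np.column_stack([cx, cy]), share
    if task == "squat":
        share = 0.5 * bw
        cycle = p.cycle_s["squat"]
        w = 2.0 * np.pi * t / cycle
        depth = 0.5 * (1.0 - np.cos(w))
        load = share * (1.0 - 0.22 * np.sin(w))
        cx = 12.0 - 4.0 * depth
        cy = 5.5 + 0.3 * np.sin(w)
        return load, np.column_stack([cx, cy]), share
    if task == "sts":
        share = 0.5 * bw
        cycle = p.cycle_s["sts"]
        phase = (t / cycle) % 1.0
        load = share * _pchip(_STS_LOAD_KNOTS)(phase)
        cx = _pchip(_STS_COPX_KNOTS)(phase)
        cy = 5.5 + 0.4 * np.sin(2.0 * np.pi * phase)
        return load, np.column_stack([cx, cy]), share
    raise ValueError(f"unknown task {task!r}; valid tasks: {', '.join(TASKS)}")


_GAIN_CACHE: dict = {}


def _patch_rect(geom: AreaGeometry, i: int) -> tuple[float, float, float, float]:
    """The sensing-patch rectangle of sensor ``i``, clipped to its area."""
    x0, x1, y0, y1 = geom.bounds[i]
    sx, sy = geom.sensor_xy[i]
    half = min(PATCH_HALF_CM, sx - x0, x1 - sx, sy - y0, y1 - sy)
    if half <= 0:
        raise ValueError(f"sensor {geom.labels[i]} sits on its area boundary")
    return (sx - half, sx + half, sy - half, sy + half)


def _sensor_gains(geom: AreaGeometry, sigma: float) -> np.ndarray:
    """Per-channel calibration gains of the simulated FSRs.

    A real FSR channel is gain-calibrated against a load applied directly
    on the sensor, so its reading approximates the local force on that
    scale; loads away from the patch are underestimated.  The gain used
    here is the largest factor that keeps the calibrated patch reading at
    or below the area force for *every* kernel position (evaluated on a
    fine grid over the insole envelope, with a small safety margin), which
    preserves the sensing-area-truncation property exactly.
    """
    key = (geom.sensor_xy.tobytes(), geom.bounds.tobytes(), float(sigma))
    if key in _GAIN_CACHE:
        return _GAIN_CACHE[key]
    ex, ey = geom.envelope
    gx, gy = np.meshgrid(np.arange(0.0, ex + 1e-9, 0.25), np.arange(0.0, ey + 1e-9, 0.25))
    centers = np.column_stack([gx.ravel(), gy.ravel()])
    gains = np.empty(6)
    for i in range(6):
        am, _ = _rect_mass_centroid(centers, geom.bounds[i], sigma)
        pm, _ = _rect_mass_centroid(centers, _patch_rect(geom, i), sigma)
        ok = pm > 1e-12
        gains[i] = 0.98 * float(np.min(am[ok] / pm[ok]))
    _GAIN_CACHE[key] = gains
    return gains


def _first_order_lag(x: np.ndarray, dt: float, tau: float, asym: float) -> np.ndarray:
    """Per-channel first-order lag with slower unloading (hysteresis)."""
    alpha_load = 1.0 - math.exp(-dt / tau)
    alpha_unload = 1.0 - math.exp(-dt / (tau * asym))
    out = np.empty_like(x)
    u = x[0].copy()
    out[0] = u
    for i in range(1, x.shape[0]):
        loading = x[i] > u
        alpha = np.where(loading, alpha_load, alpha_unload)
        u = u + alpha * (x[i] - u)
        out[i] = u
    return out


# ---------------------------------------------------------------------------
# Trial generation
# ---------------------------------------------------------------------------


def simulate_trial(
    task: str,
    duration: float,
    body_weight: float | None = None,
    seed: int = 0,
    params: SimulatorParams | None = None,
    geometry: AreaGeometry | None = None,
) -> SyntheticTrial:
    """Generate one paired (truth, sensed) trial.

    ``duration`` is in seconds (>= 5 s); ``body_weight`` overrides the
    simulator default.  Same seed and parameters give a bit-identical
    trial.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; valid tasks: {', '.join(TASKS)}")
    if duration < 5.0:
        raise ValueError(f"duration must be >= 5 s, got {duration}")
    p = params or SimulatorParams()
    if body_weight is not None:
        p = SimulatorParams.from_dict({**p.to_dict(), "body_weight": body_weight})
    geom = geometry or AreaGeometry()
    rng = np.random.default_rng(seed)

    dt = 1.0 / p.fs
    n = int(round(duration * p.fs))
    t = np.arange(n) * dt
    load, centers, _share = _profile(task, t, p)

    # kernel mass per area rectangle and per sensor patch
    area_mass = np.empty((n, 6))
    patch_mass = np.empty((n, 6))
    centroids = np.empty((n, 6, 2))
    for i in range(6):
        m, c = _rect_mass_centroid(centers, geom.bounds[i], p.kernel_sigma)
        area_mass[:, i] = m
        centroids[:, i] = c
        pm, _ = _rect_mass_centroid(centers, _patch_rect(geom, i), p.kernel_sigma)
        patch_mass[:, i] = pm

    env_mass = area_mass.sum(axis=1)  # the rectangles tile the envelope
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(env_mass > 0, load / np.where(env_mass > 0, env_mass, 1.0), 0.0)
    truth_F = area_mass * scale[:, None]
    gains = _sensor_gains(geom, p.kernel_sigma)
    sensed_clean = gains * patch_mass * scale[:, None]

    # unloaded areas: zero force, undefined centroid, zero sensed signal
    unloaded = truth_F < p.force_floor
    truth_F[unloaded] = 0.0
    sensed_clean[unloaded] = 0.0
    truth_xy = centroids.copy()
    truth_xy[unloaded] = np.nan

    truth_grf = truth_F.sum(axis=1)
    truth_cop = wma_cop_series(truth_F, truth_xy)

    sensed = _first_order_lag(sensed_clean, dt, p.lag_tau, p.lag_asym)
    if p.noise_frac > 0 and p.body_weight > 0:
        sensed = sensed + rng.normal(0.0, p.noise_frac * p.body_weight, sensed.shape)
    sensed = np.maximum(sensed, 0.0)

    return SyntheticTrial(
        task=task,
        fs=p.fs,
        t=t,
        truth_F=truth_F,
        truth_xy=truth_xy,
        truth_grf=truth_grf,
        truth_cop=truth_cop,
        sensed=sensed,
        sensed_clean=sensed_clean,
        body_weight=p.body_weight,
        seed=seed,
        params=p,
    )


def simulate_protocol(
    duration: float = 30.0,
    body_weight: float | None = None,
    seed: int = 0,
    params: SimulatorParams | None = None,
    geometry: AreaGeometry | None = None,
) -> list[SyntheticTrial]:
    """One trial per task, with per-task seeds derived from ``seed``."""
    return [
        simulate_trial(
            task,
            duration,
            body_weight=body_weight,
            seed=seed * 10 + k,
            params=params,
            geometry=geometry,
        )
        for k, task in enumerate(TASKS)
    ]


# ---------------------------------------------------------------------------
# Training matrices
# ---------------------------------------------------------------------------

TARGET_COLUMNS = tuple(
    [f"F_{a}" for a in AREA_LABELS]
    + [f"x_{a}" for a in AREA_LABELS]
    + [f"y_{a}" for a in AREA_LABELS]
)


def make_training_set(
    trials: list[SyntheticTrial],
    n_frames: int,
    seed: int = 0,
    conditioning: ConditioningConfig | None = None,
):
    """Sample a balanced training matrix from a set of trials.

    Draws ``n_frames`` rows with equal counts per task (within one frame),
    sampling frames without replacement after the sensed stream has been
    conditioned and expanded to features.  Returns ``(X, Y, tasks)`` where
    ``X`` is (n, 18) features, ``Y`` is (n, 18) targets ordered
    F_A..F_F, x_A..x_F, y_A..y_F (coordinates NaN where the area is
    unloaded) and ``tasks`` labels each row's task.
    """
    if not trials:
        raise ValueError("no trials given")
    tasks = sorted({tr.task for tr in trials}, key=TASKS.index)
    missing = [tk for tk in TASKS if tk not in tasks]
    if missing:
        raise ValueError(f"trials must cover all five tasks; missing {missing}")
    conditioning = conditioning or ConditioningConfig()
    rng = np.random.default_rng(seed)

    per_task = {tk: [] for tk in tasks}
    for tr in trials:
        dt = 1.0 / tr.fs
        cond = conditioning.condition(tr.t, tr.sensed)
        X = build_feature_matrix(cond, dt)
        Y = np.concatenate(
            [tr.truth_F, tr.truth_xy[:, :, 0], tr.truth_xy[:, :, 1]], axis=1
        )
        per_task[tr.task].append((X, Y))

    base = n_frames // len(tasks)
    extra = n_frames - base * len(tasks)
    X_parts, Y_parts, task_parts = [], [], []
    for k, tk in enumerate(tasks):
        want = base + (1 if k < extra else 0)
        Xt = np.concatenate([x for x, _ in per_task[tk]])
        Yt = np.concatenate([y for _, y in per_task[tk]])
        if want > Xt.shape[0]:
            raise ValueError(
                f"task {tk!r} has only {Xt.shape[0]} frames, need {want}; "
                "simulate longer trials or request fewer frames"
            )
        pick = rng.choice(Xt.shape[0], size=want, replace=False)
        pick.sort()
        X_parts.append(Xt[pick])
        Y_parts.append(Yt[pick])
        task_parts.extend([tk] * want)
    return (
        np.concatenate(X_parts),
        np.concatenate(Y_parts),
        np.array(task_parts),
    )
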