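"""Scoring of GRF/CoP estimators against reference streams.

Metrics follow the conventions of in-shoe pressure validation studies:
root-mean-square error for the GRF (N) and for the CoP the planar
Euclidean-distance RMSE in millimetres, plus Pearson correlation
coefficients for the GRF and each CoP axis.  Frames where either stream's
CoP is undefined (unloaded foot) are excluded from CoP metrics and the
exclusion count is reported; GRF metrics keep swing frames as zeros.

Also provides the hidden-width and data-amount scans used to pick the
regressor capacity and the training-set size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .feature_builder import build_feature_matrix
from .signal_conditioning import ConditioningConfig
from .synthetic_gait import SyntheticTrial, make_training_set
from .vfa_core import (
    LinearCoeffs,
    RegressorSpec,
    VfaModel,
    fixed_wma_cop_series,
    linear_force_estimate,
    train_regressor,
)


def rmse(est: np.ndarray, ref: np.ndarray) -> float:
    """Root-mean-square error between two equal-length series."""
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != ref.shape:
        raise ValueError(f"length mismatch: {est.shape} vs {ref.shape}")
    if est.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    return float(np.sqrt(np.mean((est - ref) ** 2)))


def rmse_planar(est: np.ndarray, ref: np.ndarray) -> float:
    """Planar distance RMSE between two (n, 2) coordinate series."""
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != ref.shape or est.ndim != 2 or est.shape[1] != 2:
        raise ValueError("expected matching (n, 2) coordinate series")
    if est.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    d2 = ((est - ref) ** 2).sum(axis=1)
    return float(np.sqrt(np.mean(d2)))


def correlation(est: np.ndarray, ref: np.ndarray) -> float:
    """Pearson correlation coefficient; NaN (with a warning) if either
    series has zero variance."""
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != ref.shape:
        raise ValueError(f"length mismatch: {est.shape} vs {ref.shape}")
    if np.ptp(est) == 0.0 or np.ptp(ref) == 0.0:
        warnings.warn("zero-variance series; correlation undefined", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(est, ref)[0, 1])


@dataclass
class TrialMetrics:
    """Per-trial, per-estimator scores."""

    task: str
    estimator: str  # "VFA", "WMA" or "linear"
    rmse_grf: float
    rmse_cop_mm: float
    rmse_x_mm: float
    rmse_y_mm: float
    cc_grf: float
    cc_x: float
    cc_y: float
    n_frames: int
    n_excluded: int


def _cop_metrics(est_cop: np.ndarray, ref_cop: np.ndarray):
    """CoP scores on frames where both streams are defined (cm in, mm out)."""
    ok = np.all(np.isfinite(est_cop), axis=1) & np.all(np.isfinite(ref_cop), axis=1)
    n_exc = int(est_cop.shape[0] - ok.sum())
    if ok.sum() < 2:
        nan = float("nan")
        return nan, nan, nan, nan, nan, n_exc
    e, r = est_cop[ok], ref_cop[ok]
    return (
        10.0 * rmse_planar(e, r),
        10.0 * rmse(e[:, 0], r[:, 0]),
        10.0 * rmse(e[:, 1], r[:, 1]),
        correlation(e[:, 0], r[:, 0]),
        correlation(e[:, 1], r[:, 1]),
        n_exc,
    )


def evaluate_trial(
    model: VfaModel, trial: SyntheticTrial, linear_coeffs: LinearCoeffs | None = None
) -> list[TrialMetrics]:
    """Score the trained estimator and the WMA baseline on one trial."""
    pred = model.predict_raw(trial.t, trial.sensed)
    rows = []

    cop_mm, x_mm, y_mm, cc_x, cc_y, n_exc = _cop_metrics(pred["cop"], trial.truth_cop)
    rows.append(
        TrialMetrics(
            task=trial.task,
            estimator="VFA",
            rmse_grf=rmse(pred["grf"], trial.truth_grf),
            rmse_cop_mm=cop_mm,
            rmse_x_mm=x_mm,
            rmse_y_mm=y_mm,
            cc_grf=correlation(pred["grf"], trial.truth_grf),
            cc_x=cc_x,
            cc_y=cc_y,
            n_frames=trial.n_frames,
            n_excluded=n_exc,
        )
    )

    cond = pred["conditioned"]
    wma_cop = fixed_wma_cop_series(cond, model.geometry)
    wma_grf = cond.sum(axis=1)  # naive baseline: sum of channel readings
    cop_mm, x_mm, y_mm, cc_x, cc_y, n_exc = _cop_metrics(wma_cop, trial.truth_cop)
    rows.append(
        TrialMetrics(
            task=trial.task,
            estimator="WMA",
            rmse_grf=rmse(wma_grf, trial.truth_grf),
            rmse_cop_mm=cop_mm,
            rmse_x_mm=x_mm,
            rmse_y_mm=y_mm,
            cc_grf=correlation(wma_grf, trial.truth_grf),
            cc_x=cc_x,
            cc_y=cc_y,
            n_frames=trial.n_frames,
            n_excluded=n_exc,
        )
    )

    if linear_coeffs is not None:
        lin_grf = np.array(
            [linear_force_estimate(row, linear_coeffs) for row in cond]
        )
        rows.append(
            TrialMetrics(
                task=trial.task,
                estimator="linear",
                rmse_grf=rmse(lin_grf, trial.truth_grf),
                rmse_cop_mm=float("nan"),
                rmse_x_mm=float("nan"),
                rmse_y_mm=float("nan"),
                cc_grf=correlation(lin_grf, trial.truth_grf),
                cc_x=float("nan"),
                cc_y=float("nan"),
                n_frames=trial.n_frames,
                n_excluded=trial.n_frames,
            )
        )
    return rows


def evaluate_suite(
    model: VfaModel,
    trials: list[SyntheticTrial],
    linear_coeffs: LinearCoeffs | None = None,
) -> pd.DataFrame:
    """Per-task, per-estimator metric table for a set of trials.

    Rows are sorted by (task, estimator) so the result does not depend on
    trial order.
    """
    rows: list[TrialMetrics] = []
    for trial in trials:
        rows.extend(evaluate_trial(model, trial, linear_coeffs))
    df = pd.DataFrame([asdict(r) for r in rows])
    return df.sort_values(["task", "estimator"], kind="stable").reset_index(drop=True)


def comparison_summary(df: pd.DataFrame) -> pd.DataFrame:
    """Unweighted per-task means plus the VFA-minus-WMA CoP RMSE delta."""
    mean = (
        df.groupby(["task", "estimator"], as_index=False)[
            ["rmse_grf", "rmse_cop_mm", "cc_grf", "cc_x", "cc_y"]
        ].mean()
    )
    wide = mean.pivot(index="task", columns="estimator", values="rmse_cop_mm")
    if {"VFA", "WMA"} <= set(wide.columns):
        wide["vfa_minus_wma_mm"] = wide["VFA"] - wide["WMA"]
    return wide.reset_index()


# ---------------------------------------------------------------------------
# Capacity and data-amount scans
# ---------------------------------------------------------------------------


def hyperparameter_scan(
    widths: list[int],
    X: np.ndarray,
    Y_forces: np.ndarray,
    seed: int = 0,
    base_spec: RegressorSpec | None = None,
) -> pd.DataFrame:
    """Train one force-net set per hidden width; report mean held-out scores.

    ``Y_forces`` is the (n, 6) area-force target block.  All widths share
    the same seed so the split is identical across rows.
    """
    base = base_spec or RegressorSpec()
    rows = []
    for w in widths:
        rmses, ccs = [], []
        for i in range(6):
            spec = RegressorSpec.from_dict(
                {**base.to_dict(), "n_hidden": int(w), "seed": seed + i}
            )
            net = train_regressor(X, Y_forces[:, i], spec)
            rmses.append(net.test_rmse)
            # correlation on the net's held-out split
            rng = np.random.default_rng(spec.seed)
            perm = rng.permutation(X.shape[0])
            n_tr = int(round(spec.split[0] * X.shape[0]))
            n_val = int(round(spec.split[1] * X.shape[0]))
            idx_te = perm[n_tr + n_val :]
            pred = net.predict(X[idx_te])
            ref = Y_forces[idx_te, i]
            ccs.append(correlation(pred, ref) if np.ptp(ref) > 0 else np.nan)
        rows.append(
            {
                "n_hidden": int(w),
                "mean_test_rmse": float(np.mean(rmses)),
                "mean_test_cc": float(np.nanmean(ccs)),
            }
        )
    return pd.DataFrame(rows)


def data_amount_scan(
    frame_counts: list[int],
    trials_train: list[SyntheticTrial],
    trials_eval: list[SyntheticTrial],
    seed: int = 0,
    force_spec: RegressorSpec | None = None,
) -> pd.DataFrame:
    """Force-net error as a function of training-set size.

    For each count a balanced training set is drawn from ``trials_train``,
    six force nets are trained, and the mean GRF-component RMSE is measured
    on a fixed evaluation set built from ``trials_eval`` — the common
    yardstick that makes errors comparable across counts.
    """
    base = force_spec or RegressorSpec()
    Xe_parts, Fe_parts = [], []
    for tr in trials_eval:
        cond = ConditioningConfig().condition(tr.t, tr.sensed)
        Xe_parts.append(build_feature_matrix(cond, 1.0 / tr.fs))
        Fe_parts.append(tr.truth_F)
    X_eval = np.concatenate(Xe_parts)
    F_eval = np.concatenate(Fe_parts)

    rows = []
    for count in frame_counts:
        X, Y, _tasks = make_training_set(trials_train, int(count), seed=seed)
        rmses = []
        for i in range(6):
            spec = RegressorSpec.from_dict(
                {**base.to_dict(), "seed": seed + i}
            )
            net = train_regressor(X, Y[:, i], spec)
            rmses.append(rmse(net.predict(X_eval), F_eval[:, i]))
        rows.append({"n_frames": int(count), "mean_eval_rmse": float(np.mean(rmses))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Optional plots
# ---------------------------------------------------------------------------


def plot_cop_trajectory(model: VfaModel, trial: SyntheticTrial, ax=None):
    """Overlay reference, estimated and baseline CoP paths (needs matplotlib)."""
    import matplotlib.pyplot as plt

    pred = model.predict_raw(trial.t, trial.sensed)
    wma = fixed_wma_cop_series(pred["conditioned"], model.geometry)
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(*trial.truth_cop.T, label="reference", lw=1.5)
    ax.plot(*pred["cop"].T, label="VFA", lw=1.0)
    ax.plot(*wma.T, label="WMA", lw=1.0, ls="--")
    ax.scatter(*model.geometry.sensor_xy.T, c="gray", edgecolors="k", zorder=3,
               label="sensors")
    ax.set_xlabel("x (cm)")
    ax.set_ylabel("y (cm)")
    ax.set_title(f"CoP trajectory — {trial.task}")
    ax.legend()
    return ax


def plot_grf_trace(model: VfaModel, trial: SyntheticTrial, ax=None):
    """Reference vs estimated GRF over time (needs matplotlib)."""
    import matplotlib.pyplot as plt

    pred = model.predict_raw(trial.t, trial.sensed)
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(trial.t, trial.truth_grf, label="reference", lw=1.5)
    ax.plot(trial.t, pred["grf"], label="VFA", lw=1.0)
    ax.set_xlabel("t (s)")
    ax.set_ylabel("GRF (N)")
    ax.set_title(f"GRF — {trial.task}")
    ax.legend()
    return ax
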