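"""Mono-exponential relaxation-time fitting for spin-lock (T1rho) and multi-echo (T2)
magnitude image series.

A voxel's signal across preparation times t (spin-lock times TSL for T1rho, echo times
TE for T2) is modelled as

    S(t) = S0 * exp(-t / T)

and (S0, T) are estimated per voxel by unweighted nonlinear least squares using the
Levenberg-Marquardt algorithm.  Magnitude data are fitted as-is, with no noise-floor
(Rician) correction and no weighting.  Fitted maps are cleaned by an upper threshold on
T — by default 100 ms for T1rho and 80 ms for T2 — which removes voxels dominated by
synovial fluid or partial-volume effects.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .errors import InputError

__all__ = [
    "Contrast",
    "EchoSeries",
    "FitResult",
    "RelaxationMap",
    "fit_monoexponential",
    "fit_map",
    "apply_upper_threshold",
    "DEFAULT_UPPER_THRESHOLD_MS",
]


class Contrast(str, enum.Enum):
    """Which relaxation mechanism the series encodes."""

    T1RHO = "t1rho"
    T2 = "t2"


#: Upper cut-offs (ms) applied to fitted maps to suppress fluid / partial-volume voxels.
DEFAULT_UPPER_THRESHOLD_MS: dict[Contrast, float] = {
    Contrast.T1RHO: 100.0,
    Contrast.T2: 80.0,
}

#: Default preparation-time grids (ms) of the acquisition protocol.
DEFAULT_TIMES_MS: dict[Contrast, tuple[float, ...]] = {
    Contrast.T1RHO: (0.0, 15.0, 30.0, 45.0),
    Contrast.T2: (0.0, 10.4, 20.8, 41.6),
}


@dataclass
class EchoSeries:
    """A 4-D stack of magnitude images indexed by preparation time.

    Parameters
    ----------
    signals
        Array of shape ``(slices, rows, cols, n_times)``; nonnegative magnitudes.
    times_ms
        Strictly increasing preparation times in ms (TSL or TE), length >= 3.
    contrast
        Whether ``times_ms`` are spin-lock times (T1rho) or echo times (T2).
    """

    signals: np.ndarray
    times_ms: np.ndarray
    contrast: Contrast

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.contrast = Contrast(self.contrast)
        if self.signals.ndim != 4:
            raise InputError(
                f"signals must be 4-D (slices, rows, cols, times); got {self.signals.ndim}-D"
            )
        if self.times_ms.ndim != 1 or self.times_ms.size < 3:
            raise InputError("times_ms must be a vector with at least 3 entries")
        if self.signals.shape[-1] != self.times_ms.size:
            raise InputError(
                f"last signal axis ({self.signals.shape[-1]}) must match number of "
                f"times ({self.times_ms.size})"
            )
        if self.times_ms[0] < 0 or np.any(np.diff(self.times_ms) <= 0):
            raise InputError("times_ms must be strictly increasing and start at >= 0")
        if not np.all(np.isfinite(self.signals)) or np.any(self.signals < 0):
            raise InputError("signals must be finite and nonnegative")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.signals.shape[:3]

    @property
    def slice_count(self) -> int:
        return self.signals.shape[0]


@dataclass(frozen=True)
class FitResult:
    """Outcome of a single-voxel mono-exponential fit."""

    amplitude: float
    relaxation_time: float
    residual_ss: float
    fit_ok: bool


@dataclass
class RelaxationMap:
    """Per-voxel relaxation times (ms) with amplitudes and a validity mask.

    ``valid`` marks voxels with a successful fit that survived any thresholding.
    ``upper_threshold_ms`` is ``inf`` until :func:`apply_upper_threshold` runs.
    """

    values: np.ndarray
    amplitudes: np.ndarray
    valid: np.ndarray
    contrast: Contrast
    upper_threshold_ms: float = math.inf

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.contrast = Contrast(self.contrast)
        if not (self.values.shape == self.amplitudes.shape == self.valid.shape):
            raise InputError("values, amplitudes and valid must share one shape")
        if self.values.ndim != 3:
            raise InputError("relaxation maps are 3-D (slices, rows, cols)")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def slice_count(self) -> int:
        return self.values.shape[0]

    def copy(self) -> "RelaxationMap":
        return RelaxationMap(
            self.values.copy(),
            self.amplitudes.copy(),
            self.valid.copy(),
            self.contrast,
            self.upper_threshold_ms,
        )


def _initial_guess(times: np.ndarray, signals: np.ndarray) -> tuple[float, float]:
    # Two-point closed-form start: S0 from the first sample, T from the log-ratio of the
    # first and last samples (clipped so a non-decaying pair still yields a positive T).
    s0 = float(signals[0]) if signals[0] > 0 else float(np.max(signals))
    span = float(times[-1] - times[0])
    if signals[0] > 0 and signals[-1] > 0:
        log_ratio = math.log(signals[0] / signals[-1])
    else:
        log_ratio = 1.0
    t0 = span / max(log_ratio, 1e-6)
    t0 = min(max(t0, 1e-3), 10.0 * float(times[-1]))
    return s0, t0


def fit_monoexponential(
    times_ms,
    signals,
    initial_guess: tuple[float, float] | None = None,
    divergence_cap_factor: float = 10.0,
) -> FitResult:
    """Fit ``S(t) = S0 * exp(-t/T)`` to one voxel's decay by Levenberg-Marquardt.

    Parameters
    ----------
    times_ms, signals
        Matching vectors (>= 3 points); signals nonnegative.
    initial_guess
        Optional ``(S0, T)`` start; defaults to a closed-form two-point estimate.
    divergence_cap_factor
        Fits with ``T > cap_factor * max(times)`` are marked failed: at the sampled
        times such a decay is indistinguishable from a constant signal.

    Returns
    -------
    FitResult
        ``fit_ok`` is False (never an exception) when the optimizer fails, T <= 0,
        T exceeds the divergence cap, or the signals are all zero.
    """
    times = np.asarray(times_ms, dtype=float)
    sig = np.asarray(signals, dtype=float)
    if times.ndim != 1 or sig.ndim != 1 or times.size != sig.size:
        raise InputError("times and signals must be matching vectors")
    if times.size < 3:
        raise InputError("at least 3 points are required for a mono-exponential fit")
    if np.any(sig < 0):
        raise InputError("signals must be nonnegative")

    if not np.any(sig > 0):
        return FitResult(0.0, math.nan, float(np.sum(sig**2)), False)

    x0 = np.array(initial_guess if initial_guess is not None else _initial_guess(times, sig))

    def residuals(p):
        return p[0] * np.exp(-times / p[1]) - sig

    def jac(p):
        e = np.exp(-times / p[1])
        return np.column_stack([e, p[0] * times * e / p[1] ** 2])

    try:
        sol = least_squares(
            residuals, x0, jac=jac, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14,
            max_nfev=200,
        )
    except Exception:
        return FitResult(math.nan, math.nan, math.nan, False)

    s0_hat, t_hat = float(sol.x[0]), float(sol.x[1])
    rss = float(np.sum(sol.fun**2))
    cap = divergence_cap_factor * float(times[-1])
    ok = (
        sol.success
        and math.isfinite(t_hat)
        and math.isfinite(s0_hat)
        and 0.0 < t_hat <= cap
        and s0_hat > 0.0
    )
    return FitResult(s0_hat, t_hat, rss, bool(ok))


def fit_map(series: EchoSeries, mask: np.ndarray, divergence_cap_factor: float = 10.0) -> RelaxationMap:
    """Fit every in-mask voxel of a series; out-of-mask or failed voxels are invalid.

    No upper threshold is applied here — the returned map carries an ``inf`` threshold
    sentinel until :func:`apply_upper_threshold` runs.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.grid_shape:
        raise InputError(
            f"mask shape {mask.shape} does not match series grid {series.grid_shape}"
        )
    shape = series.grid_shape
    values = np.full(shape, np.nan)
    amplitudes = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)
    times = series.times_ms
    for idx in np.argwhere(mask):
        i, j, k = idx
        res = fit_monoexponential(
            times, series.signals[i, j, k], divergence_cap_factor=divergence_cap_factor
        )
        if res.fit_ok:
            values[i, j, k] = res.relaxation_time
            amplitudes[i, j, k] = res.amplitude
            valid[i, j, k] = True
    return RelaxationMap(values, amplitudes, valid, series.contrast)


def apply_upper_threshold(rmap: RelaxationMap, threshold_ms: float | None = None) -> RelaxationMap:
    """Invalidate voxels whose relaxation time strictly exceeds the upper threshold.

    The default threshold is 100 ms for T1rho and 80 ms for T2.  The comparison is
    strict, so a voxel exactly at the threshold is retained.  Idempotent and monotone:
    re-applying the same threshold changes nothing, and lowering the threshold never
    re-validates a voxel.
    """
    thr = DEFAULT_UPPER_THRESHOLD_MS[rmap.contrast] if threshold_ms is None else float(threshold_ms)
    out = rmap.copy()
    with np.errstate(invalid="ignore"):
        out.valid &= ~(out.values > thr)
    out.upper_threshold_ms = min(thr, rmap.upper_threshold_ms)
    return out
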