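"""Multi-echo BOLD T2* mapping and optimal echo combination.

Gradient-echo signal decays across echo times as S(TE) = S0 * exp(-TE/T2*).
Each voxel's decay is fitted with a monoexponential model: a log-linear
regression of ln S on TE provides the exact closed-form initial values, and a
nonlinear least-squares refinement minimises the sum of squared residuals in
signal space. Echoes with non-positive signal in a voxel are dropped so the
fit uses the maximum number of reliable echoes; voxels left with fewer than
two reliable echoes, or with T2* outside the physiological clamp (1, 500) ms,
are marked invalid.

The fitted T2* map then weights the per-echo BOLD series into a single
optimally combined series using contrast-to-noise weights

    w_i  proportional to  TE_i * exp(-TE_i / T2*),   sum_i w_i = 1.

Voxels without a valid T2* fall back to the unweighted echo mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "MultiEchoSeries",
    "T2StarMap",
    "fit_monoexponential",
    "fit_t2star_map",
    "optimal_combine",
    "combination_weights",
]

T2STAR_MIN_MS = 1.0
T2STAR_MAX_MS = 500.0


@dataclass
class MultiEchoSeries:
    """Per-echo 4-D volumes (x, y, z, t) with increasing echo times in ms."""

    echo_volumes: list
    te_ms: np.ndarray

    def __post_init__(self) -> None:
        self.te_ms = np.asarray(self.te_ms, dtype=float)
        self.echo_volumes = [np.asarray(v, dtype=float) for v in self.echo_volumes]
        if len(self.echo_volumes) < 2:
            raise ValueError("need at least 2 echoes")
        if self.te_ms.size != len(self.echo_volumes):
            raise ValueError("one echo time per echo volume required")
        if np.any(self.te_ms <= 0) or np.any(np.diff(self.te_ms) <= 0):
            raise ValueError("echo times must be positive and strictly increasing")
        shape = self.echo_volumes[0].shape
        if any(v.shape != shape for v in self.echo_volumes):
            raise ValueError("all echo volumes must share lattice and frame count")

    @property
    def n_echoes(self) -> int:
        return len(self.echo_volumes)

    @property
    def spatial_shape(self) -> tuple:
        return self.echo_volumes[0].shape[:3]


@dataclass
class T2StarMap:
    """Per-voxel T2* (ms) and S0; invalid voxels are NaN with valid=False."""

    t2star_ms: np.ndarray
    s0: np.ndarray
    valid: np.ndarray


def _loglinear(signal: np.ndarray, te: np.ndarray) -> tuple[float, float]:
    # exact log-linear solution: ln S = ln S0 - TE / T2*
    slope, intercept = np.polyfit(te, np.log(signal), 1)
    s0 = float(np.exp(intercept))
    t2 = np.inf if slope >= 0 else float(-1.0 / slope)
    return s0, t2


def fit_monoexponential(signal_by_echo, te_ms) -> tuple[float, float]:
    """Fit S(TE) = S0 exp(-TE/T2*) for one voxel; returns (S0, T2* in ms).

    Echoes with non-positive signal are dropped. With exactly two reliable
    echoes the closed-form (log-linear) solution is returned; with more, the
    log-linear estimate initialises a nonlinear least-squares refinement in
    signal space. T2* outside (1, 500) ms marks the voxel as a fit failure.
    """
    s = np.asarray(signal_by_echo, dtype=float)
    te = np.asarray(te_ms, dtype=float)
    if s.shape != te.shape:
        raise ValueError("signal and TE arrays must have equal length")
    reliable = s > 0
    s, te = s[reliable], te[reliable]
    if s.size < 2:
        raise ValueError("fewer than 2 reliable echoes; voxel fit failed")
    s0, t2 = _loglinear(s, te)
    sse0 = np.sum((s0 * np.exp(-te / t2) - s) ** 2) if np.isfinite(t2) else np.inf
    if s.size > 2 and np.isfinite(t2) and sse0 > 1e-14 * np.sum(s**2):
        def resid(p):
            return p[0] * np.exp(-te / p[1]) - s

        sol = least_squares(resid, x0=[s0, t2], ftol=1e-8, xtol=1e-12, max_nfev=200)
        if np.sum(sol.fun**2) <= np.sum(resid([s0, t2]) ** 2):
            s0, t2 = float(sol.x[0]), float(sol.x[1])
    if not (T2STAR_MIN_MS < t2 < T2STAR_MAX_MS) or s0 <= 0:
        raise ValueError(f"T2* = {t2:.3g} ms outside the physiological clamp; voxel invalid")
    return s0, t2


def fit_t2star_map(series: MultiEchoSeries) -> T2StarMap:
    """Voxelwise monoexponential fit on the time-averaged echo signals."""
    means = np.stack([v.mean(axis=-1) for v in series.echo_volumes], axis=-1)
    shape = series.spatial_shape
    t2 = np.full(shape, np.nan)
    s0 = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)
    for idx in np.ndindex(shape):
        try:
            s0_v, t2_v = fit_monoexponential(means[idx], series.te_ms)
        except ValueError:
            continue
        s0[idx], t2[idx] = s0_v, t2_v
        valid[idx] = True
    return T2StarMap(t2star_ms=t2, s0=s0, valid=valid)


def combination_weights(te_ms: np.ndarray, t2star_ms: float) -> np.ndarray:
    """Normalised contrast-to-noise weights w_i ~ TE_i exp(-TE_i/T2*)."""
    te = np.asarray(te_ms, dtype=float)
    w = te * np.exp(-te / t2star_ms)
    return w / w.sum()


def optimal_combine(series: MultiEchoSeries, t2star: T2StarMap) -> np.ndarray:
    """Combine echoes into one 4-D series with T2*-weighted averaging.

    Per voxel, combined(t) = sum_i w_i S_i(t) with w_i normalised to 1.
    Voxels with an invalid T2* fall back to the unweighted echo mean.
    """
    if t2star.t2star_ms.shape != series.spatial_shape:
        raise ValueError("T2* map lattice does not match the echo volumes")
    stack = np.stack(series.echo_volumes, axis=0)  # (echo, x, y, z, t)
    te = series.te_ms
    t2 = t2star.t2star_ms
    with np.errstate(invalid="ignore", divide="ignore"):
        w = te[:, None, None, None] * np.exp(-te[:, None, None, None] / t2[None])
        wsum = w.sum(axis=0)
        w = np.where(t2star.valid[None], w / wsum, 1.0 / series.n_echoes)
    combined = np.einsum("exyz,exyzt->xyzt", w, stack)
    return combined
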