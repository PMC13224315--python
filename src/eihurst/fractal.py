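"""Exact simulation of fractional Gaussian noise (fGn) and fractional
Brownian motion (fBm).

fGn with Hurst exponent H in (0, 1) is the stationary-increment process whose
autocovariance is

    gamma(k) = (sigma^2 / 2) * (|k-1|^{2H} - 2|k|^{2H} + |k+1|^{2H}),

and fBm is its cumulative sum. Sample paths are generated by circulant
embedding (Davies-Harte), which is exact: the simulated series has the target
covariance in finite samples, not just asymptotically. That exactness is what
makes these paths usable as ground truth when validating spectral Hurst
estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FgnSpec",
    "TimeSeries",
    "fgn_autocovariance",
    "simulate_fgn",
    "simulate_fgn_batch",
    "simulate_fbm",
    "write_tsv",
]


@dataclass(frozen=True)
class FgnSpec:
    """Parameters of a fractional-Gaussian-noise sample path.

    Parameters
    ----------
    hurst : float
        Target Hurst exponent, strictly inside (0, 1).
    sigma : float
        Standard deviation of the increments (arbitrary units), > 0.
    length : int
        Number of samples, >= 8.
    sampling_interval : float
        Sampling interval in seconds; carried on the output series and used
        only to scale the frequency axis downstream.
    seed : int
        Seed for the random generator; identical specs yield identical paths.
    """

    hurst: float
    sigma: float = 1.0
    length: int = 1024
    sampling_interval: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.hurst < 1.0):
            raise ValueError(f"hurst must lie strictly in (0, 1); got {self.hurst}")
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive; got {self.sigma}")
        if self.length < 8:
            raise ValueError(f"length must be >= 8; got {self.length}")
        if not self.sampling_interval > 0:
            raise ValueError(f"sampling_interval must be positive; got {self.sampling_interval}")


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled real-valued signal."""

    values: np.ndarray
    sampling_interval: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("TimeSeries requires a 1-D sequence of length >= 2")
        if not np.all(np.isfinite(values)):
            raise ValueError("TimeSeries values must all be finite")
        if not self.sampling_interval > 0:
            raise ValueError("sampling_interval must be positive")

    def __len__(self) -> int:
        return self.values.size


def fgn_autocovariance(hurst: float, sigma: float, max_lag: int) -> np.ndarray:
    """Autocovariance gamma(k), k = 0..max_lag, of fGn with given H and sigma.

    gamma(0) equals sigma**2; for H = 0.5 all lags k >= 1 vanish (white noise).
    """
    if not (0.0 < hurst < 1.0):
        raise ValueError(f"hurst must lie strictly in (0, 1); got {hurst}")
    if not sigma > 0:
        raise ValueError(f"sigma must be positive; got {sigma}")
    if max_lag < 0:
        raise ValueError(f"max_lag must be >= 0; got {max_lag}")
    k = np.arange(max_lag + 1, dtype=float)
    two_h = 2.0 * hurst
    gamma = 0.5 * sigma**2 * (np.abs(k - 1) ** two_h - 2.0 * np.abs(k) ** two_h + (k + 1) ** two_h)
    return gamma


def _embedding_eigenvalues(spec: FgnSpec) -> np.ndarray:
    """Eigenvalues of the circulant embedding of the fGn covariance.

    Embedding size is the next power of two >= 2*(length - 1), for exactness
    and FFT efficiency. fGn embeddings are non-negative definite in theory; a
    materially negative eigenvalue indicates a defect and is raised, never
    clipped, so that ground-truth validity is preserved.
    """
    n = spec.length
    m = 1
    while m < 2 * (n - 1):
        m *= 2
    gamma = fgn_autocovariance(spec.hurst, spec.sigma, m // 2)
    # circular covariance: gamma(0..m/2) then mirrored gamma(m/2-1..1)
    circ = np.concatenate([gamma, gamma[-2:0:-1]])
    eig = np.fft.fft(circ).real
    tol = 1e-10 * eig.max()
    if eig.min() < -tol:
        raise RuntimeError(
            "circulant embedding produced a negative eigenvalue "
            f"({eig.min():.3e}); double the embedding grid and retry"
        )
    return np.clip(eig, 0.0, None)


def simulate_fgn_batch(spec: FgnSpec, n_series: int) -> np.ndarray:
    """Simulate ``n_series`` independent fGn paths sharing one spec.

    Returns an array of shape (n_series, spec.length). The single-path
    ``simulate_fgn(spec)`` equals row 0 of ``simulate_fgn_batch(spec, 1)``.
    """
    if n_series < 1:
        raise ValueError("n_series must be >= 1")
    eig = _embedding_eigenvalues(spec)
    m = eig.size
    rng = np.random.default_rng(spec.seed)
    half = m // 2
    # Davies-Harte: Hermitian-symmetric complex Gaussian weights per eigenvalue
    w = np.empty((n_series, m), dtype=complex)
    w[:, 0] = rng.standard_normal(n_series)
    w[:, half] = rng.standard_normal(n_series)
    re = rng.standard_normal((n_series, half - 1))
    im = rng.standard_normal((n_series, half - 1))
    w[:, 1:half] = (re + 1j * im) / np.sqrt(2.0)
    w[:, half + 1 :] = np.conj(w[:, half - 1 : 0 : -1])
    path = np.fft.fft(np.sqrt(eig / m)[None, :] * w, axis=1).real[:, : spec.length]
    return path


def simulate_fgn(spec: FgnSpec) -> TimeSeries:
    """Draw one exact fGn sample path; deterministic given ``spec.seed``."""
    values = simulate_fgn_batch(spec, 1)[0]
    return TimeSeries(values=values, sampling_interval=spec.sampling_interval)


def simulate_fbm(spec: FgnSpec) -> TimeSeries:
    """Fractional Brownian motion: cumulative sum of the fGn path.

    The first value equals the first increment, so differencing (with the
    first sample prepended) recovers the fGn path exactly.
    """
    fgn = simulate_fgn(spec)
    return TimeSeries(values=np.cumsum(fgn.values), sampling_interval=spec.sampling_interval)


def write_tsv(series: TimeSeries, path) -> None:
    """Export a series as plain two-column TSV (time_s, value)."""
    t = np.arange(len(series)) * series.sampling_interval
    data = np.column_stack([t, series.values])
    np.savetxt(path, data, delimiter="\t", header="time_s\tvalue", comments="")
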