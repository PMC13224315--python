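"""Spectral Hurst-exponent estimation for BOLD-like signals.

The estimator follows the Welch-PSD route: the one-sided power spectral
density of a voxel's time series is estimated with Welch's method (8 windows,
50% overlap by default), log10 power is regressed on log10 frequency over the
full positive-frequency spectrum, the spectral index beta = -slope is
converted to the Hurst exponent via

    H = (1 + beta) / 2,

and the "extended Hurst" convention classifies the signal: H in (0, 1) is
fractional Gaussian noise (stationary), H in (1, 2) is fractional Brownian
motion (non-stationary with stationary increments). H = 0.5 corresponds to
uncorrelated white noise; persistent long-range temporal correlations push H
toward 1 and beyond.

Voxelwise maps and the grey-matter-within-MRS-voxel ROI mean reproduce the
whole-brain workflow: H is computed for every voxel, invalid voxels carry the
sentinel 0, and the ROI mean uses only non-zero voxels inside the mask
intersection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import signal as sps

from eihurst.fractal import TimeSeries

__all__ = [
    "SignalClass",
    "PsdEstimate",
    "HurstFit",
    "HurstMap",
    "HurstModel",
    "welch_psd",
    "fit_spectral_index",
    "beta_to_hurst",
    "classify_signal",
    "hurst_map",
    "roi_mean_hurst",
]


class SignalClass(str, Enum):
    FGN = "fGn"
    FBM = "fBm"
    OUT_OF_RANGE = "out_of_range"


@dataclass(frozen=True)
class PsdEstimate:
    """One-sided Welch power spectral density of a time series."""

    frequencies_hz: np.ndarray
    power: np.ndarray
    n_segments: int
    overlap_fraction: float
    window_name: str

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies_hz, dtype=float)
        p = np.asarray(self.power, dtype=float)
        object.__setattr__(self, "frequencies_hz", f)
        object.__setattr__(self, "power", p)
        if f.shape != p.shape:
            raise ValueError("frequencies and power must have the same length")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if not np.all(np.isfinite(p)) or np.any(p < 0):
            raise ValueError("power must be finite and non-negative")


@dataclass(frozen=True)
class HurstFit:
    """Result of a spectral-index fit for one series.

    Attributes
    ----------
    beta : float
        Spectral index, PSD ~ f^{-beta} (minus the log-log slope).
    hurst : float
        Extended Hurst exponent, (1 + beta) / 2 exactly.
    intercept : float
        log10 power at log10 frequency = 0.
    r_squared : float
        Coefficient of determination of the log-log fit.
    n_bins : int
        Number of frequency bins used in the regression.
    signal_class : SignalClass
        fGn for H in (0, 1), fBm for H in [1, 2), out_of_range otherwise.
    """

    beta: float
    hurst: float
    intercept: float
    r_squared: float
    n_bins: int
    signal_class: SignalClass

    def summary(self) -> str:
        lines = [
            "Spectral Hurst fit",
            "------------------",
            f"beta (spectral index)  {self.beta: .4f}",
            f"H = (1 + beta)/2       {self.hurst: .4f}",
            f"signal class           {self.signal_class.value}",
            f"log10 intercept        {self.intercept: .4f}",
            f"fit r^2                {self.r_squared: .4f}",
            f"frequency bins used    {self.n_bins}",
        ]
        return "\n".join(lines)


class HurstModel:
    """Spectral Hurst estimator for a single time series.

    Statsmodels-style: construct from data, call :meth:`fit` for a
    :class:`HurstFit` result.

    Parameters
    ----------
    values : array-like
        The signal samples.
    sampling_interval : float
        Sampling interval in seconds (the fMRI TR for BOLD data).
    """

    def __init__(self, values, sampling_interval: float):
        self.series = (
            values
            if isinstance(values, TimeSeries)
            else TimeSeries(values=np.asarray(values, dtype=float), sampling_interval=sampling_interval)
        )

    @classmethod
    def from_series(cls, series: TimeSeries) -> "HurstModel":
        return cls(series, series.sampling_interval)

    def fit(self, n_segments: int = 8, overlap_fraction: float = 0.5) -> HurstFit:
        psd = welch_psd(self.series, n_segments=n_segments, overlap_fraction=overlap_fraction)
        beta, intercept, r2, n_bins = fit_spectral_index(psd)
        h = beta_to_hurst(beta)
        return HurstFit(
            beta=beta,
            hurst=h,
            intercept=intercept,
            r_squared=r2,
            n_bins=n_bins,
            signal_class=classify_signal(h),
        )


def _segment_length(n: int, n_segments: int) -> int:
    # L such that n_segments half-overlapping windows tile N samples;
    # trailing remainder samples are dropped.
    return (2 * n) // (n_segments + 1)


def welch_psd(
    series: TimeSeries, n_segments: int = 8, overlap_fraction: float = 0.5
) -> PsdEstimate:
    """Welch PSD with ``n_segments`` Hann-tapered windows.

    Segment length is L = floor(2N / (n_segments + 1)) so that ``n_segments``
    windows at 50% overlap tile the series. Each segment is mean-detrended.
    The one-sided density is normalised so that the integral of power over
    frequency equals the signal variance (Parseval, up to taper correction).
    """
    if not isinstance(series, TimeSeries):
        series = TimeSeries(values=np.asarray(series, dtype=float), sampling_interval=1.0)
    if not (0.0 <= overlap_fraction < 1.0):
        raise ValueError("overlap_fraction must lie in [0, 1)")
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    x = series.values
    n = x.size
    if np.ptp(x) == 0:
        raise ValueError("constant series has no spectral content")
    if n_segments == 1:
        nperseg = n
        noverlap = 0
    else:
        nperseg = _segment_length(n, n_segments)
        noverlap = int(np.floor(nperseg * overlap_fraction))
    if nperseg < 8:
        min_n = (8 * (n_segments + 1) + 1) // 2
        raise ValueError(
            f"series too short: {n} samples give segments of {nperseg} < 8; "
            f"need at least N = {min_n} for {n_segments} segments"
        )
    fs = 1.0 / series.sampling_interval
    freqs, power = sps.welch(
        x,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend="constant",
        return_onesided=True,
        scaling="density",
    )
    return PsdEstimate(
        frequencies_hz=freqs,
        power=power,
        n_segments=n_segments,
        overlap_fraction=overlap_fraction,
        window_name="hann",
    )


def fit_spectral_index(psd: PsdEstimate) -> tuple[float, float, float, int]:
    """OLS fit of log10 power on log10 frequency over the full spectrum.

    All bins with frequency > 0 and power > 0 enter the regression (the zero
    frequency bin is excluded because log 0 is undefined). Returns
    ``(beta, intercept, r_squared, n_bins)`` with beta = -slope.
    """
    usable = (psd.frequencies_hz > 0) & (psd.power > 0)
    n_bins = int(usable.sum())
    if n_bins < 3:
        raise ValueError(f"need >= 3 usable frequency bins; got {n_bins}")
    logf = np.log10(psd.frequencies_hz[usable])
    logp = np.log10(psd.power[usable])
    slope, intercept = np.polyfit(logf, logp, 1)
    resid = logp - (slope * logf + intercept)
    ss_tot = np.sum((logp - logp.mean()) ** 2)
    r2 = 1.0 if ss_tot == 0 else float(1.0 - np.sum(resid**2) / ss_tot)
    return float(-slope), float(intercept), r2, n_bins


def beta_to_hurst(beta: float) -> float:
    """H = (1 + beta) / 2; beta = 0 (flat spectrum) gives H = 0.5."""
    if not np.isfinite(beta):
        raise ValueError(f"beta must be finite; got {beta}")
    return (1.0 + beta) / 2.0


def classify_signal(hurst: float) -> SignalClass:
    """Extended-Hurst class: (0,1) fGn; [1,2) fBm; otherwise out of range.

    The H = 1 boundary is deterministically assigned to fBm.
    """
    if not np.isfinite(hurst):
        raise ValueError(f"hurst must be finite; got {hurst}")
    if 0.0 < hurst < 1.0:
        return SignalClass.FGN
    if 1.0 <= hurst < 2.0:
        return SignalClass.FBM
    return SignalClass.OUT_OF_RANGE


@dataclass
class HurstMap:
    """Per-voxel Hurst values on the image lattice.

    Invalid voxels (constant/zero series or failed fits) carry the sentinel
    value 0, matching the downstream non-zero-voxel aggregation rule; the
    validity mask is carried explicitly as well.
    """

    values: np.ndarray
    valid: np.ndarray
    meta: dict | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and validity mask must share a shape")

    def to_nifti(self, affine: np.ndarray):
        import nibabel as nib

        return nib.Nifti1Image(self.values.astype(np.float32), affine)

    def save(self, path, affine: np.ndarray | None = None) -> None:
        import nibabel as nib

        if affine is None:
            affine = np.eye(4)
        nib.save(self.to_nifti(affine), str(path))
        sidecar = dict(self.meta or {})
        with open(str(path).replace(".nii.gz", "").replace(".nii", "") + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2)


def hurst_map(
    volume4d: np.ndarray,
    sampling_interval: float,
    n_segments: int = 8,
    overlap_fraction: float = 0.5,
) -> HurstMap:
    """Voxelwise Hurst map of a 4-D volume (x, y, z, time).

    Runs welch_psd -> spectral-index fit -> H = (1+beta)/2 per voxel,
    vectorised across voxels. Voxels with constant or all-zero series, or
    whose fit fails (fewer than 3 usable bins), are marked invalid and set to
    the sentinel 0. NaNs in the input mark their voxels invalid.
    """
    vol = np.asarray(volume4d, dtype=float)
    if vol.ndim != 4:
        raise ValueError(f"expected a 4-D volume; got shape {vol.shape}")
    nx, ny, nz, nt = vol.shape
    if nt < 64:
        raise ValueError(f"need >= 64 time points; got {nt}")
    flat = vol.reshape(-1, nt)
    finite = np.all(np.isfinite(flat), axis=1)
    nonconst = np.ptp(np.where(np.isfinite(flat), flat, 0.0), axis=1) > 0
    candidate = finite & nonconst

    hs = np.zeros(flat.shape[0])
    valid = np.zeros(flat.shape[0], dtype=bool)

    if candidate.any():
        nperseg = _segment_length(nt, n_segments) if n_segments > 1 else nt
        if nperseg < 8:
            raise ValueError("time series too short for the Welch segment scheme")
        noverlap = int(np.floor(nperseg * overlap_fraction)) if n_segments > 1 else 0
        fs = 1.0 / sampling_interval
        freqs, power = sps.welch(
            flat[candidate],
            fs=fs,
            window="hann",
            nperseg=nperseg,
            noverlap=noverlap,
            detrend="constant",
            return_onesided=True,
            scaling="density",
            axis=-1,
        )
        pos_f = freqs > 0
        logf = np.log10(freqs[pos_f])
        pw = power[:, pos_f]
        ok_power = np.all(pw > 0, axis=1)
        # vectorised OLS for voxels with strictly positive spectra
        if ok_power.any():
            logp = np.log10(pw[ok_power])
            fc = logf - logf.mean()
            slope = (logp @ fc) / (fc @ fc)
            h_ok = (1.0 - slope) / 2.0
            idx = np.flatnonzero(candidate)[ok_power]
            hs[idx] = h_ok
            valid[idx] = True
        # per-voxel fallback where some power bins are non-positive
        hard = np.flatnonzero(candidate)[~ok_power]
        for local, i in zip(np.flatnonzero(~ok_power), hard):
            pw_row = power[local]
            usable = pos_f & (pw_row > 0)
            if usable.sum() < 3:
                continue
            lf = np.log10(freqs[usable])
            lp = np.log10(pw_row[usable])
            slope = np.polyfit(lf, lp, 1)[0]
            hs[i] = (1.0 - slope) / 2.0
            valid[i] = True

    hs[~valid] = 0.0
    meta = {
        "n_segments": n_segments,
        "overlap_fraction": overlap_fraction,
        "window": "hann",
        "detrend": "constant",
        "fit_range": "all bins with f > 0 and power > 0 up to Nyquist",
        "sampling_interval_s": sampling_interval,
        "n_valid_voxels": int(valid.sum()),
        "n_voxels": int(valid.size),
    }
    return HurstMap(values=hs.reshape(nx, ny, nz), valid=valid.reshape(nx, ny, nz), meta=meta)


def roi_mean_hurst(hmap: HurstMap, gm_mask: np.ndarray, mrs_mask: np.ndarray) -> float:
    """Mean H over grey matter within the MRS voxel, non-zero voxels only.

    The ROI is the intersection of the grey-matter mask and the MRS-voxel
    mask; voxels whose map value is zero or non-finite are excluded from the
    average, mirroring the non-zero-voxel aggregation rule.
    """
    gm = np.asarray(gm_mask) > 0.5
    mrs = np.asarray(mrs_mask) > 0.5
    if gm.shape != hmap.values.shape or mrs.shape != hmap.values.shape:
        raise ValueError("masks must share the map's lattice")
    roi = gm & mrs
    if not roi.any():
        raise ValueError("empty ROI: grey-matter and MRS masks do not intersect")
    vals = hmap.values[roi]
    vals = vals[np.isfinite(vals) & (vals != 0)]
    if vals.size == 0:
        raise ValueError("ROI mean undefined: every voxel in the intersection is invalid")
    return float(vals.mean())
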