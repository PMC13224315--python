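"""Synthetic cohort and phantom generation.

Two generators make the full pipeline testable without acquired data:

* :func:`generate_cohort_table` draws subject x condition records with the
  study's statistical structure: metabolite concentrations from per-condition
  normal distributions (Glx 9.84+/-1.06 mM at rest, 10.04+/-0.79 during movie
  watching; GABA+ 5.48+/-0.77 and 5.23+/-0.71 mM, truncated at zero), a
  within-subject metabolite correlation induced by a shared subject-level
  offset, a condition effect on the Hurst exponent (rest lower than movie by
  0.07 by default), an optional E:I effect on H, per-subject random
  intercepts, residual noise, and quality-control covariates (mean framewise
  displacement, water-peak FWHM, frequency shift) spanning the exclusion
  thresholds so that QC rules are exercised.

* :func:`generate_phantom_subject` builds a small multi-echo 4-D phantom
  whose voxels carry fractional-Gaussian-noise signals with tissue-specific
  Hurst exponents (grey matter > white matter > CSF), monoexponential
  T2*-weighted echo scaling, additive white noise, a jittered cubic MRS-voxel
  mask, and a random-walk motion trace.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from eihurst.fractal import FgnSpec, simulate_fgn_batch
from eihurst.multiecho import MultiEchoSeries
from eihurst.qc import MotionTrace

__all__ = [
    "CohortSpec",
    "PhantomSpec",
    "generate_cohort_table",
    "generate_phantom_subject",
    "write_bids_layout",
]

CONDITIONS = ("rest", "movie")


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters of a synthetic subject x condition cohort.

    Metabolite means/SDs default to the study-scale values (mM). The Hurst
    generative model is

        H = intercept + beta_rest * 1[rest] + beta_ei * EI
            + subject_intercept + residual,

    with movie as the reference condition. The default intercept of 1.05 and
    rest effect of -0.07 put condition means near 1.05 (movie) and 0.98
    (rest). The default E:I effect is 0 (the null); a nonzero value is the
    knob for power experiments. ``metab_shared_frac`` sets the SD of the
    shared subject-level metabolite offset as a fraction of the
    between-subject SD, inducing within-subject correlation across
    conditions.
    """

    n_subjects: int = 18
    glx_mean: dict = field(default_factory=lambda: {"rest": 9.84, "movie": 10.04})
    glx_sd: dict = field(default_factory=lambda: {"rest": 1.06, "movie": 0.79})
    gaba_mean: dict = field(default_factory=lambda: {"rest": 5.48, "movie": 5.23})
    gaba_sd: dict = field(default_factory=lambda: {"rest": 0.77, "movie": 0.71})
    hurst_intercept: float = 1.05
    beta_rest: float = -0.07
    beta_ei: float = 0.0
    subject_intercept_sd: float = 0.10
    residual_sd: float = 0.06
    metab_shared_frac: float = 0.5
    fd_range: tuple = (0.05, 0.20)
    fwhm_range: tuple = (6.0, 11.0)
    freq_shift_range: tuple = (-2.0, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if self.n_subjects < 2:
            problems.append(f"n_subjects must be >= 2 (got {self.n_subjects})")
        for name, d in [
            ("glx_sd", self.glx_sd),
            ("gaba_sd", self.gaba_sd),
        ]:
            if any(v < 0 for v in d.values()):
                problems.append(f"{name} must be >= 0")
        for name, v in [
            ("subject_intercept_sd", self.subject_intercept_sd),
            ("residual_sd", self.residual_sd),
        ]:
            if v < 0:
                problems.append(f"{name} must be >= 0")
        if not (0.0 <= self.metab_shared_frac <= 1.0):
            problems.append("metab_shared_frac must lie in [0, 1]")
        if problems:
            raise ValueError("invalid CohortSpec: " + "; ".join(problems))


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal draw truncated at 0 by resampling (concentrations are positive)."""
    if sd == 0:
        return mean
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v > 0:
            return v
    raise RuntimeError("truncated-normal resampling failed; check mean/sd")


def generate_cohort_table(spec: CohortSpec) -> pd.DataFrame:
    """Draw a subject x condition cohort table; deterministic given seed."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for i in range(spec.n_subjects):
        sid = f"sub-{i + 1:02d}"
        u = rng.normal(0.0, spec.subject_intercept_sd) if spec.subject_intercept_sd else 0.0
        # shared subject-level metabolite offsets -> within-subject correlation
        offsets = {}
        for met, sds in [("glx", spec.glx_sd), ("gaba", spec.gaba_sd)]:
            mean_sd = float(np.mean(list(sds.values())))
            off_sd = spec.metab_shared_frac * mean_sd
            offsets[met] = rng.normal(0.0, off_sd) if off_sd else 0.0
        for cond in CONDITIONS:
            draws = {}
            for met, means, sds in [
                ("glx", spec.glx_mean, spec.glx_sd),
                ("gaba", spec.gaba_mean, spec.gaba_sd),
            ]:
                sd_c = sds[cond]
                mean_sd = float(np.mean(list(sds.values())))
                off_sd = spec.metab_shared_frac * mean_sd
                indep_sd = float(np.sqrt(max(sd_c**2 - off_sd**2, 0.0)))
                val = -1.0
                while val <= 0:
                    val = means[cond] + offsets[met] + (rng.normal(0.0, indep_sd) if indep_sd else 0.0)
                    if sd_c == 0:
                        val = means[cond]
                        break
                draws[met] = val
            ei = draws["glx"] / draws["gaba"]
            resid = rng.normal(0.0, spec.residual_sd) if spec.residual_sd else 0.0
            h = (
                spec.hurst_intercept
                + (spec.beta_rest if cond == "rest" else 0.0)
                + spec.beta_ei * ei
                + u
                + resid
            )
            rows.append(
                {
                    "subject_id": sid,
                    "condition": cond,
                    "hurst": h,
                    "glx_mM": draws["glx"],
                    "gaba_mM": draws["gaba"],
                    "ei": ei,
                    "mean_fd_mm": rng.uniform(*spec.fd_range),
                    "fwhm_slaser": rng.uniform(*spec.fwhm_range),
                    "fwhm_mega": rng.uniform(*spec.fwhm_range),
                    "freq_shift_slaser": rng.uniform(*spec.freq_shift_range),
                    "freq_shift_mega": rng.uniform(*spec.freq_shift_range),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters of a multi-echo 4-D phantom subject.

    The grid is partitioned into CSF / WM / GM slabs along x; per-tissue
    target Hurst exponents default to GM 0.9 > WM 0.7 > CSF 0.5 and per-tissue
    T2* to values typical of 3 T (GM 50 ms, WM 45 ms, CSF 200 ms). Echo times
    default to the three-echo acquisition (12.2, 35.352, 58.504 ms) and the
    repetition time to 1.5 s with 480 frames. The MRS voxel is a cube of side
    ``mrs_size`` centred in the GM slab and jittered per subject by up to
    ``mrs_jitter`` voxels per axis.
    """

    shape: tuple = (16, 16, 16)
    hurst_by_tissue: dict = field(
        default_factory=lambda: {"gm": 0.9, "wm": 0.7, "csf": 0.5}
    )
    t2star_ms_by_tissue: dict = field(
        default_factory=lambda: {"gm": 50.0, "wm": 45.0, "csf": 200.0}
    )
    te_ms: tuple = (12.2, 35.352, 58.504)
    n_frames: int = 480
    sampling_interval: float = 1.5
    s0: float = 100.0
    fluctuation_amp: float = 5.0
    noise_sd: float = 0.5
    mrs_size: int = 6
    mrs_jitter: int = 1
    motion_amplitude_mm: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 64:
            raise ValueError("n_frames must be >= 64")
        if len(self.shape) != 3 or any(s < 4 for s in self.shape):
            raise ValueError("shape must be 3-D with each side >= 4")
        if self.mrs_size < 1:
            raise ValueError("mrs_size must be >= 1")


def _tissue_labels(shape: tuple) -> dict:
    """Partition the grid into CSF / WM / GM slabs along x."""
    nx = shape[0]
    x = np.arange(nx)
    csf = x < nx // 4
    wm = (x >= nx // 4) & (x < nx // 2)
    gm = x >= nx // 2
    masks = {}
    for name, sel in [("csf", csf), ("wm", wm), ("gm", gm)]:
        m = np.zeros(shape, dtype=bool)
        m[sel, :, :] = True
        masks[name] = m
    return masks


def generate_phantom_subject(spec: PhantomSpec):
    """Build one phantom subject.

    Returns ``(MultiEchoSeries, tissue_masks, mrs_mask, MotionTrace)``. Each
    voxel's base signal is an exact fGn path at its tissue's Hurst exponent;
    echo i scales the fluctuating signal by exp(-TE_i / T2*_tissue) and adds
    white noise. Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    masks = _tissue_labels(spec.shape)
    n_vox = int(np.prod(spec.shape))
    base = np.zeros((n_vox, spec.n_frames))
    for t_idx, (tissue, mask) in enumerate(masks.items()):
        idx = np.flatnonzero(mask.ravel())
        fspec = FgnSpec(
            hurst=spec.hurst_by_tissue[tissue],
            sigma=1.0,
            length=spec.n_frames,
            sampling_interval=spec.sampling_interval,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        base[idx] = simulate_fgn_batch(fspec, idx.size)

    te = np.asarray(spec.te_ms, dtype=float)
    t2 = np.zeros(n_vox)
    for tissue, mask in masks.items():
        t2[mask.ravel()] = spec.t2star_ms_by_tissue[tissue]
    echoes = []
    for te_i in te:
        decay = np.exp(-te_i / t2)[:, None]
        sig = decay * (spec.s0 + spec.fluctuation_amp * base)
        if spec.noise_sd > 0:
            sig = sig + rng.normal(0.0, spec.noise_sd, size=sig.shape)
        echoes.append(sig.reshape(*spec.shape, spec.n_frames))
    series = MultiEchoSeries(echo_volumes=echoes, te_ms=te)

    # cubic MRS voxel centred in the GM slab, jittered per subject
    nx, ny, nz = spec.shape
    cx = (nx // 2 + nx) // 2
    cy, cz = ny // 2, nz // 2
    half = spec.mrs_size // 2
    # base position clamped so the jitter range stays in-grid when feasible;
    # infeasible specs (cube ~ grid sized with jitter) surface as an error
    limits_lo = np.minimum(spec.mrs_jitter, np.maximum(0, np.array(spec.shape) - spec.mrs_size))
    limits_hi = np.maximum(limits_lo, np.array(spec.shape) - spec.mrs_size - spec.mrs_jitter)
    base = np.clip(np.array([cx, cy, cz]) - half, limits_lo, limits_hi)
    jitter = rng.integers(-spec.mrs_jitter, spec.mrs_jitter + 1, size=3) if spec.mrs_jitter else np.zeros(3, dtype=int)
    lo = base + jitter
    hi = lo + spec.mrs_size
    if np.any(lo < 0) or np.any(hi > np.array(spec.shape)):
        raise ValueError("MRS voxel placed outside the grid after jitter")
    mrs_mask = np.zeros(spec.shape, dtype=bool)
    mrs_mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = True

    # random-walk motion trace; rotation amplitude scaled so rotations
    # contribute comparably to FD under the 50 mm head radius
    amp_t = spec.motion_amplitude_mm
    amp_r = spec.motion_amplitude_mm / 50.0
    trans = np.cumsum(rng.normal(0.0, amp_t, size=(spec.n_frames, 3)), axis=0)
    rot = np.cumsum(rng.normal(0.0, amp_r, size=(spec.n_frames, 3)), axis=0)
    trace = MotionTrace(translations_mm=trans, rotations_rad=rot)
    return series, masks, mrs_mask, trace


def write_bids_layout(root, subjects: dict, cohort: pd.DataFrame | None = None) -> None:
    """Write phantom subjects in a BIDS-flavoured layout.

    ``subjects`` maps subject id -> the tuple returned by
    :func:`generate_phantom_subject`. Writes per-echo 4-D NIfTIs, tissue
    segmentations, the MRS mask, a motion TSV, and optionally ``cohort.tsv``.
    """
    import nibabel as nib
    from pathlib import Path

    root = Path(root)
    aff = np.eye(4)
    for sid, (series, masks, mrs_mask, trace) in subjects.items():
        func = root / sid / "func"
        anat = root / sid / "anat"
        func.mkdir(parents=True, exist_ok=True)
        anat.mkdir(parents=True, exist_ok=True)
        for i, vol in enumerate(series.echo_volumes, start=1):
            nib.save(
                nib.Nifti1Image(vol.astype(np.float32), aff),
                func / f"{sid}_echo-{i}_bold.nii.gz",
            )
        dseg = np.zeros(masks["gm"].shape, dtype=np.int16)
        for code, tissue in [(1, "csf"), (2, "wm"), (3, "gm")]:
            dseg[masks[tissue]] = code
        nib.save(nib.Nifti1Image(dseg, aff), anat / f"{sid}_dseg.nii.gz")
        nib.save(
            nib.Nifti1Image(mrs_mask.astype(np.uint8), aff), root / sid / "mrs_mask.nii.gz"
        )
        motion = pd.DataFrame(
            np.hstack([trace.translations_mm, trace.rotations_rad]),
            columns=["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"],
        )
        motion.to_csv(func / f"{sid}_motion.tsv", sep="\t", index=False)
    if cohort is not None:
        cohort.to_csv(root / "cohort.tsv", sep="\t", index=False)
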