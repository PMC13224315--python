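"""Quality control: framewise displacement, exclusion rules, Dice overlap,
and majority-vote consensus masks.

Framewise displacement (FD) summarises head motion per frame as the sum of
absolute backward differences of the six rigid-body parameters, with
rotations (radians) converted to millimetres of arc on a 50 mm head radius.
Subjects are excluded when any condition's mean FD exceeds 0.15 mm or any MRS
scan's water-peak FWHM exceeds 10 (strict inequalities). Inter-subject
consistency of MRS voxel placement is quantified by a strict-majority
consensus mask and the mean Dice coefficient of each subject's mask against
that consensus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MotionTrace",
    "framewise_displacement",
    "read_motion_tsv",
    "apply_exclusions",
    "dice",
    "consensus_mask",
]

MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


@dataclass(frozen=True)
class MotionTrace:
    """Per-frame rigid-body motion: translations (mm) and rotations (rad)."""

    translations_mm: np.ndarray  # (n_frames, 3)
    rotations_rad: np.ndarray  # (n_frames, 3)

    def __post_init__(self) -> None:
        t = np.atleast_2d(np.asarray(self.translations_mm, dtype=float))
        r = np.atleast_2d(np.asarray(self.rotations_rad, dtype=float))
        object.__setattr__(self, "translations_mm", t)
        object.__setattr__(self, "rotations_rad", r)
        if t.shape != r.shape or t.shape[1] != 3:
            raise ValueError("translations and rotations must both be (n_frames, 3)")
        if t.shape[0] < 2:
            raise ValueError("motion trace needs at least 2 frames")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(r))):
            raise ValueError("motion parameters must be finite")

    @property
    def n_frames(self) -> int:
        return self.translations_mm.shape[0]


def read_motion_tsv(path) -> MotionTrace:
    """Read a 6-column motion TSV with validated column names."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MOTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"motion TSV missing columns: {missing}")
    return MotionTrace(
        translations_mm=df[MOTION_COLUMNS[:3]].to_numpy(),
        rotations_rad=df[MOTION_COLUMNS[3:]].to_numpy(),
    )


def framewise_displacement(
    trace: MotionTrace, head_radius_mm: float = 50.0
) -> tuple[np.ndarray, float]:
    """Per-frame FD (first frame 0) and the mean FD over frames 2..N.

    FD_t = sum |delta translation| + head_radius * sum |delta rotation|.
    Adding a constant offset to any parameter leaves FD unchanged.
    """
    dt = np.abs(np.diff(trace.translations_mm, axis=0)).sum(axis=1)
    dr = np.abs(np.diff(trace.rotations_rad, axis=0)).sum(axis=1)
    fd = np.concatenate([[0.0], dt + head_radius_mm * dr])
    return fd, float(fd[1:].mean())


def apply_exclusions(
    records: pd.DataFrame,
    fd_threshold: float = 0.15,
    fwhm_threshold: float = 10.0,
) -> tuple[list, list]:
    """Apply motion and spectral-linewidth exclusion rules to a QC table.

    ``records`` holds one row per subject x condition with columns
    ``subject_id``, ``condition``, ``mean_fd_mm``, ``fwhm_slaser`` and
    ``fwhm_mega``. A subject is excluded if ANY condition's mean FD exceeds
    ``fd_threshold`` or ANY MRS scan's water FWHM exceeds ``fwhm_threshold``
    (both strict `>`). Returns ``(retained_ids, excluded)`` where each
    exclusion is a dict with the subject, reason code (``FD`` or ``FWHM``)
    and the offending value; FD violations take precedence in the code.
    """
    required = {"subject_id", "condition", "mean_fd_mm", "fwhm_slaser", "fwhm_mega"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"QC table missing columns: {sorted(missing)}")
    conditions = set(records["condition"].unique())
    retained, excluded = [], []
    for sid, grp in records.groupby("subject_id", sort=True):
        if set(grp["condition"]) != conditions:
            raise ValueError(f"subject {sid} lacks records for every condition")
        max_fd = grp["mean_fd_mm"].max()
        max_fwhm = grp[["fwhm_slaser", "fwhm_mega"]].to_numpy().max()
        if max_fd > fd_threshold:
            excluded.append({"subject_id": sid, "reason": "FD", "value": float(max_fd)})
        elif max_fwhm > fwhm_threshold:
            excluded.append({"subject_id": sid, "reason": "FWHM", "value": float(max_fwhm)})
        else:
            retained.append(sid)
    return retained, excluded


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|); two empty masks give 1."""
    a = np.asarray(a) > 0.5
    b = np.asarray(b) > 0.5
    if a.shape != b.shape:
        raise ValueError("masks must share a lattice")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0  # degenerate: identical empty masks
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def consensus_mask(masks) -> tuple[np.ndarray, float]:
    """Strict-majority consensus mask and mean per-subject Dice against it.

    A voxel enters the consensus iff it is present in strictly more than half
    of the masks (a tie at exactly half is excluded). The result is invariant
    to permuting the input list.
    """
    arrs = [np.asarray(m) > 0.5 for m in masks]
    if len(arrs) < 2:
        raise ValueError("need at least 2 masks")
    shape = arrs[0].shape
    if any(m.shape != shape for m in arrs):
        raise ValueError("masks must share a lattice")
    votes = np.sum(arrs, axis=0)
    consensus = votes > len(arrs) / 2.0
    mean_dice = float(np.mean([dice(m, consensus) for m in arrs]))
    return consensus, mean_dice
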