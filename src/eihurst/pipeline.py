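"""End-to-end orchestration: phantoms -> T2* combination -> Hurst maps ->
QC exclusions -> cohort table -> mixed model (and optional power).

The pipeline mirrors the study workflow. Per subject and condition it fits
the multi-echo T2* map and optimally combines the echoes, estimates the
voxelwise Hurst map from the combined series, and averages H over grey
matter within the MRS voxel. Framewise displacement comes from the motion
trace; metabolite and spectral-quality values come from the cohort table.
Subjects failing the motion or linewidth thresholds are excluded, MRS-voxel
placement consistency is summarised by the consensus-mask Dice, and the
retained cohort is fitted with the H ~ E:I mixed model. Conditions are
processed independently and merged at table assembly. All randomness derives
from one seed via per-stage substreams.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from eihurst.cohort import EIHurstLMM, paired_condition_test, pearson_corr, power_simulation
from eihurst.hurst import hurst_map, roi_mean_hurst
from eihurst.multiecho import fit_t2star_map, optimal_combine
from eihurst.qc import apply_exclusions, consensus_mask, framewise_displacement
from eihurst.synthgen import CONDITIONS, CohortSpec, PhantomSpec, generate_cohort_table, generate_phantom_subject

logger = logging.getLogger("eihurst.pipeline")

__all__ = ["RunConfig", "run_pipeline"]

# per-subject spread of the imaging grey-matter Hurst exponent; kept small so
# tissue targets stay inside the fGn-valid (0, 1) range
SUBJECT_H_SD = 0.02


@dataclass
class RunConfig:
    """Configuration of an end-to-end synthetic run.

    ``cohort`` drives metabolite/QC draws and the generative condition
    effect; ``phantom`` drives the imaging phantoms. The phantom grey-matter
    Hurst target is shifted by the cohort's rest effect in the rest
    condition, so the condition contrast flows through the imaging branch.
    ``include_ei`` toggles the E:I term in the model formula (the full model
    is the default). ``power_betas`` non-empty triggers the power stage.
    """

    cohort: CohortSpec = field(default_factory=CohortSpec)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    n_segments: int = 8
    overlap_fraction: float = 0.5
    fd_threshold: float = 0.15
    fwhm_threshold: float = 10.0
    include_ei: bool = True
    power_betas: tuple = ()
    power_n_sims: int = 1000
    seed: int = 0
    output_root: str | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("cohort"), dict):
            co = dict(d["cohort"])
            for key in ("fd_range", "fwhm_range", "freq_shift_range"):
                if key in co and isinstance(co[key], list):
                    co[key] = tuple(co[key])
            d["cohort"] = CohortSpec(**co)
        if isinstance(d.get("phantom"), dict):
            ph = dict(d["phantom"])
            for key in ("shape", "te_ms"):
                if key in ph and isinstance(ph[key], list):
                    ph[key] = tuple(ph[key])
            d["phantom"] = PhantomSpec(**ph)
        for key in ("power_betas",):
            if isinstance(d.get(key), list):
                d[key] = tuple(d[key])
        return cls(**d)


def _clip_h(h: float) -> float:
    return float(np.clip(h, 0.05, 0.95))


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate -> multi-echo -> Hurst -> QC -> model; return the report.

    The report JSON-serialisable dict records per-stage parameters, the
    per-subject measurements, exclusions with reasons, consensus Dice, the
    paired condition contrasts, correlations, the mixed-model fit with R^2
    and VIFs, and (if requested) simulate-refit power. A model stage left
    with too few retained subjects is reported as insufficient data rather
    than aborting the run.
    """
    ss = np.random.SeedSequence(config.seed)
    sub_streams = ss.spawn(3)
    phantom_rng = np.random.default_rng(sub_streams[0])
    report: dict = {"config": _jsonable(config.to_dict()), "stages": {}}

    # stage 0: cohort table (metabolites, spectral QC draws, generative H)
    cohort_seed = int(np.random.default_rng(sub_streams[1]).integers(0, 2**31 - 1))
    cohort = generate_cohort_table(replace(config.cohort, seed=cohort_seed))
    subjects = sorted(cohort["subject_id"].unique())

    # per-subject imaging measurements
    stage_meas = []
    mrs_masks = []
    gm_h_base = config.phantom.hurst_by_tissue["gm"]
    for i, sid in enumerate(subjects):
        subj_offset = float(phantom_rng.normal(0.0, SUBJECT_H_SD))
        for cond in CONDITIONS:
            h_gm = _clip_h(gm_h_base + subj_offset + (config.cohort.beta_rest if cond == "rest" else 0.0))
            tissues = dict(config.phantom.hurst_by_tissue)
            tissues["gm"] = h_gm
            pspec = replace(
                config.phantom,
                hurst_by_tissue=tissues,
                seed=int(phantom_rng.integers(0, 2**31 - 1)),
            )
            try:
                series, masks, mrs_mask, trace = generate_phantom_subject(pspec)
                t2map = fit_t2star_map(series)
                combined = optimal_combine(series, t2map)
                hmap = hurst_map(
                    combined,
                    config.phantom.sampling_interval,
                    n_segments=config.n_segments,
                    overlap_fraction=config.overlap_fraction,
                )
                roi_h = roi_mean_hurst(hmap, masks["gm"], mrs_mask)
                _, mean_fd = framewise_displacement(trace)
            except Exception as exc:
                raise RuntimeError(
                    f"stage imaging failed for subject {sid}, condition {cond}: {exc}"
                ) from exc
            tissue_means = {
                t: float(np.mean(hmap.values[m & hmap.valid])) if (m & hmap.valid).any() else None
                for t, m in masks.items()
            }
            stage_meas.append(
                {
                    "subject_id": sid,
                    "condition": cond,
                    "roi_hurst": roi_h,
                    "mean_fd_mm": mean_fd,
                    "tissue_mean_hurst": tissue_means,
                    "n_valid_voxels": int(hmap.valid.sum()),
                }
            )
            if cond == CONDITIONS[0]:
                mrs_masks.append(mrs_mask)
    meas = pd.DataFrame([{k: v for k, v in m.items() if not isinstance(v, dict)} for m in stage_meas])
    report["stages"]["imaging"] = {
        "per_subject": _jsonable(stage_meas),
        "welch": {"n_segments": config.n_segments, "overlap_fraction": config.overlap_fraction},
    }

    # consensus MRS mask consistency
    consensus, mean_dice = consensus_mask(mrs_masks)
    report["stages"]["mrs_consensus"] = {
        "mean_dice": mean_dice,
        "consensus_voxels": int(consensus.sum()),
    }

    # assemble the cohort table: imaging H and FD replace the generative draws
    table = cohort.drop(columns=["hurst", "mean_fd_mm"]).merge(
        meas[["subject_id", "condition", "roi_hurst", "mean_fd_mm"]],
        on=["subject_id", "condition"],
    )
    table = table.rename(columns={"roi_hurst": "hurst"})

    # QC exclusions
    retained, excluded = apply_exclusions(
        table, fd_threshold=config.fd_threshold, fwhm_threshold=config.fwhm_threshold
    )
    report["stages"]["qc"] = {
        "retained": list(retained),
        "excluded": _jsonable(excluded),
        "fd_threshold": config.fd_threshold,
        "fwhm_threshold": config.fwhm_threshold,
    }
    table = table[table["subject_id"].isin(retained)].reset_index(drop=True)

    # statistics
    stats_report: dict = {}
    wide = table.pivot(index="subject_id", columns="condition")
    if len(retained) >= 3:
        for var in ["hurst", "glx_mM", "gaba_mM", "ei"]:
            rest = wide[(var, "rest")].to_numpy()
            movie = wide[(var, "movie")].to_numpy()
            try:
                stats_report.setdefault("paired_tests", {})[var] = _jsonable(
                    paired_condition_test(rest, movie)
                )
            except ValueError as exc:
                stats_report.setdefault("paired_tests", {})[var] = {"error": str(exc)}
        corr = {}
        for cond in CONDITIONS:
            sub = table[table["condition"] == cond]
            for var in ["glx_mM", "gaba_mM", "ei"]:
                try:
                    corr[f"hurst_vs_{var}_{cond}"] = pearson_corr(sub["hurst"], sub[var])
                except ValueError as exc:
                    corr[f"hurst_vs_{var}_{cond}"] = {"error": str(exc)}
        stats_report["correlations"] = corr
    try:
        if config.include_ei:
            res = EIHurstLMM.from_dataframe(table).fit()
            stats_report["lmm"] = res.to_dict()
        else:
            stats_report["lmm"] = {"note": "model without E:I term", **_reduced_fit(table)}
    except (ValueError, RuntimeError) as exc:
        stats_report["lmm"] = {"error": f"insufficient data for model stage: {exc}"}
    report["stages"]["statistics"] = stats_report

    # optional power stage
    if config.power_betas:
        power_seed = int(np.random.default_rng(sub_streams[2]).integers(0, 2**31 - 1))
        power = [
            _jsonable(asdict(power_simulation(config.cohort, b, n_sims=config.power_n_sims, seed=power_seed + i)))
            for i, b in enumerate(config.power_betas)
        ]
        report["stages"]["power"] = power

    if config.output_root:
        out = Path(config.output_root)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        table.to_csv(out / "cohort.tsv", sep="\t", index=False)
    return report


def _reduced_fit(table: pd.DataFrame) -> dict:
    """Fit the mixed model without the E:I term (formula toggle off)."""
    import eihurst.cohort as cs

    work = table.copy()
    X_cols = [c for c in cs.FIXED_EFFECTS if c != "ei"]
    cond = work["condition"].astype(str).str.lower()
    work["condition_rest"] = (cond == "rest").astype(float)
    from scipy import stats as sstats
    from statsmodels.regression.mixed_linear_model import MixedLM

    X = np.column_stack([np.ones(len(work))] + [work[c].to_numpy(dtype=float) for c in X_cols])
    names = ["intercept"] + X_cols
    y = work["hurst"].to_numpy(dtype=float)
    fit = MixedLM(y, X, groups=work["subject_id"].to_numpy()).fit(reml=True)
    n, k = X.shape
    n_subj = work["subject_id"].nunique()
    df = n - k - n_subj + 1
    est = np.asarray(fit.fe_params)
    se = np.asarray(fit.bse_fe)
    t = est / se
    p = 2 * sstats.t.sf(np.abs(t), df)
    return {
        "fixed_effects": {
            nm: {"estimate": float(e), "std_error": float(s), "t": float(tv), "df": df, "p": float(pv)}
            for nm, e, s, tv, pv in zip(names, est, se, t, p)
        },
        "random_intercept_var": float(np.asarray(fit.cov_re)[0, 0]),
        "residual_var": float(fit.scale),
    }


def _jsonable(obj):
    """Recursively convert numpy scalars/arrays for JSON serialisation."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
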