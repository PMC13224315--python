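"""Subject-level statistics: E:I ratios, paired contrasts, correlations,
the random-intercept linear mixed-effects model, and simulate-refit power.

The central model regresses the ROI-mean Hurst exponent on the MRS-derived
excitation-inhibition ratio with condition and spectral/motion quality
covariates as fixed effects and a per-subject random intercept:

    H ~ EI + Condition + meanFD + FWHM_sLASER + FWHM_MEGA
        + FreqShift_sLASER + FreqShift_MEGA + (1 | Subject)

Condition is coded with movie as the reference level, so the reported
condition coefficient is the rest-vs-movie contrast. The model is fitted by
restricted maximum likelihood; fixed-effect t-tests use the residual-df
approximation df = n_obs - n_fixed - n_subjects + 1, and 95% confidence
intervals come from the t distribution on that df. Marginal and conditional
R^2 follow the Nakagawa-Schielzeth variance decomposition. Power for a given
E:I effect size is computed by simulating the response from the generative
model, refitting, and counting significant E:I coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = [
    "FIXED_EFFECTS",
    "LmmResult",
    "PowerResult",
    "EIHurstLMM",
    "EIHurstLMMResults",
    "ei_ratio",
    "paired_condition_test",
    "pearson_corr",
    "fit_lmm",
    "r2_nakagawa",
    "vif",
    "power_simulation",
]

# fixed-effect design, in reporting order (after the intercept)
FIXED_EFFECTS = [
    "ei",
    "condition_rest",
    "mean_fd_mm",
    "fwhm_slaser",
    "fwhm_mega",
    "freq_shift_slaser",
    "freq_shift_mega",
]

REQUIRED_COLUMNS = [
    "subject_id",
    "condition",
    "hurst",
    "ei",
    "mean_fd_mm",
    "fwhm_slaser",
    "fwhm_mega",
    "freq_shift_slaser",
    "freq_shift_mega",
]


def ei_ratio(glx_mM: float, gaba_mM: float) -> float:
    """Excitation-inhibition ratio Glx / GABA+ (both in mM, both > 0)."""
    if not (glx_mM > 0 and gaba_mM > 0):
        raise ValueError("metabolite concentrations must be positive")
    return glx_mM / gaba_mM


def paired_condition_test(rest, movie) -> dict:
    """Two-sided paired t-test of (movie - rest) with CI and Cohen's d.

    Cohen's d for paired data is mean(diff) / sd(diff). A zero-variance
    difference vector (e.g. an exact constant shift) is degenerate and raised.
    """
    rest = np.asarray(rest, dtype=float)
    movie = np.asarray(movie, dtype=float)
    if rest.shape != movie.shape or rest.size < 3:
        raise ValueError("need equal-length paired samples of size >= 3")
    diff = movie - rest
    sd = diff.std(ddof=1)
    n = diff.size
    mean_diff = float(diff.mean())
    # float rounding of an exactly constant shift leaves sd at machine noise
    if sd <= 1e-12 * max(1.0, abs(mean_diff)):
        raise ValueError("zero variance of paired differences; t-test undefined")
    se = sd / np.sqrt(n)
    t = mean_diff / se
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    tcrit = stats.t.ppf(0.975, df)
    return {
        "mean_diff": mean_diff,
        "ci95": (mean_diff - tcrit * se, mean_diff + tcrit * se),
        "t": float(t),
        "df": df,
        "p": float(p),
        "cohens_d": float(mean_diff / sd),
    }


def pearson_corr(x, y) -> dict:
    """Pearson product-moment correlation with two-sided t-based p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p)}


@dataclass
class LmmResult:
    """Random-intercept LMM fit: estimates, uncertainties and diagnostics."""

    fixed_effects: pd.DataFrame  # index: term; columns: estimate, std_error, t, df, p, ci95_low, ci95_high
    random_intercept_var: float
    residual_var: float
    r2_marginal: float
    r2_conditional: float
    n_obs: int
    n_subjects: int
    converged: bool
    df_convention: str = "residual: n_obs - n_fixed - n_subjects + 1"


@dataclass
class PowerResult:
    """Simulate-refit power estimate for one E:I effect size."""

    effect_size_beta: float
    n_simulations: int
    alpha: float
    power: float
    ci95: tuple
    n_failed: int = 0


def _design_matrix(table: pd.DataFrame) -> tuple[np.ndarray, list]:
    cond = table["condition"].astype(str).str.lower()
    bad = set(cond.unique()) - {"rest", "movie"}
    if bad:
        raise ValueError(f"unknown condition labels: {sorted(bad)}")
    rest = (cond == "rest").astype(float).to_numpy()
    cols = [np.ones(len(table)), table["ei"].to_numpy(dtype=float), rest]
    names = ["intercept", "ei", "condition_rest"]
    for c in FIXED_EFFECTS[2:]:
        cols.append(table[c].to_numpy(dtype=float))
        names.append(c)
    return np.column_stack(cols), names


def fit_lmm(table: pd.DataFrame) -> LmmResult:
    """Fit the H ~ E:I random-intercept model by REML.

    ``table`` holds one row per subject x condition with the columns of
    ``REQUIRED_COLUMNS``. Requires >= 6 subjects with complete cases in both
    conditions. Raises on a rank-deficient fixed-effects design (naming the
    collinear columns) or on non-convergence.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    table = table.dropna(subset=REQUIRED_COLUMNS)
    n_subjects = table["subject_id"].nunique()
    if n_subjects < 6:
        raise ValueError(f"need >= 6 subjects; got {n_subjects}")
    X, names = _design_matrix(table)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by dropping each in turn
        collinear = [
            names[j]
            for j in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise ValueError(f"singular fixed-effects design; collinear columns: {collinear}")
    y = table["hurst"].to_numpy(dtype=float)
    groups = table["subject_id"].to_numpy()
    model = MixedLM(y, X, groups=groups)
    fit = None
    errors = []
    # gradient-based first; derivative-free fallbacks cover boundary fits
    # (random-intercept variance -> 0) where the REML score turns singular
    for method in ("lbfgs", "powell", "nm"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cand = model.fit(reml=True, method=method)
        except (np.linalg.LinAlgError, ValueError) as exc:
            errors.append(f"{method}: {exc}")
            continue
        if cand.converged:
            fit = cand
            break
        errors.append(f"{method}: did not converge")
    if fit is None:
        raise RuntimeError("mixed-model fit failed to converge; optimizer trace: " + "; ".join(errors))
    k = X.shape[1]
    n = len(y)
    df = n - k - n_subjects + 1
    est = np.asarray(fit.fe_params, dtype=float)
    se = np.asarray(fit.bse_fe, dtype=float)
    tvals = est / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    tcrit = stats.t.ppf(0.975, df)
    fe = pd.DataFrame(
        {
            "estimate": est,
            "std_error": se,
            "t": tvals,
            "df": df,
            "p": pvals,
            "ci95_low": est - tcrit * se,
            "ci95_high": est + tcrit * se,
        },
        index=names,
    )
    var_intercept = float(np.asarray(fit.cov_re)[0, 0])
    var_resid = float(fit.scale)
    var_fixed = float(np.var(X @ est, ddof=1))
    total = var_fixed + var_intercept + var_resid
    r2m = var_fixed / total if total > 0 else np.nan
    r2c = (var_fixed + var_intercept) / total if total > 0 else np.nan
    return LmmResult(
        fixed_effects=fe,
        random_intercept_var=var_intercept,
        residual_var=var_resid,
        r2_marginal=r2m,
        r2_conditional=r2c,
        n_obs=n,
        n_subjects=int(n_subjects),
        converged=bool(fit.converged),
    )


def r2_nakagawa(fit: LmmResult, table: pd.DataFrame) -> tuple[float, float]:
    """Marginal and conditional R^2 (Nakagawa-Schielzeth decomposition).

    marginal   = var(X beta) / (var_fixed + var_intercept + var_residual)
    conditional adds the random-intercept variance to the numerator.
    """
    X, names = _design_matrix(table.dropna(subset=REQUIRED_COLUMNS))
    est = fit.fixed_effects["estimate"].reindex(names).to_numpy()
    var_fixed = float(np.var(X @ est, ddof=1))
    total = var_fixed + fit.random_intercept_var + fit.residual_var
    if total <= 0:
        raise ValueError("zero total variance; R^2 undefined")
    return var_fixed / total, (var_fixed + fit.random_intercept_var) / total


def vif(table: pd.DataFrame, predictors: list | None = None) -> dict:
    """Variance inflation factors of the fixed-effects design.

    VIF_j = 1 / (1 - R^2_j) from regressing predictor j on the others (with
    intercept). Perfect collinearity is reported as +inf with a warning.
    """
    if predictors is None:
        predictors = list(FIXED_EFFECTS)
    work = table.copy()
    if "condition_rest" in predictors and "condition_rest" not in work.columns:
        work["condition_rest"] = (work["condition"].astype(str).str.lower() == "rest").astype(float)
    if len(work) < len(predictors) + 2:
        raise ValueError("too few rows for VIF computation")
    Z = work[predictors].to_numpy(dtype=float)
    out = {}
    for j, name in enumerate(predictors):
        yj = Z[:, j]
        Xj = np.column_stack([np.ones(len(Z)), np.delete(Z, j, axis=1)])
        beta, _, _, _ = np.linalg.lstsq(Xj, yj, rcond=None)
        resid = yj - Xj @ beta
        ss_tot = np.sum((yj - yj.mean()) ** 2)
        r2 = 0.0 if ss_tot == 0 else 1.0 - np.sum(resid**2) / ss_tot
        if r2 >= 1.0 - 1e-12:
            warnings.warn(f"predictor {name!r} is perfectly collinear; VIF infinite")
            out[name] = np.inf
        else:
            out[name] = float(1.0 / (1.0 - r2))
    return out


def power_simulation(
    generative_spec,
    effect_size: float,
    n_subjects: int | None = None,
    n_sims: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> PowerResult:
    """Simulate-refit power for the E:I coefficient at a given effect size.

    Each replicate draws a fresh cohort from ``generative_spec`` (a
    :class:`eihurst.synthgen.CohortSpec`) with the E:I coefficient set to
    ``effect_size``, refits the mixed model, and records whether the E:I
    coefficient's two-sided p-value falls below ``alpha``. Power is the
    fraction of significant replicates with an exact (Clopper-Pearson)
    binomial 95% CI. Replicates whose refit fails are excluded and counted.
    Deterministic given ``seed``.
    """
    from dataclasses import replace

    from eihurst.synthgen import generate_cohort_table

    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    spec = generative_spec
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_sims)
    n_sig = 0
    n_failed = 0
    for s in sub_seeds:
        rep = replace(
            spec,
            n_subjects=n_subjects or spec.n_subjects,
            beta_ei=effect_size,
            seed=int(s),
        )
        table = generate_cohort_table(rep)
        try:
            fit = fit_lmm(table)
        except (ValueError, RuntimeError):
            n_failed += 1
            continue
        if fit.fixed_effects.loc["ei", "p"] < alpha:
            n_sig += 1
    n_ok = n_sims - n_failed
    if n_ok == 0:
        raise RuntimeError("every power replicate failed to fit")
    power = n_sig / n_ok
    ci = stats.binomtest(n_sig, n_ok).proportion_ci(confidence_level=0.95, method="exact")
    return PowerResult(
        effect_size_beta=effect_size,
        n_simulations=n_ok,
        alpha=alpha,
        power=float(power),
        ci95=(float(ci.low), float(ci.high)),
        n_failed=n_failed,
    )


class EIHurstLMM:
    """The H ~ E:I mixed model as a statsmodels-style model object.

    Build from a cohort table (one row per subject x condition) and call
    :meth:`fit` for an :class:`EIHurstLMMResults` carrying estimates,
    confidence intervals, variance components, R^2 and VIF diagnostics.
    """

    def __init__(self, table: pd.DataFrame):
        self.table = table.copy()

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame) -> "EIHurstLMM":
        return cls(table)

    @classmethod
    def from_tsv(cls, path) -> "EIHurstLMM":
        return cls(pd.read_csv(path, sep="\t"))

    def fit(self) -> "EIHurstLMMResults":
        res = fit_lmm(self.table)
        vifs = vif(self.table)
        return EIHurstLMMResults(model=self, lmm=res, vifs=vifs)


@dataclass
class EIHurstLMMResults:
    """Fitted H ~ E:I mixed model with diagnostics and power simulation."""

    model: EIHurstLMM
    lmm: LmmResult
    vifs: dict

    @property
    def fixed_effects(self) -> pd.DataFrame:
        return self.lmm.fixed_effects

    @property
    def r2_marginal(self) -> float:
        return self.lmm.r2_marginal

    @property
    def r2_conditional(self) -> float:
        return self.lmm.r2_conditional

    def power(self, generative_spec, effect_sizes, n_sims: int = 1000, seed: int = 0):
        return [
            power_simulation(generative_spec, beta, n_sims=n_sims, seed=seed + i)
            for i, beta in enumerate(effect_sizes)
        ]

    def summary(self) -> str:
        fe = self.lmm.fixed_effects
        lines = [
            "Linear mixed-effects model: H ~ EI + Condition + QC covariates + (1 | Subject)",
            f"  observations: {self.lmm.n_obs}   subjects: {self.lmm.n_subjects}",
            f"  random intercept var: {self.lmm.random_intercept_var:.4g}   "
            f"residual var: {self.lmm.residual_var:.4g}",
            f"  marginal R2: {self.lmm.r2_marginal:.3f}   conditional R2: {self.lmm.r2_conditional:.3f}",
            "",
            f"  {'term':<20}{'est':>9}{'se':>9}{'t':>8}{'df':>5}{'p':>8}{'ci95':>22}{'vif':>7}",
        ]
        for term, row in fe.iterrows():
            v = self.vifs.get(term)
            vtxt = f"{v:7.2f}" if v is not None and np.isfinite(v) else "       "
            lines.append(
                f"  {term:<20}{row['estimate']:9.4f}{row['std_error']:9.4f}"
                f"{row['t']:8.2f}{int(row['df']):5d}{row['p']:8.3f}"
                f"  [{row['ci95_low']:7.3f}, {row['ci95_high']:7.3f}]{vtxt}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        fe = self.lmm.fixed_effects
        return {
            "fixed_effects": {
                term: {k: (float(v) if np.isfinite(v) else None) for k, v in row.items()}
                for term, row in fe.iterrows()
            },
            "random_intercept_var": self.lmm.random_intercept_var,
            "residual_var": self.lmm.residual_var,
            "r2_marginal": self.lmm.r2_marginal,
            "r2_conditional": self.lmm.r2_conditional,
            "n_obs": self.lmm.n_obs,
            "n_subjects": self.lmm.n_subjects,
            "vif": {k: (v if np.isfinite(v) else None) for k, v in self.vifs.items()},
            "df_convention": self.lmm.df_convention,
        }
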