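"""Across-subject statistics: participant count maps, mixed-effects models
of tuning geometry, and the categorical-GLM control analysis."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .conditioning import average_runs
from .schedule import StimulusSchedule
from .tuning import canonical_hrf, condition_regressors

__all__ = [
    "ContrastSpec",
    "participant_count_map",
    "mixed_effects_geometry",
    "categorical_glm_contrast",
    "group_t_test",
]


@dataclass(frozen=True)
class ContrastSpec:
    """Contrast over the six condition regressors (1, 2, 3, 4, 5, 20).

    The default weights implement "small numerosities minus baseline":
    (1/5, 1/5, 1/5, 1/5, 1/5, -1), summing to zero.
    """

    conditions: tuple = (1, 2, 3, 4, 5, 20)
    weights: tuple = (0.2, 0.2, 0.2, 0.2, 0.2, -1.0)

    def __post_init__(self) -> None:
        if len(self.conditions) != len(self.weights):
            raise ValueError("one weight per condition required")
        if abs(sum(self.weights)) > 1e-12:
            raise ValueError("contrast weights must sum to zero")


def participant_count_map(masks) -> np.ndarray:
    """Per-vertex count of subjects selected at that vertex (standard space)."""
    masks = [np.asarray(m, dtype=bool) for m in masks]
    lengths = {len(m) for m in masks}
    if len(lengths) != 1:
        raise ValueError("selection masks must share one vertex index space")
    return np.sum(masks, axis=0).astype(int)


def mixed_effects_geometry(table: pd.DataFrame, dependent: str = "area") -> pd.DataFrame:
    """Linear mixed-effects model of binned tuning geometry.

    Fixed effects: hemisphere (two-level factor, L reference) and
    hemisphere-specific slopes of preferred numerosity; random intercept
    per subject; REML estimation. ``table`` needs columns subject, hemi
    ('L'/'R'), mu (bin center) and the dependent ('area' in mm^2 or
    'fwhm'). Returns one row per fixed effect with coefficient, Wald z,
    p-value and 95% CI — the hemi / mu[L] / mu[R] layout.

    Falls back to pooled OLS (with a warning) if the random-effects fit is
    singular.
    """
    if dependent not in ("area", "fwhm"):
        raise ValueError("dependent must be 'area' or 'fwhm'")
    df = table.copy()
    required = {"subject", "hemi", "mu", dependent}
    if not required.issubset(df.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    if df["subject"].nunique() < 2 or df["hemi"].nunique() < 2:
        raise ValueError("need >= 2 subjects and both hemispheres")
    formula = f"{dependent} ~ C(hemi, Treatment('L')) + mu:C(hemi)"

    def _frame(params, bse, pvalues, conf):
        rows = {}
        for name in params.index:
            if "Intercept" in name:
                continue
            if "T.R" in name and "mu" not in name:
                key = "hemi"
            elif "mu" in name and "[L]" in name:
                key = "mu[L]"
            elif "mu" in name and "[R]" in name:
                key = "mu[R]"
            else:
                continue
            z = params[name] / bse[name]
            rows[key] = {
                "coef": params[name], "z": z, "p": pvalues[name],
                "ci_low": conf.loc[name, 0], "ci_high": conf.loc[name, 1],
            }
        return pd.DataFrame(rows).T.loc[["hemi", "mu[L]", "mu[R]"]]

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, df, groups=df["subject"])
            fit = model.fit(reml=True)
        if not np.isfinite(fit.bse.iloc[:-1]).all():
            raise np.linalg.LinAlgError("singular mixed-effects fit")
        params = fit.params.drop("Group Var", errors="ignore")
        bse = fit.bse.drop("Group Var", errors="ignore")
        conf = fit.conf_int().drop("Group Var", errors="ignore")
        return _frame(params, bse, fit.pvalues, conf)
    except (np.linalg.LinAlgError, ValueError):
        warnings.warn("singular random-effects fit; falling back to pooled OLS",
                      stacklevel=2)
        fit = smf.ols(formula, df).fit()
        return _frame(fit.params, fit.bse, fit.pvalues, fit.conf_int())


def categorical_glm_contrast(runs, schedule: StimulusSchedule, confounds=None,
                             spec: ContrastSpec = ContrastSpec(), dt: float = 0.1):
    """Categorical GLM control analysis for one subject.

    Fits six HRF-convolved condition boxcar regressors (numerosities 1–5
    and 20) plus confounds and an intercept to the run-averaged signal by
    OLS, and returns (contrast, se) per vertex for the given weights.
    """
    runs = [np.asarray(r, dtype=float) for r in runs]
    y = average_runs(runs)
    if y.ndim == 1:
        y = y[:, None]
    hrf = canonical_hrf(dt)
    C = condition_regressors(schedule, hrf, spec.conditions)
    parts = [C]
    if confounds is not None:
        X_conf = (confounds.to_numpy(dtype=float)
                  if isinstance(confounds, pd.DataFrame)
                  else np.asarray(confounds, dtype=float))
        parts.append(X_conf)
    X = np.column_stack(parts + [np.ones(len(y))])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient categorical design")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
    c = np.zeros(X.shape[1])
    c[: len(spec.weights)] = spec.weights
    xtx_inv = np.linalg.inv(X.T @ X)
    var_scale = float(c @ xtx_inv @ c)
    contrast = c @ beta
    se = np.sqrt(sigma2 * var_scale)
    if contrast.shape[0] == 1 and np.ndim(runs[0]) == 1:
        return float(contrast[0]), float(se[0])
    return contrast, se


def group_t_test(values) -> dict:
    """One-sample t-test of per-subject contrast values against zero.

    Reports t and one-sided p-values for both directions (positive:
    small numerosities > baseline; negative: baseline > small).
    Zero-variance inputs are flagged and yield undefined t.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim == 1:
        v = v[:, None]
    if v.shape[0] < 2:
        raise ValueError("need >= 2 subjects")
    sd = v.std(axis=0, ddof=1)
    zero_var = sd < 1e-300
    with np.errstate(invalid="ignore", divide="ignore"):
        t = v.mean(axis=0) / (sd / np.sqrt(v.shape[0]))
    t[zero_var] = np.nan
    dof = v.shape[0] - 1
    p_pos = stats.t.sf(t, dof)
    p_neg = stats.t.cdf(t, dof)
    out = {"t": t, "p_positive": p_pos, "p_negative": p_neg,
           "zero_variance": zero_var}
    if v.shape[1] == 1 and np.ndim(values) == 1:
        out = {k: (a[0] if isinstance(a, np.ndarray) else a)
               for k, a in out.items()}
    return out
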