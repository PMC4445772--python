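"""Cohort-level estimation of pure-tissue metabolite levels.

The per-voxel model is a random-intercept linear mixed model

    y_ij = beta0 + beta1 * x_ij + u_i + eps_ij,     u_i ~ N(0, sigma_subj^2)

where y is a metabolite level (IU) or a per-voxel ratio and x is the
normalised tissue contrast (%WM - %GM)/(%WM + %GM), so that x = +1 is pure
white matter and x = -1 pure grey matter.  The extrapolated pure-tissue
levels are then wm = beta0 + beta1 and gm = beta0 - beta1.  Estimation is
by REML (statsmodels MixedLM) with a Wald test on beta1; a fixed-effects
ANOVA variant (subject as a fixed factor) is available for comparison.

Ratios are modelled per voxel exactly like levels.  Because a quotient is
a convex function of x, the extrapolated ratio estimates need not equal
quotients of the extrapolated levels; both are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf


@dataclass
class CohortFit:
    """Mixed-model tissue regression for one response."""

    response: str
    beta0: float
    beta1: float
    sigma_subject: float
    sigma_resid: float
    p_tissue: float
    n_voxels: int
    n_subjects: int
    method: str = "mixed"

    @property
    def wm_estimate(self) -> float:
        return self.beta0 + self.beta1

    @property
    def gm_estimate(self) -> float:
        return self.beta0 - self.beta1

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "beta0": self.beta0,
            "beta1": self.beta1,
            "wm_estimate": self.wm_estimate,
            "gm_estimate": self.gm_estimate,
            "sigma_subject": self.sigma_subject,
            "sigma_resid": self.sigma_resid,
            "p_tissue": self.p_tissue,
            "n_voxels": self.n_voxels,
            "n_subjects": self.n_subjects,
            "method": self.method,
        }


@dataclass
class CorrelationResult:
    var_a: str
    var_b: str
    r: float
    p: float
    n: int
    defined: bool = True


def fit_tissue_model(
    table: pd.DataFrame,
    response: str,
    x_col: str = "x",
    subject_col: str = "subject",
    method: str = "mixed",
) -> CohortFit:
    """Fit the tissue-contrast model for one response column.

    ``table`` holds one row per valid voxel.  Raises on fewer than two
    subjects or on a design with no tissue contrast (all x equal).
    """
    df = table[[subject_col, x_col, response]].dropna()
    subjects = df[subject_col].unique()
    if len(subjects) < 2:
        raise ValueError("need at least two subjects")
    x = df[x_col].to_numpy(dtype=float)
    y = df[response].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("no tissue contrast: all x values are equal")

    # Degenerate noiseless case: a perfect linear fit leaves REML without
    # an identifiable variance decomposition; return the exact solution.
    X = np.column_stack([np.ones_like(x), x])
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_ols
    ssr = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    if ssr <= 1e-12 * max(sst, 1.0):
        return CohortFit(
            response=response,
            beta0=float(beta_ols[0]),
            beta1=float(beta_ols[1]),
            sigma_subject=0.0,
            sigma_resid=0.0,
            p_tissue=0.0 if beta_ols[1] != 0 else 1.0,
            n_voxels=len(df),
            n_subjects=len(subjects),
            method="exact",
        )

    if method == "mixed":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, X, groups=df[subject_col].to_numpy())
            fit = model.fit(reml=True)
        cov_re = float(np.asarray(fit.cov_re)[0, 0])
        scale = float(max(fit.scale, 0.0))
        # REML boundary: when the subject variance collapses to zero the
        # profiled intercept can be lost (few groups); the model then IS
        # pooled OLS, so report that solution instead
        degenerate = (
            not np.all(np.isfinite(fit.fe_params))
            or cov_re <= 1e-10 * max(scale, 1e-300)
        )
        if not degenerate:
            return CohortFit(
                response=response,
                beta0=float(fit.fe_params[0]),
                beta1=float(fit.fe_params[1]),
                sigma_subject=float(np.sqrt(max(cov_re, 0.0))),
                sigma_resid=float(np.sqrt(scale)),
                p_tissue=float(fit.pvalues[1]),
                n_voxels=len(df),
                n_subjects=len(subjects),
                method="mixed",
            )
        ols = sm.OLS(y, X).fit()
        return CohortFit(
            response=response,
            beta0=float(ols.params[0]),
            beta1=float(ols.params[1]),
            sigma_subject=0.0,
            sigma_resid=float(np.sqrt(ols.mse_resid)),
            p_tissue=float(ols.pvalues[1]),
            n_voxels=len(df),
            n_subjects=len(subjects),
            method="mixed-ols-boundary",
        )
    elif method == "anova":
        # fixed-effects variant: subject as a (sum-coded) fixed factor
        d = df.rename(columns={response: "_y", x_col: "_x", subject_col: "_s"})
        fit = smf.ols("_y ~ _x + C(_s, Sum)", data=d).fit()
        return CohortFit(
            response=response,
            beta0=float(fit.params["Intercept"]),
            beta1=float(fit.params["_x"]),
            sigma_subject=float(np.std([v for k, v in fit.params.items() if "C(_s" in k], ddof=0)) if len(subjects) > 1 else 0.0,
            sigma_resid=float(np.sqrt(fit.mse_resid)),
            p_tissue=float(fit.pvalues["_x"]),
            n_voxels=len(df),
            n_subjects=len(subjects),
            method="anova",
        )
    raise ValueError(f"unknown method {method!r}")


def subject_summaries(
    table: pd.DataFrame,
    attrition: dict[str, dict] | None = None,
    naa_fwhm: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per subject: mean levels/ratios, yield, mean NAA linewidth.

    ``table`` is the long valid-voxel table (one row per voxel with level
    and ratio columns).  ``attrition`` maps subject -> attrition dict for
    the percent-valid computation; ``naa_fwhm`` optionally supplies the
    per-voxel NAA linewidths of NAA-valid (retained) voxels.
    """
    num_cols = [c for c in table.columns if c not in ("subject", "voxel_x", "voxel_y")
                and pd.api.types.is_numeric_dtype(table[c])]
    out = table.groupby("subject")[num_cols].mean()
    out["n_valid"] = table.groupby("subject").size()
    if attrition is not None:
        pct = {}
        for subj, att in attrition.items():
            n_tot = att["n_total"]
            pct[subj] = 100.0 * att["n_valid_all"] / n_tot if n_tot else np.nan
        out["percent_valid"] = pd.Series(pct)
    if naa_fwhm is not None:
        out["mean_naa_fwhm_hz"] = naa_fwhm.groupby("subject")["naa_fwhm_hz"].mean()
    return out.reset_index()


def correlate(
    summaries: pd.DataFrame, var_a: str, var_b: str
) -> CorrelationResult:
    """Pearson correlation across subjects with a two-sided t-test p."""
    df = summaries[[var_a, var_b]].dropna()
    n = len(df)
    if n < 3:
        raise ValueError("need at least three paired observations")
    a = df[var_a].to_numpy(dtype=float)
    b = df[var_b].to_numpy(dtype=float)
    if np.std(a) == 0 or np.std(b) == 0:
        return CorrelationResult(var_a, var_b, np.nan, np.nan, n, defined=False)
    r, p = scipy.stats.pearsonr(a, b)
    return CorrelationResult(var_a, var_b, float(r), float(p), n)
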