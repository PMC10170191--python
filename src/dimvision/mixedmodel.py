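"""Random-intercept linear mixed models by maximum likelihood, from scratch.

The model for observation j of group (subject) i is

    y_ij = x_ij' beta + b_i + e_ij,   b_i ~ N(0, sigma_b^2),  e_ij ~ N(0, sigma^2)

fitted by full maximum likelihood (not REML, so likelihood-ratio tests on the
fixed effects are valid).  The likelihood is profiled over the variance ratio
lambda = sigma_b^2 / sigma^2: for fixed lambda the per-group marginal
covariance is V_i = I + lambda * 11', whose inverse and log-determinant are
closed-form, so beta and sigma^2 come from generalized least squares and a
bounded one-dimensional search over lambda does the rest.  The fit is
deterministic: no random initialisation.

Also here: likelihood-ratio tests of nested fits, AIC, back-transformed
per-level estimates with Wald confidence intervals, pairwise Wald-z contrasts
with multiplicity adjustment, and the response-time / inter-trial-time
summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

Transform = Literal["log10", "inverse", "identity"]

_TRANSFORMS = {
    "log10": (np.log10, lambda x: 10.0**x),
    "inverse": (lambda x: 1.0 / x, lambda x: 1.0 / x),
    "identity": (lambda x: x, lambda x: x),
}


@dataclass(frozen=True)
class ModelSpec:
    """Model description: response, transform, fixed terms, grouping factor.

    ``fixed_terms`` are column names; categorical (non-numeric) columns are
    dummy-coded against their first sorted level, and ``a:b`` denotes an
    interaction (element-wise products of the two terms' columns).  An
    intercept is always included.
    """

    response: str
    fixed_terms: tuple[str, ...]
    grouping_factor: str
    response_transform: Transform = "identity"


@dataclass
class LMMFit:
    """A fitted random-intercept LMM (maximum likelihood)."""

    spec: ModelSpec
    beta: pd.Series  # fixed effects, transformed scale
    cov_beta: pd.DataFrame  # Wald covariance of beta
    sigma_b2: float
    sigma2: float
    loglik: float
    n_obs: int
    n_params: int  # fixed effects + 2 variance components
    converged: bool
    factor_levels: dict[str, list] = field(default_factory=dict)
    covariate_means: dict[str, float] = field(default_factory=dict)

    @property
    def n_fixed(self) -> int:
        return len(self.beta)


def _term_columns(df: pd.DataFrame, term: str, factor_levels: dict) -> pd.DataFrame:
    """Design columns for one term (dummy-coded factors, numeric covariates,
    ':'-interactions as products)."""
    parts = term.split(":")
    out: Optional[pd.DataFrame] = None
    for part in parts:
        if part not in df.columns:
            raise KeyError(f"term {part!r} not in data")
        col = df[part]
        if pd.api.types.is_numeric_dtype(col) and not pd.api.types.is_bool_dtype(col):
            block = pd.DataFrame({part: col.astype(float)})
        else:
            levels = factor_levels.setdefault(part, sorted(col.astype(str).unique()))
            block = pd.DataFrame(
                {
                    f"{part}[{lv}]": (col.astype(str) == lv).astype(float)
                    for lv in levels[1:]  # first level is the reference
                }
            )
        if out is None:
            out = block
        else:
            out = pd.DataFrame(
                {
                    f"{a}:{b}": out[a].to_numpy() * block[b].to_numpy()
                    for a in out.columns
                    for b in block.columns
                },
                index=df.index,
            )
    assert out is not None
    return out


def build_design(
    df: pd.DataFrame,
    fixed_terms: Sequence[str],
    factor_levels: Optional[dict] = None,
) -> tuple[np.ndarray, list[str], dict]:
    """Fixed-effects design matrix with intercept; returns (X, names, levels)."""
    factor_levels = dict(factor_levels or {})
    blocks = [pd.DataFrame({"Intercept": np.ones(len(df))}, index=df.index)]
    for term in fixed_terms:
        blocks.append(_term_columns(df, term, factor_levels))
    X = pd.concat(blocks, axis=1)
    return X.to_numpy(float), list(X.columns), factor_levels


def _profile_loglik(
    lam: float, y: np.ndarray, X: np.ndarray, group_slices: list[slice]
) -> tuple[float, np.ndarray, float, np.ndarray]:
    """Profiled ML log-likelihood at variance ratio ``lam``.

    Returns (loglik, beta, sigma2, XtVinvX) using the closed-form per-group
    inverse V_i^{-1} = I - (lam / (1 + lam n_i)) 11'.
    """
    n, p = X.shape
    A = np.zeros((p, p))
    bvec = np.zeros(p)
    logdet = 0.0
    for sl in group_slices:
        Xi, yi = X[sl], y[sl]
        ni = Xi.shape[0]
        c = lam / (1.0 + lam * ni)
        xs, ys = Xi.sum(axis=0), yi.sum()
        A += Xi.T @ Xi - c * np.outer(xs, xs)
        bvec += Xi.T @ yi - c * xs * ys
        logdet += np.log1p(lam * ni)
    beta = np.linalg.solve(A, bvec)
    rss_v = 0.0
    for sl in group_slices:
        ri = y[sl] - X[sl] @ beta
        ni = ri.shape[0]
        c = lam / (1.0 + lam * ni)
        rss_v += ri @ ri - c * ri.sum() ** 2
    sigma2 = max(rss_v / n, 1e-300)  # guard: perfectly fit (degenerate) data
    loglik = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)
    return loglik, beta, sigma2, A


def fit_lmm(data: pd.DataFrame, spec: ModelSpec) -> LMMFit:
    """Fit the random-intercept LMM by profiled maximum likelihood.

    Deterministic given the data: beta and sigma^2 are profiled out in closed
    form and a bounded scalar search over log(lambda) (plus an explicit
    boundary evaluation at lambda = 0) locates the optimum to ~1e-10 in the
    profiled log-likelihood.  A fit that maximises at the boundary is returned
    with ``sigma_b2 = 0``; it coincides with ordinary least squares.
    """
    df = data.dropna(subset=[spec.response, spec.grouping_factor]).copy()
    y_raw = df[spec.response].to_numpy(float)
    fwd, _ = _TRANSFORMS[spec.response_transform]
    if spec.response_transform in ("log10", "inverse") and np.any(y_raw <= 0):
        raise ValueError(f"{spec.response_transform} transform needs positive responses")
    y = fwd(y_raw)

    groups = df[spec.grouping_factor].astype(str).to_numpy()
    if len(np.unique(groups)) < 2:
        raise ValueError("grouping factor must have at least 2 groups")
    order = np.argsort(groups, kind="stable")
    df = df.iloc[order]
    y = y[order]
    groups = groups[order]

    X, names, factor_levels = build_design(df, spec.fixed_terms)
    boundaries = np.flatnonzero(np.r_[True, groups[1:] != groups[:-1], True])
    group_slices = [
        slice(a, b) for a, b in zip(boundaries[:-1], boundaries[1:])
    ]

    def neg(t: float) -> float:
        return -_profile_loglik(np.exp(t), y, X, group_slices)[0]

    res = optimize.minimize_scalar(
        neg, bounds=(-16.0, 12.0), method="bounded", options={"xatol": 1e-10}
    )
    ll_opt, beta_opt, s2_opt, A_opt = _profile_loglik(
        np.exp(res.x), y, X, group_slices
    )
    ll_0, beta_0, s2_0, A_0 = _profile_loglik(0.0, y, X, group_slices)
    if ll_0 >= ll_opt:
        lam, ll, beta, s2, A = 0.0, ll_0, beta_0, s2_0, A_0
    else:
        lam, ll, beta, s2, A = float(np.exp(res.x)), ll_opt, beta_opt, s2_opt, A_opt
        if lam < 1e-7:  # effectively at the boundary
            lam = 0.0
            ll, beta, s2, A = ll_0, beta_0, s2_0, A_0
    converged = bool(res.success or ll_0 >= ll_opt)

    cov = s2 * np.linalg.inv(A)
    covariate_means = {
        t: float(df[t].mean())
        for t in _numeric_terms(spec.fixed_terms, df)
    }
    return LMMFit(
        spec=spec,
        beta=pd.Series(beta, index=names),
        cov_beta=pd.DataFrame(cov, index=names, columns=names),
        sigma_b2=lam * s2,
        sigma2=float(s2),
        loglik=float(ll),
        n_obs=len(y),
        n_params=len(beta) + 2,
        converged=converged,
        factor_levels=factor_levels,
        covariate_means=covariate_means,
    )


def _numeric_terms(fixed_terms: Sequence[str], df: pd.DataFrame) -> list[str]:
    out = []
    for term in fixed_terms:
        for part in term.split(":"):
            if part in df.columns and pd.api.types.is_numeric_dtype(df[part]):
                if part not in out:
                    out.append(part)
    return out


def likelihood_ratio_test(full: LMMFit, reduced: LMMFit) -> tuple[float, int, float]:
    """Chi-squared likelihood-ratio test of nested ML fits.

    Returns (statistic, df, p).  df is the difference in fixed-effect counts;
    the statistic is clipped at 0 (nesting guarantees non-negativity up to
    optimiser tolerance).
    """
    if full.n_obs != reduced.n_obs:
        raise ValueError("fits must use the same data")
    if full.n_fixed <= reduced.n_fixed:
        raise ValueError("'full' must have more fixed-effect parameters")
    if not set(reduced.spec.fixed_terms) <= set(full.spec.fixed_terms):
        raise ValueError("reduced model terms must nest within the full model")
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    df = full.n_fixed - reduced.n_fixed
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return stat, df, p


def aic(fit: LMMFit) -> float:
    """Akaike information criterion, variance components counted as parameters."""
    if not fit.converged:
        raise ValueError("AIC requires a converged fit")
    return -2.0 * fit.loglik + 2.0 * fit.n_params


@dataclass(frozen=True)
class EstimateWithCI:
    """Back-transformed per-level estimate with a Wald 95% interval."""

    label: str
    point: float
    lower: float
    upper: float


def _level_rows(fit: LMMFit, factor: str) -> tuple[list, np.ndarray]:
    """Design rows predicting each level of ``factor`` with numeric covariates
    at their data means and other factors at their reference level."""
    if factor not in fit.factor_levels:
        raise ValueError(f"{factor!r} is not a categorical term of the fit")
    levels = fit.factor_levels[factor]
    rows = []
    for lv in levels:
        row = pd.Series(0.0, index=fit.beta.index)
        row["Intercept"] = 1.0
        col = f"{factor}[{lv}]"
        if col in row.index:
            row[col] = 1.0
        for name in row.index:
            # numeric covariate main effects held at their means
            if name in fit.covariate_means:
                row[name] = fit.covariate_means[name]
        rows.append(row.to_numpy())
    return levels, np.vstack(rows)


def back_transform_estimates(
    fit: LMMFit, factor: str, alpha: float = 0.05
) -> list[EstimateWithCI]:
    """Per-level point estimates and Wald CIs mapped back to the natural scale.

    Intervals are computed on the transformed scale and pushed through the
    inverse map; for the inverse transform the endpoints swap to keep
    lower <= upper.  A non-positive bound under a non-identity transform maps
    to a flagged (NaN) endpoint rather than a spurious value.
    """
    _, inv = _TRANSFORMS[fit.spec.response_transform]
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    levels, L = _level_rows(fit, factor)
    est = L @ fit.beta.to_numpy()
    se = np.sqrt(np.einsum("ij,jk,ik->i", L, fit.cov_beta.to_numpy(), L))
    out = []
    for lv, e, s in zip(levels, est, se):
        lo_t, hi_t = e - z * s, e + z * s
        if fit.spec.response_transform == "inverse":
            bounds = []
            for b in (hi_t, lo_t):  # inverse is decreasing: endpoints swap
                bounds.append(float(inv(b)) if b > 0 else float("nan"))
            lo, hi = bounds
            point = float(inv(e)) if e > 0 else float("nan")
        else:
            lo, hi, point = float(inv(lo_t)), float(inv(hi_t)), float(inv(e))
        out.append(EstimateWithCI(label=str(lv), point=point, lower=lo, upper=hi))
    return out


def pairwise_comparisons(
    fit: LMMFit, factor: str, adjust: Literal["holm", "bonferroni", "none"] = "holm"
) -> pd.DataFrame:
    """All pairwise Wald-z contrasts between the levels of ``factor``.

    An approximation to single-step Tukey adjustment: z statistics on the
    transformed scale with Holm (default) or Bonferroni multiplicity control.
    """
    levels, L = _level_rows(fit, factor)
    cov = fit.cov_beta.to_numpy()
    beta = fit.beta.to_numpy()
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            c = L[i] - L[j]
            diff = float(c @ beta)
            se = float(np.sqrt(c @ cov @ c))
            zstat = diff / se if se > 0 else 0.0
            p = float(2.0 * stats.norm.sf(abs(zstat)))
            rows.append(
                {
                    "contrast": f"{levels[i]} - {levels[j]}",
                    "estimate": diff,
                    "se": se,
                    "z": zstat,
                    "p_unadjusted": p,
                }
            )
    table = pd.DataFrame(rows)
    if adjust == "none":
        table["p_adjusted"] = table["p_unadjusted"]
    else:
        table["p_adjusted"] = multipletests(
            table["p_unadjusted"].to_numpy(), method=adjust
        )[1]
    return table


def summarize_times(trial_logs) -> pd.DataFrame:
    """Median and quartiles of response and inter-trial times per experiment.

    Trials flagged as multiple-entry are excluded from the response-time
    summaries only; inter-trial summaries keep every trial.
    """
    rows = []
    for log in trial_logs:
        for rec in log:
            rows.append(
                {
                    "experiment": rec.experiment,
                    "response_time": rec.response_time,
                    "inter_trial_time": rec.inter_trial_time,
                    "multi_entry": rec.multi_entry,
                }
            )
    df = pd.DataFrame(rows)
    out = []
    for exp, grp in df.groupby("experiment"):
        rt = grp.loc[~grp["multi_entry"], "response_time"]
        itt = grp["inter_trial_time"]
        out.append(
            {
                "experiment": exp,
                "n_choices": len(grp),
                "n_response_time": len(rt),
                "response_time_median": rt.median(),
                "response_time_q1": rt.quantile(0.25),
                "response_time_q3": rt.quantile(0.75),
                "inter_trial_median": itt.median(),
                "inter_trial_q1": itt.quantile(0.25),
                "inter_trial_q3": itt.quantile(0.75),
            }
        )
    return pd.DataFrame(out)
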