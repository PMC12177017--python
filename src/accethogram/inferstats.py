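"""Comparison statistics: maximum-likelihood beta regression on accuracy
proportions, OLS for drag coefficients, Wald tests, and estimated-marginal-
means pairwise contrasts with Tukey adjustment.

Beta regression models a (0,1) response y_i ~ Beta(mu_i * phi, (1 - mu_i) * phi)
with logit(mu_i) = x_i' beta and a constant precision phi (log link), the
standard parameterisation for accuracy/proportion responses.  Accuracies
that touch 0 or 1 are squeezed with the usual compression
y' = (y * (n - 1) + 0.5) / n before fitting, since the beta likelihood is
undefined at the boundaries.

Pairwise contrasts follow the estimated-marginal-means recipe: a reference
grid is built over the crossed factor levels, model-matrix rows are
averaged over the levels of the non-focal factors, differences of marginal
means are computed on the link scale with delta-method standard errors, and
p-values use the Tukey (studentized-range) adjustment within the factor
family.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from patsy import build_design_matrices
from scipy import stats
from statsmodels.formula.api import ols as _sm_ols
from statsmodels.othermod.betareg import BetaModel

__all__ = [
    "RegressionDesign",
    "BetaRegFit",
    "OlsFit",
    "ContrastResult",
    "fit_beta_regression",
    "wald_tests",
    "pairwise_contrasts",
    "fit_ols",
    "squeeze_proportions",
]


@dataclass(frozen=True)
class RegressionDesign:
    """A response name plus a patsy right-hand-side formula (treatment
    contrasts with the default first-level reference)."""

    response: str
    rhs: str

    @property
    def formula(self) -> str:
        return f"{self.response} ~ {self.rhs}"


@dataclass
class BetaRegFit:
    """Maximum-likelihood beta-regression fit (mean model on the logit
    link, constant precision on the log link)."""

    beta: pd.Series
    phi: float
    vcov: pd.DataFrame
    loglik: float
    n: int
    converged: bool
    design: RegressionDesign
    link: str = "logit"
    df_resid: float = np.inf
    _res: object = field(default=None, repr=False)

    @property
    def fitted_means(self) -> np.ndarray:
        return np.asarray(self._res.fittedvalues)


@dataclass
class OlsFit:
    """Ordinary least-squares fit with classical standard errors."""

    beta: pd.Series
    vcov: pd.DataFrame
    loglik: float
    n: int
    df_resid: float
    design: RegressionDesign
    converged: bool = True
    link: str = "identity"
    _res: object = field(default=None, repr=False)


@dataclass(frozen=True)
class ContrastResult:
    """One pairwise difference of estimated marginal means on the link
    scale."""

    contrast: str
    estimate: float
    se: float
    z_ratio: float
    p_value: float
    adjustment: str
    df: float


def squeeze_proportions(y: np.ndarray) -> np.ndarray:
    """Compress proportions off the boundary: y' = (y (n-1) + 0.5) / n."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    return (y * (n - 1) + 0.5) / n


def fit_beta_regression(design: RegressionDesign, data: pd.DataFrame) -> BetaRegFit:
    """Fit the beta regression by maximum likelihood.

    The boundary squeeze is applied automatically when any response lies
    outside (0, 1) exclusive.  Non-convergence is flagged on the returned
    fit, never silent.
    """
    data = data.copy()
    y = data[design.response].to_numpy(dtype=float)
    if np.any(y <= 0) or np.any(y >= 1):
        data[design.response] = squeeze_proportions(y)
    model = BetaModel.from_formula(design.formula, data)
    if len(data) <= model.exog.shape[1] + 1:
        raise ValueError(
            f"n={len(data)} too small for {model.exog.shape[1]} mean coefficients"
        )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=500, disp=False)
        converged = bool(getattr(res, "mle_retvals", {}).get("converged", True))
        if not converged:
            # quasi-Newton stall on flat likelihoods: polish with a simplex
            # restart from the stalled parameters
            res2 = model.fit(start_params=res.params, method="nm",
                             maxiter=5000, disp=False)
            if res2.llf >= res.llf:
                res = res2
            converged = bool(getattr(res, "mle_retvals", {}).get("converged", True))
    params = res.params
    mean_names = [p for p in params.index if p != "precision"]
    try:
        vcov = res.cov_params().loc[mean_names, mean_names]
    except ValueError:  # singular Hessian: flag, do not fail silently
        converged = False
        vcov = pd.DataFrame(np.nan, index=mean_names, columns=mean_names)
    return BetaRegFit(
        beta=params[mean_names],
        phi=float(np.exp(params["precision"])),
        vcov=vcov,
        loglik=float(res.llf),
        n=len(data),
        converged=converged,
        design=design,
        _res=res,
    )


def fit_ols(design: RegressionDesign, data: pd.DataFrame) -> OlsFit:
    """Ordinary least squares via the same design interface; rank-deficient
    model matrices raise."""
    model = _sm_ols(design.formula, data)
    X = model.exog
    if len(data) <= X.shape[1]:
        raise ValueError(f"n={len(data)} too small for {X.shape[1]} coefficients")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient model matrix (collinear or missing levels)")
    # patsy silently collapses single-level factors; that is still a
    # rank-deficient request (the factor's effect is unidentifiable)
    for fac, info in model.data.design_info.factor_infos.items():
        if info.type == "categorical" and len(info.categories) < 2:
            raise ValueError(
                f"rank-deficient design: factor '{fac.name()}' has a single level"
            )
    res = model.fit()
    return OlsFit(
        beta=res.params,
        vcov=res.cov_params(),
        loglik=float(res.llf),
        n=len(data),
        df_resid=float(res.df_resid),
        design=design,
        _res=res,
    )


def wald_tests(fit: BetaRegFit | OlsFit) -> pd.DataFrame:
    """Per-coefficient (estimate, SE, Z, two-sided P).  Beta-regression
    tests use the normal reference (df = inf); OLS uses Student t on the
    residual df."""
    if not fit.converged:
        raise ValueError("fit did not converge; Wald tests unreliable")
    est = fit.beta
    se = pd.Series(np.sqrt(np.diag(fit.vcov)), index=est.index)
    z = est / se
    if np.isfinite(fit.df_resid):
        p = 2 * stats.t.sf(np.abs(z), df=fit.df_resid)
    else:
        p = 2 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {"term": est.index, "estimate": est.values, "se": se.values,
         "z": z.values, "p": p}
    ).reset_index(drop=True)


def _reference_grid(
    data: pd.DataFrame, design_info, factor: str, at: dict | None
) -> pd.DataFrame:
    """Cross the levels of every categorical variable in the model; hold
    numeric covariates at their mean (or at the values given in ``at``).
    Formulas must use bare column names so the grid can be evaluated."""
    at = dict(at or {})
    cols: dict[str, list] = {}
    for fac, info in design_info.factor_infos.items():
        name = fac.name()
        if name not in data.columns:
            raise ValueError(
                f"pairwise_contrasts needs bare column names in the formula; "
                f"cannot build a reference grid for term '{name}'"
            )
        if name in at:
            cols[name] = [at[name]]
        elif info.type == "categorical":
            cols[name] = list(info.categories)
        elif name == factor:
            cols[name] = sorted(pd.unique(data[name]))
        else:
            cols[name] = [float(data[name].mean())]
    if factor not in cols:
        raise ValueError(f"factor '{factor}' not in design")
    names = list(cols)
    grid = pd.DataFrame(
        [dict(zip(names, combo)) for combo in itertools.product(*(cols[n] for n in names))]
    )
    return grid


def pairwise_contrasts(
    fit: BetaRegFit | OlsFit,
    factor: str,
    at: dict | None = None,
    adjustment: str = "tukey",
) -> list[ContrastResult]:
    """All pairwise differences of estimated marginal means for ``factor``.

    Marginal means are computed on the link scale by averaging model-matrix
    rows over the reference grid; SEs follow from the coefficient
    covariance by the delta method.  With ``adjustment="tukey"`` the
    p-value for |z| uses the studentized-range distribution with k = number
    of levels (the emmeans default for a single factor family); "none"
    gives unadjusted two-sided p-values.
    """
    res = fit._res
    design_info = res.model.data.design_info
    data = pd.DataFrame(res.model.data.frame)
    grid = _reference_grid(data, design_info, factor, at)
    levels = list(grid[factor].unique())
    if len(levels) < 2:
        raise ValueError(f"factor '{factor}' has fewer than two levels")
    (X,) = build_design_matrices([design_info], grid)
    X = np.asarray(X)
    emm_rows = {}
    for lev in levels:
        mask = (grid[factor] == lev).to_numpy()
        emm_rows[lev] = X[mask].mean(axis=0)
    beta = fit.beta.to_numpy()
    V = fit.vcov.to_numpy()
    k = len(levels)
    df = fit.df_resid
    out: list[ContrastResult] = []
    for a, b in itertools.combinations(levels, 2):
        L = emm_rows[a] - emm_rows[b]
        est = float(L @ beta)
        se = float(np.sqrt(max(L @ V @ L, 0.0)))
        # degenerate cases (e.g. exactly equal responses): a numerically
        # zero difference is a zero difference, whatever the tiny SE says
        if abs(est) < 1e-12:
            z = 0.0
        elif se > 0:
            z = est / se
        else:
            z = np.inf * np.sign(est)
        if adjustment == "tukey":
            q_df = df if np.isfinite(df) else 1e7
            p = float(stats.studentized_range.sf(abs(z) * np.sqrt(2), k, q_df))
        elif adjustment == "none":
            p = float(
                2 * stats.t.sf(abs(z), df) if np.isfinite(df) else 2 * stats.norm.sf(abs(z))
            )
        else:
            raise ValueError(f"unknown adjustment '{adjustment}'")
        out.append(
            ContrastResult(
                contrast=f"{a} - {b}",
                estimate=est,
                se=se,
                z_ratio=z,
                p_value=min(max(p, 0.0), 1.0),
                adjustment=adjustment,
                df=df,
            )
        )
    return out


def contrasts_to_frame(contrasts: list[ContrastResult]) -> pd.DataFrame:
    """Tidy one-row-per-contrast table."""
    return pd.DataFrame(
        [
            {
                "contrast": c.contrast,
                "estimate": c.estimate,
                "se": c.se,
                "z_ratio": c.z_ratio,
                "p_value": c.p_value,
                "adjustment": c.adjustment,
            }
            for c in contrasts
        ]
    )
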