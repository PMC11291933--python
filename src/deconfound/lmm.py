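"""Random-intercept linear mixed models and nested likelihood-ratio tests.

Responses are midranked feature abundances; each model carries a
per-subject random intercept to absorb the correlation between repeated
samples of the same patient.  All fits use full maximum likelihood (not
REML) because every likelihood-ratio test here compares *fixed-effect*
structures, which REML likelihoods cannot do validly.

Two degeneracies are handled explicitly rather than silently:

* one observation per subject -- the random intercept is unidentifiable
  and the fit falls back to ordinary least squares (flagged);
* a singular fit (random-intercept variance estimated at the zero
  boundary) -- the mixed likelihood equals the OLS likelihood, and the
  fit is flagged ``singular`` with the OLS log-likelihood used.

Non-converged fits are flagged so callers can report the affected pair
as untestable instead of mislabeling it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = ["MixedModelFit", "LrtResult", "fit_lmm", "lrt", "classify_two_tests"]

_SINGULAR_TOL = 1e-6  # random-effect variance below this x residual variance


@dataclass
class MixedModelFit:
    formula: str
    llf: float
    n_fixed: int            # fixed-effect columns including the intercept
    n_obs: int
    converged: bool
    singular: bool
    fallback_ols: bool
    params: pd.Series
    re_variance: float
    dropped_terms: list[str] = field(default_factory=list)


def _drop_collinear(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Greedily drop later columns until the design is full rank."""
    dropped: list[str] = []
    while X.shape[1] > 1:
        arr = X.to_numpy(dtype=float)
        rank = np.linalg.matrix_rank(arr)
        if rank == X.shape[1]:
            break
        # drop the last column not contributing to the rank
        for j in range(X.shape[1] - 1, 0, -1):
            sub = np.delete(arr, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                dropped.append(str(X.columns[j]))
                X = X.drop(columns=X.columns[j])
                break
        else:  # pragma: no cover - cannot reduce further
            break
    return X, dropped


def fit_lmm(response, fixed: pd.DataFrame, groups) -> MixedModelFit:
    """ML fit of ``rank(response) ~ fixed + (1 | group)``.

    ``fixed`` holds the fixed-effect terms (no intercept column; one is
    added).  Requires at least 2 distinct groups unless falling back.
    """
    y = np.asarray(response, dtype=float)
    groups = np.asarray(groups)
    if len(y) != len(fixed) or len(y) != len(groups):
        raise ValueError("response, fixed terms and groups must align")
    X = fixed.copy()
    X.insert(0, "Intercept", 1.0)
    X, dropped = _drop_collinear(X)
    terms = "+".join(c for c in X.columns if c != "Intercept") or "1"
    formula = f"rank(y) ~ {terms} + (1|subject)"
    n_groups = len(np.unique(groups))

    def _ols(singular: bool = False) -> MixedModelFit:
        res = sm.OLS(y, X.to_numpy()).fit()
        return MixedModelFit(formula=formula + " [ols fallback]",
                             llf=float(res.llf), n_fixed=X.shape[1],
                             n_obs=len(y), converged=True, singular=singular,
                             fallback_ols=True,
                             params=pd.Series(res.params, index=X.columns),
                             re_variance=0.0, dropped_terms=dropped)

    if n_groups == len(y) or n_groups < 2:
        # one sample per subject (or a single subject): the random
        # intercept is unidentifiable -> documented OLS fallback
        return _ols()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        try:
            res = MixedLM(y, X.to_numpy(), groups=groups).fit(reml=False)
        except (np.linalg.LinAlgError, ValueError):
            return _ols(singular=True)
    re_var = float(np.asarray(res.cov_re)[0, 0])
    resid_var = float(res.scale)
    singular = re_var <= _SINGULAR_TOL * max(resid_var, 1e-12)
    # OLS is the sigma_u^2 = 0 profile of the same likelihood: if it
    # matches or beats the optimizer's solution, the ML optimum is the
    # zero-variance boundary and the documented fallback engages.
    ols_llf = float(sm.OLS(y, X.to_numpy()).fit().llf)
    if singular or ols_llf >= float(res.llf) - 1e-8:
        return _ols(singular=True)
    converged = bool(getattr(res, "converged", True)) and np.isfinite(res.llf)
    return MixedModelFit(formula=formula, llf=float(res.llf),
                         n_fixed=X.shape[1], n_obs=len(y),
                         converged=converged, singular=False,
                         fallback_ols=False,
                         params=pd.Series(res.fe_params, index=X.columns),
                         re_variance=re_var, dropped_terms=dropped)


@dataclass
class LrtResult:
    statistic: float
    df: int
    p: float
    p_adj: float = float("nan")
    testable: bool = True


def lrt(full: MixedModelFit, reduced: MixedModelFit) -> LrtResult:
    """Likelihood-ratio test between nested fixed-effect structures.

    The statistic 2*(ll_full - ll_reduced) is clamped at zero (optimizer
    noise can leave it fractionally negative) and referred to a
    chi-square with df equal to the number of added fixed-effect
    columns.  Fits over different observations or with a non-converged
    member yield an untestable result rather than a p-value.
    """
    if full.n_obs != reduced.n_obs:
        raise ValueError("nested fits must share the same observations")
    df = full.n_fixed - reduced.n_fixed
    if df < 1:
        raise ValueError("full model must add at least one fixed effect")
    if not (full.converged and reduced.converged):
        return LrtResult(float("nan"), df, float("nan"), testable=False)
    stat = max(0.0, 2.0 * (full.llf - reduced.llf))
    return LrtResult(stat, df, float(chi2.sf(stat, df)))


def classify_two_tests(p1_adj: float, p2_adj: float,
                       alpha: float = 0.05) -> str:
    """Verdict for one (feature, label, candidate) triple.

    Test 1 asks whether the candidate explains variation beyond the
    disease label; Test 2 asks the converse.  A significant Test 2
    (alone or together with Test 1) means the label keeps independent
    explanatory power -> the association ``passes`` the candidate.  Only
    Test 1 significant means the label association is statistically
    reducible to the candidate -> ``confounded``.  Neither significant
    leaves the data unable to separate the two -> ``ambiguous``.
    """
    if np.isnan(p1_adj) or np.isnan(p2_adj):
        return "untestable"
    if p2_adj <= alpha:
        return "passes"
    if p1_adj <= alpha:
        return "confounded"
    return "ambiguous"
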