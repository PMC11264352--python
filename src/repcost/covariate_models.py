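"""DEE covariate layer: all-subsets AICc over linear models, covariate-
adjusted year means with Tukey pairwise contrasts, residual-assumption
gating, and Poisson/binomial GLMs for productivity and apparent survival.

The maximal model is ``DEE ~ Year * BroodSize * BroodAge * AdultAge`` with
two-way interactions only; candidate models are all hierarchical subsets
(an interaction enters only when both mains are present).  Model averaging
is deliberately not performed; instead the set of models within 2 dAICc of
the best is returned for sensitivity re-analysis.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import patsy
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.diagnostic import het_breuschpagan

from .multistate_cmr import aicc

__all__ = [
    "MAINS",
    "LmFit",
    "AdjustedMeans",
    "enumerate_hierarchical_models",
    "all_subsets_lm",
    "adjusted_year_means",
    "residual_gate",
    "glm_poisson_productivity",
    "glm_binomial_outcome",
]

MAINS = ("C(year)", "brood_size", "brood_age_d", "adult_age_y")


def enumerate_hierarchical_models(mains: Sequence[str] = MAINS,
                                  ) -> list[tuple[str, ...]]:
    """All hierarchical models nested in the maximal two-way-interaction
    model: every subset of mains, crossed with every subset of the two-way
    interactions among the chosen mains."""
    models: list[tuple[str, ...]] = []
    for r in range(len(mains) + 1):
        for main_set in itertools.combinations(mains, r):
            pairs = list(itertools.combinations(main_set, 2))
            for k in range(len(pairs) + 1):
                for inter_set in itertools.combinations(pairs, k):
                    terms = tuple(main_set) + tuple(
                        f"{a}:{b}" for a, b in inter_set)
                    models.append(terms)
    return models


@dataclass
class LmFit:
    terms: tuple[str, ...]
    formula: str
    result: object                    # statsmodels RegressionResults
    logL: float
    K: int
    AICc: float
    normality_p: float
    heteroscedasticity_p: float
    response_transformed: bool = False

    @property
    def delta(self) -> float:         # filled by all_subsets_lm
        return getattr(self, "_delta", np.nan)


def _fit_ols(data: pd.DataFrame, response: str,
             terms: Sequence[str]) -> LmFit | None:
    rhs = " + ".join(terms) if terms else "1"
    formula = f"{response} ~ {rhs}"
    res = smf.ols(formula, data=data).fit()
    if np.linalg.matrix_rank(res.model.exog) < res.model.exog.shape[1]:
        warnings.warn(f"rank-deficient design skipped: {formula}")
        return None
    n = int(res.nobs)
    K = len(res.params) + 1           # + residual variance
    try:
        crit = aicc(res.llf, K, n)
    except ValueError:
        return None
    resid = res.resid
    norm_p = float(stats.shapiro(resid).pvalue) if 3 <= len(resid) <= 5000 \
        else np.nan
    try:
        bp_p = float(het_breuschpagan(resid, res.model.exog)[1])
    except (ValueError, np.linalg.LinAlgError):
        bp_p = np.nan
    return LmFit(tuple(terms), formula, res, float(res.llf), K, crit,
                 norm_p, bp_p)


def all_subsets_lm(data: pd.DataFrame, response: str = "dee_kj_day",
                   mains: Sequence[str] = MAINS,
                   ) -> tuple[pd.DataFrame, list[LmFit]]:
    """Fit every hierarchical submodel, rank by AICc, and return the full
    ranked table plus the retained set (dAICc <= 2)."""
    fits: list[LmFit] = []
    for terms in enumerate_hierarchical_models(mains):
        fit = _fit_ols(data, response, terms)
        if fit is not None:
            fits.append(fit)
    if not fits:
        raise ValueError("no candidate model could be fitted")
    fits.sort(key=lambda f: f.AICc)
    best = fits[0].AICc
    for f in fits:
        f._delta = f.AICc - best
    table = pd.DataFrame({
        "model": [" + ".join(f.terms) if f.terms else "(intercept)"
                  for f in fits],
        "K": [f.K for f in fits],
        "logL": [f.logL for f in fits],
        "AICc": [f.AICc for f in fits],
        "dAICc": [f._delta for f in fits],
    })
    retained = [f for f in fits if f._delta <= 2.0]
    return table, retained


@dataclass
class AdjustedMeans:
    years: list[int]
    means: np.ndarray
    ses: np.ndarray
    contrasts: pd.DataFrame           # year_a, year_b, diff, se, t, p_raw, p_tukey

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "adjusted_mean": self.means,
                             "se": self.ses})


def adjusted_year_means(fit: LmFit, data: pd.DataFrame,
                        year_col: str = "year") -> AdjustedMeans:
    """Per-year predicted response at covariate sample means, with Tukey
    (studentized-range) adjusted pairwise contrasts.

    With no continuous covariate in the model the adjusted means equal the
    raw year means.
    """
    if not any("year" in t for t in fit.terms):
        raise ValueError("fitted model does not contain a year effect")
    res = fit.result
    years = sorted(data[year_col].unique())
    ref = {}
    for col in data.columns:
        if col == year_col:
            continue
        if pd.api.types.is_numeric_dtype(data[col]):
            ref[col] = data[col].mean()
    new = pd.DataFrame([{year_col: y, **ref} for y in years])
    design_info = res.model.data.design_info
    X = np.asarray(patsy.build_design_matrices([design_info], new)[0])
    beta = res.params.to_numpy()
    cov = res.cov_params().to_numpy()
    means = X @ beta
    ses = np.sqrt(np.einsum("ij,jk,ik->i", X, cov, X))
    k = len(years)
    df_resid = res.df_resid
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        L = X[i] - X[j]
        diff = float(L @ beta)
        se = float(np.sqrt(L @ cov @ L))
        t = diff / se if se > 0 else np.inf
        p_raw = float(2 * stats.t.sf(abs(t), df_resid))
        p_tukey = float(stats.studentized_range.sf(
            abs(t) * np.sqrt(2.0), k, df_resid))
        rows.append({"year_a": years[i], "year_b": years[j], "diff": diff,
                     "se": se, "t": t, "p_raw": p_raw,
                     "p_tukey": min(1.0, p_tukey)})
    return AdjustedMeans(years, means, ses, pd.DataFrame(rows))


def residual_gate(fit: LmFit, data: pd.DataFrame,
                  alpha: float = 0.05) -> LmFit:
    """Re-fit on the log response when residual assumptions fail.

    Shapiro-Wilk (normality) and Breusch-Pagan (homoscedasticity) at
    ``alpha``; if either rejects, the response is log-transformed and the
    diagnostics re-run.  The returned fit carries the transform flag; a
    still-violating transformed fit is returned flagged, not raised.
    """
    ok = ((np.isnan(fit.normality_p) or fit.normality_p >= alpha)
          and (np.isnan(fit.heteroscedasticity_p)
               or fit.heteroscedasticity_p >= alpha))
    if ok:
        return fit
    response = fit.formula.split("~")[0].strip()
    log_col = f"_log_{response}"
    data2 = data.copy()
    data2[log_col] = np.log(data2[response])
    refit = _fit_ols(data2, log_col, fit.terms)
    if refit is None:
        return fit
    refit.response_transformed = True
    return refit


# ---------------------------------------------------------------------------
# GLMs

def _lr_row(full, reduced, term: str) -> dict:
    lr = 2.0 * (full.llf - reduced.llf)
    df = int(full.df_model - reduced.df_model)
    return {"term": term, "lr_chi2": float(max(lr, 0.0)), "df": df,
            "p": float(stats.chi2.sf(max(lr, 0.0), df)) if df > 0 else np.nan}


def glm_poisson_productivity(data: pd.DataFrame,
                             response: str = "fledged",
                             dee_col: str = "dee_kj_day",
                             year_col: str = "year") -> pd.DataFrame:
    """Analysis-of-deviance table (likelihood-ratio tests) for breeding
    productivity ~ DEE + year with a DEE x year interaction.

    Counts must be nonnegative integers.  Rows: dee, year (each tested by
    dropping from the additive model) and dee:year (tested against the
    additive model).
    """
    y = data[response]
    if not np.allclose(y, np.round(y)) or (y < 0).any():
        raise ValueError("response must be nonnegative integer counts")
    fam = sm.families.Poisson()
    f_add = f"{response} ~ {dee_col} + C({year_col})"
    f_int = f"{response} ~ {dee_col} * C({year_col})"
    add = smf.glm(f_add, data=data, family=fam).fit()
    full = smf.glm(f_int, data=data, family=fam).fit()
    no_dee = smf.glm(f"{response} ~ C({year_col})", data=data,
                     family=fam).fit()
    no_year = smf.glm(f"{response} ~ {dee_col}", data=data, family=fam).fit()
    rows = [
        _lr_row(add, no_dee, dee_col),
        _lr_row(add, no_year, f"C({year_col})"),
        _lr_row(full, add, f"{dee_col}:C({year_col})"),
    ]
    return pd.DataFrame(rows)


def glm_binomial_outcome(data: pd.DataFrame, response: str,
                         dee_col: str = "dee_kj_day",
                         year_col: str | None = None,
                         ) -> tuple[pd.DataFrame, bool]:
    """Logit-link binomial GLM with likelihood-ratio term tests; used for
    apparent survival and next-year breeding success.

    Returns (table, separated).  Complete separation is flagged and the
    model re-fit with a small ridge penalty; LR statistics then use the
    penalized estimates and should be read as approximate.
    """
    y = data[response]
    if not set(np.unique(y)).issubset({0, 1}):
        raise ValueError("response must be binary 0/1")
    fam = sm.families.Binomial()
    terms = [dee_col] + ([f"C({year_col})"] if year_col else [])
    f_full = f"{response} ~ " + " + ".join(terms)
    separated = False

    def fit(formula):
        nonlocal separated
        model = smf.glm(formula, data=data, family=fam)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(maxiter=200)
        if (np.abs(res.params) > 12).any() or not np.isfinite(res.llf):
            separated = True
            reg = model.fit_regularized(alpha=1e-3, L1_wt=0.0)
            params = np.asarray(reg.params)
            llf = model.loglike(params)

            class _Pen:
                pass
            pen = _Pen()
            pen.llf = float(llf)
            pen.df_model = model.exog.shape[1] - 1
            pen.params = params
            return pen
        return res

    full = fit(f_full)
    rows = []
    reduced_terms = [t for t in terms if t != dee_col]
    f_red = f"{response} ~ " + (" + ".join(reduced_terms) or "1")
    rows.append(_lr_row(full, fit(f_red), dee_col))
    if year_col:
        f_red2 = f"{response} ~ {dee_col}"
        rows.append(_lr_row(full, fit(f_red2), f"C({year_col})"))
    return pd.DataFrame(rows), separated
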