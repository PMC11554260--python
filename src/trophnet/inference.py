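"""The mixed-model analysis stack.

:class:`MixedModel` is the estimator around which everything is organised:
it builds the design for a :class:`~trophnet.design.ModelSpec`, fits a
Gaussian LMM (profiled ML/REML) or a gamma log-link GLMM (Laplace), and
exposes the fitted coefficients, variance components, AIC, type II Wald
analysis of deviance, variance-partition R-squared, and Tukey-adjusted
estimated-marginal-mean contrasts.

Module functions (``fit_lmm``, ``fit_glmm_gamma_log``, ``select_model_aic``,
``wald_type2_anova``, ``r2_components``, ``emm_contrasts``) are thin wrappers
over the estimator.

Conventions:

* Model selection compares maximum-likelihood fits (fixed-effect structures
  differ); the selected model is refit under REML for reported coefficients.
* Type II Wald tests respect marginality: each term is tested after all
  terms of equal or lower order, ignoring its own higher-order relatives.
* R-squared follows the variance-partition decomposition for mixed models;
  for the gamma log link the observation-level variance on the latent scale
  is ``trigamma(shape)``.
* Contrast denominator d.f. are Satterthwaite for Gaussian fits and
  asymptotic (normal) for gamma fits; the Tukey adjustment uses the
  studentized range over the compare-factor family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
from scipy.special import polygamma
from sklearn.base import BaseEstimator

from .design import (
    AVAILABILITY_LEVELS,
    DEFAULT_FRAME_RATE_BIN_WIDTH,
    FOOD_TYPE_LEVELS,
    Design,
    ModelSpec,
    build_design,
    candidate_specs,
    random_effect_codes,
)
from .errors import (
    MissingColumnError,
    MissingFactorError,
    NonPositiveResponseError,
    SingularCovarianceError,
)
from .glmm import GLMMResult, fit_glmm_gamma_core
from .lmm import LMMResult, fit_lmm_core

FACTOR_LEVELS = {"food_type": FOOD_TYPE_LEVELS, "food_availability": AVAILABILITY_LEVELS}


class MixedModel(BaseEstimator):
    """Mixed model for one response of the behavioural analysis.

    Parameters
    ----------
    spec : ModelSpec
        Response, interaction structure, covariates, random factors, family.
    criterion : {"REML", "ML"}
        Estimation criterion for Gaussian fits (gamma fits are Laplace ML).
    zero_handling : {"shift", "drop", "error"}
        Treatment of non-positive responses under the gamma family:
        add ``zero_shift`` to the response, drop the rows, or raise.
    reference_levels : mapping, optional
        Reference level per factor (default: protein / limited).
    frame_rate_bin_width : float
        Bin width (images/s) turning the continuous mean frame rate into a
        random grouping factor.
    """

    def __init__(self, spec: ModelSpec | None = None, criterion: str = "REML",
                 zero_handling: str = "shift", zero_shift: float = 1.0,
                 reference_levels: Mapping[str, str] | None = None,
                 frame_rate_bin_width: float = DEFAULT_FRAME_RATE_BIN_WIDTH):
        self.spec = spec
        self.criterion = criterion
        self.zero_handling = zero_handling
        self.zero_shift = zero_shift
        self.reference_levels = reference_levels
        self.frame_rate_bin_width = frame_rate_bin_width

    # --- fitting ------------------------------------------------------------

    def fit(self, data: pd.DataFrame, y=None):
        spec = self.spec
        if spec is None:
            raise ValueError("MixedModel requires a ModelSpec")
        if spec.response not in data.columns:
            raise MissingColumnError(f"response column {spec.response!r} not in data")
        data = data.reset_index(drop=True)
        yv = data[spec.response].to_numpy(float)
        if spec.family == "gamma":
            bad = yv <= 0
            if bad.any():
                if self.zero_handling == "error":
                    raise NonPositiveResponseError(
                        f"{int(bad.sum())} non-positive response values"
                    )
                if self.zero_handling == "drop":
                    data = data.loc[~bad].reset_index(drop=True)
                    yv = yv[~bad]
                elif self.zero_handling == "shift":
                    yv = yv + self.zero_shift
                else:
                    raise ValueError(f"unknown zero_handling {self.zero_handling!r}")
        design = build_design(spec, data, reference_levels=self.reference_levels)
        codes, sizes, fnames = random_effect_codes(
            data, spec.random_effects, frame_rate_bin_width=self.frame_rate_bin_width
        )
        if spec.family == "gamma":
            result = fit_glmm_gamma_core(
                design.X, yv, codes, sizes,
                coef_names=design.column_names, factor_names=fnames,
            )
        else:
            result = fit_lmm_core(
                design.X, yv, codes, sizes, method=self.criterion,
                coef_names=design.column_names, factor_names=fnames,
            )
        self.design_ = design
        self.result_ = result
        self.coef_ = pd.Series(result.coef, index=design.column_names)
        self.se_ = pd.Series(result.se, index=design.column_names)
        self.vcov_ = pd.DataFrame(result.vcov, index=design.column_names,
                                  columns=design.column_names)
        self.random_var_ = dict(result.re_var)
        self.resid_var_ = getattr(result, "sigma2", None)
        self.shape_ = getattr(result, "shape", None)
        self.loglik_ = result.loglik
        self.aic_ = result.aic
        self.k_params_ = result.k_params
        self.converged_ = result.converged
        self.n_obs_ = result.n
        r2m, r2c, re_pct = _r2_from(result, design)
        self.r2_marginal_ = r2m
        self.r2_conditional_ = r2c
        self.random_explained_pct_ = re_pct
        return self

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        """Population-level prediction (response scale for gamma)."""
        design = build_design(self.spec, data, reference_levels=self.reference_levels)
        return self.result_.predict(design.X)

    # --- inference ----------------------------------------------------------

    def anova(self) -> pd.DataFrame:
        """Type II Wald chi-square analysis of deviance."""
        return wald_type2_anova(self)

    def r2(self) -> tuple[float, float, float]:
        return self.r2_marginal_, self.r2_conditional_, self.random_explained_pct_

    def conf_int(self, level: float = 0.95, use_satterthwaite: bool = True) -> pd.DataFrame:
        """Coefficient confidence intervals (Satterthwaite t for Gaussian fits)."""
        alpha = 1.0 - level
        lo, hi = [], []
        for j, name in enumerate(self.coef_.index):
            c = np.zeros(len(self.coef_)); c[j] = 1.0
            df = (self.result_.satterthwaite_df(c)
                  if use_satterthwaite else float("inf"))
            q = st.t.ppf(1 - alpha / 2, df) if np.isfinite(df) else st.norm.ppf(1 - alpha / 2)
            lo.append(self.coef_.iloc[j] - q * self.se_.iloc[j])
            hi.append(self.coef_.iloc[j] + q * self.se_.iloc[j])
        return pd.DataFrame({"lower": lo, "upper": hi}, index=self.coef_.index)

    def emmeans(self, factors: Sequence[str] = ("food_type", "food_availability"),
                ) -> pd.DataFrame:
        """Estimated marginal means over the factor grid, covariates at means."""
        rows = []
        grid_gs = self._grid_group_size()
        for levels in _level_grid(factors):
            x = self.design_.make_row(group_size=grid_gs, **levels)
            est = float(x @ self.result_.coef)
            se = float(np.sqrt(x @ self.result_.vcov @ x))
            rows.append({**levels, "emmean": est, "se": se})
        return pd.DataFrame(rows)

    def contrasts(self, within: str = "food_type", compare: str = "food_availability",
                  adjust: str = "tukey") -> pd.DataFrame:
        return emm_contrasts(self, within=within, compare=compare, adjust=adjust)

    def _grid_group_size(self) -> float:
        # covariates held at their sample means on the reference grid
        return float(np.mean(self.design_.X[:, self.design_.column_names.index("group_size")])
                     + (self.design_.group_size_center if self.spec.poly_group_size else 0.0))


# --- module-level operations -------------------------------------------------


def fit_lmm(spec: ModelSpec, data: pd.DataFrame, criterion: str = "REML",
            **kwargs) -> MixedModel:
    """Fit a Gaussian linear mixed model for ``spec``."""
    if spec.family != "gaussian":
        raise ValueError("fit_lmm requires a gaussian-family spec")
    return MixedModel(spec=spec, criterion=criterion, **kwargs).fit(data)


def fit_glmm_gamma_log(spec: ModelSpec, data: pd.DataFrame,
                       zero_handling: str = "shift", **kwargs) -> MixedModel:
    """Fit the gamma log-link GLMM for ``spec`` (Laplace approximation)."""
    if spec.family != "gamma":
        raise ValueError("fit_glmm_gamma_log requires a gamma-family spec")
    return MixedModel(spec=spec, zero_handling=zero_handling, **kwargs).fit(data)


def select_model_aic(specs: Sequence[ModelSpec], data: pd.DataFrame,
                     **kwargs) -> tuple[ModelSpec, pd.DataFrame]:
    """AIC model selection over candidate fixed-effect structures.

    Gaussian candidates are fit under ML (their fixed effects differ, so
    REML likelihoods would not be comparable).  Non-converged candidates are
    excluded with a warning.  Ties break toward fewer parameters, then toward
    the earlier candidate, so the ordering is deterministic.
    """
    rows = []
    fits = []
    for i, spec in enumerate(specs):
        kw = dict(kwargs)
        if spec.family == "gaussian":
            kw["criterion"] = "ML"
        try:
            m = MixedModel(spec=spec, **kw).fit(data)
        except Exception as exc:  # rank deficiency etc.
            warnings.warn(f"candidate {spec.label()} failed: {exc}", stacklevel=2)
            continue
        if not m.converged_:
            warnings.warn(f"candidate {spec.label()} did not converge; excluded",
                          stacklevel=2)
            continue
        rows.append({
            "model": spec.label(), "interaction": spec.interaction,
            "poly_group_size": spec.poly_group_size,
            "k_params": m.k_params_, "loglik": m.loglik_, "aic": m.aic_,
            "order": i,
        })
        fits.append((spec, m))
    if not rows:
        raise SingularCovarianceError("no candidate converged")
    table = pd.DataFrame(rows).sort_values(
        ["aic", "k_params", "order"], kind="mergesort").reset_index(drop=True)
    table["delta_aic"] = table["aic"] - table["aic"].iloc[0]
    best_label = table["model"].iloc[0]
    best_spec = next(s for s, _ in fits if s.label() == best_label)
    return best_spec, table.drop(columns="order")


def wald_type2_anova(model: MixedModel) -> pd.DataFrame:
    """Type II Wald chi-square tests for every fixed term (intercept excluded).

    For a term T with higher-order relatives R (terms whose variable sets
    strictly contain T's), the hypothesis matrix maps the full-model
    coefficients onto T's coefficients in the reduced design without R's
    columns, ``L = [pinv(X_-R) X]_T``; the statistic is
    ``(L b)' (L V L')^-1 (L b)`` with d.f. = rank(L).  Terms without
    relatives reduce to the familiar block Wald test.
    """
    design = model.design_
    beta = model.result_.coef
    V = model.result_.vcov
    X = design.X
    rows = []
    for term in design.terms:
        if term.name == "Intercept":
            continue
        rel_cols = sorted({c for r in design.relatives(term) for c in r.columns})
        if rel_cols:
            keep = [j for j in range(X.shape[1]) if j not in rel_cols]
            Xr = X[:, keep]
            A = np.linalg.pinv(Xr) @ X          # E[beta_reduced] = A beta_full
            pos = [keep.index(c) for c in term.columns]
            L = A[pos, :]
        else:
            L = np.zeros((len(term.columns), X.shape[1]))
            for r, c in enumerate(term.columns):
                L[r, c] = 1.0
        lb = L @ beta
        lvl = L @ V @ L.T
        try:
            stat = float(lb @ np.linalg.solve(lvl, lb))
        except np.linalg.LinAlgError as exc:
            raise SingularCovarianceError(str(exc)) from exc
        df = int(np.linalg.matrix_rank(L))
        rows.append({
            "term": term.name, "chisq": stat, "df": df,
            "p_value": float(st.chi2.sf(stat, df)),
        })
    return pd.DataFrame(rows).set_index("term")


def _r2_from(result: LMMResult | GLMMResult, design: Design) -> tuple[float, float, float]:
    var_f = float(np.var(design.X @ result.coef))
    var_re = float(sum(result.re_var.values()))
    if isinstance(result, GLMMResult):
        var_eps = float(polygamma(1, result.shape))  # latent-scale obs variance
    else:
        var_eps = result.sigma2
    total = var_f + var_re + var_eps
    if total <= 0:
        return 0.0, 0.0, 0.0
    r2m = var_f / total
    r2c = (var_f + var_re) / total
    return r2m, r2c, 100.0 * (r2c - r2m)


def r2_components(model: MixedModel) -> tuple[float, float, float]:
    """(marginal R2, conditional R2, random-effects share in percent)."""
    return _r2_from(model.result_, model.design_)


def _level_grid(factors: Sequence[str]):
    for f in factors:
        if f not in FACTOR_LEVELS:
            raise MissingFactorError(f"unknown factor {f!r}")
    grids = [[(f, l) for l in FACTOR_LEVELS[f]] for f in factors]

    def rec(i, acc):
        if i == len(grids):
            yield dict(acc)
            return
        for item in grids[i]:
            yield from rec(i + 1, acc + [item])

    yield from rec(0, [])


def emm_contrasts(model: MixedModel, within: str = "food_type",
                  compare: str = "food_availability",
                  adjust: str = "tukey") -> pd.DataFrame:
    """Pairwise compare-factor contrasts of EMMs within each within-factor level.

    Covariates sit at their sample means on the reference grid.  Gaussian
    fits use Satterthwaite denominator d.f.; gamma fits the normal reference.
    ``adjust="tukey"`` applies the studentized-range adjustment over the
    number of compare-factor levels (for two levels it coincides with the
    unadjusted two-sided test).
    """
    for f in (within, compare):
        if f not in FACTOR_LEVELS:
            raise MissingFactorError(f"unknown factor {f!r}")
    if within == compare:
        raise MissingFactorError("within and compare factors must differ")
    gs = model._grid_group_size()
    k = len(FACTOR_LEVELS[compare])
    rows = []
    for w_level in FACTOR_LEVELS[within]:
        for l2, l1 in combinations(FACTOR_LEVELS[compare][::-1], 2):
            # report later level minus earlier level (e.g. unlimited - limited)
            x1 = model.design_.make_row(group_size=gs, **{within: w_level, compare: l2})
            x0 = model.design_.make_row(group_size=gs, **{within: w_level, compare: l1})
            c = x1 - x0
            est = float(c @ model.result_.coef)
            se = float(np.sqrt(c @ model.result_.vcov @ c))
            df = model.result_.satterthwaite_df(c)
            t = est / se if se > 0 else np.nan
            if adjust == "tukey" and k > 2:
                dfq = df if np.isfinite(df) else 1e6
                p = float(st.studentized_range.sf(abs(t) * np.sqrt(2.0), k, dfq))
            elif np.isfinite(df):
                p = float(2 * st.t.sf(abs(t), df))
            else:
                p = float(2 * st.norm.sf(abs(t)))
            rows.append({
                "contrast": f"{l2} - {l1}", within: w_level,
                "estimate": est, "se": se, "df": df, "t_ratio": t, "p_value": p,
            })
    return pd.DataFrame(rows)
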