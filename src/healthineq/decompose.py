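"""Wagstaff-type decomposition of a concentration index into factor contributions.

Given a linear model for a binary outcome,

.. math:: y_i = \\alpha + \\sum_k \\beta_k x_{ki} + \\varepsilon_i,

the concentration index of :math:`y` decomposes exactly as

.. math:: C = \\sum_k \\Big(\\frac{\\beta_k \\bar x_k}{\\mu}\\Big) C_k
             + \\frac{GC_\\varepsilon}{\\mu},

where :math:`C_k` is the concentration index of regressor :math:`x_k`
computed with the *same* fractional ranks and weights as the outcome's
index, :math:`\\beta_k \\bar x_k / \\mu` is the elasticity of the outcome
with respect to that regressor, and :math:`GC_\\varepsilon = 2\\,
\\mathrm{cov}_w(\\varepsilon, R)` is the generalized (unscaled)
concentration index of the residuals.  With a weighted least-squares fit
(linear probability model, ``lpm``) the identity holds to machine precision;
with a weighted logit the β's are replaced by finite-difference average
marginal effects (``logit_ame``) and the residual is defined as
total − explained.

Regressors are the dummy-coded socio-demographic covariates with reference
categories rural residence, age 15-24, first birth order, no education,
"Others" caste and no mass-media exposure, so the rows line up with the
standard decomposition-table layout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .ranking import concentration_index, weighted_cov, weighted_mean
from .survey import DataError, DomainError, SurveyTable

logger = logging.getLogger("healthineq.decompose")

__all__ = [
    "EstimationError",
    "DesignMatrix",
    "CoefficientSet",
    "DecompositionRow",
    "DecompositionResult",
    "DEFAULT_REFERENCE_LEVELS",
    "build_design",
    "fit_lpm",
    "fit_logit_ame",
    "generalized_ci",
    "wagstaff_decompose",
    "percent_contributions",
    "recover_planted_structure",
]


class EstimationError(RuntimeError):
    """Model estimation failed (rank deficiency, non-convergence)."""


#: omitted category per covariate
DEFAULT_REFERENCE_LEVELS: dict[str, str] = {
    "residence": "rural",
    "age_group": "15-24",
    "birth_order": "1",
    "education": "none",
    "caste": "Others",
    "media_exposure": "no",
}

#: (covariate, level) pairs in decomposition-table row order, with dummy names
_LEVEL_ORDER: dict[str, tuple[str, ...]] = {
    "residence": ("urban", "rural"),
    "age_group": ("15-24", "25-34", "35-49"),
    "birth_order": ("1", "2", "3+"),
    "education": ("none", "primary", "secondary", "higher"),
    "caste": ("SC", "ST", "OBC", "Others"),
    "media_exposure": ("no", "yes"),
}

_SLUGS = {
    ("residence", "urban"): "urban",
    ("residence", "rural"): "rural",
    ("age_group", "15-24"): "age_15_24",
    ("age_group", "25-34"): "age_25_34",
    ("age_group", "35-49"): "age_35_49",
    ("birth_order", "1"): "birth_order_1",
    ("birth_order", "2"): "birth_order_2",
    ("birth_order", "3+"): "birth_order_3plus",
    ("education", "none"): "edu_none",
    ("education", "primary"): "edu_primary",
    ("education", "secondary"): "edu_secondary",
    ("education", "higher"): "edu_higher",
    ("caste", "SC"): "caste_sc",
    ("caste", "ST"): "caste_st",
    ("caste", "OBC"): "caste_obc",
    ("caste", "Others"): "caste_others",
    ("media_exposure", "no"): "media_no",
    ("media_exposure", "yes"): "media_yes",
}


@dataclass
class DesignMatrix:
    """Dummy-coded regressors with their weighted means.

    ``X`` holds one 0/1 column per non-reference covariate level (no
    intercept column); ``variable_of`` maps each dummy back to its source
    covariate, which the planted-structure diagnostics use to pool
    contributions by variable.
    """

    X: pd.DataFrame
    reference_levels: dict[str, str]
    means: pd.Series
    variable_of: dict[str, str] = field(default_factory=dict)


@dataclass
class CoefficientSet:
    """Fitted outcome model: coefficients (or AMEs), fitted values, residuals."""

    model_kind: str
    intercept: float | None
    beta: dict[str, float]
    fitted: np.ndarray
    residuals: np.ndarray


@dataclass
class DecompositionRow:
    regressor: str
    beta: float
    mean: float
    ck: float
    elasticity: float
    contribution: float


@dataclass
class DecompositionResult:
    rows: list[DecompositionRow]
    explained: float
    residual: float
    total: float
    model_kind: str
    mu: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows])


def build_design(table: SurveyTable,
                 overrides: dict[str, str] | None = None) -> DesignMatrix:
    """Dummy-code the covariates against their reference categories.

    One 0/1 column per non-reference level of each covariate (12 dummies
    under the defaults); weighted means are recorded for the elasticity
    terms.  ``overrides`` swaps the omitted level of selected covariates.
    """
    refs = dict(DEFAULT_REFERENCE_LEVELS)
    if overrides:
        for var, level in overrides.items():
            if var not in _LEVEL_ORDER:
                raise DomainError(f"unknown covariate {var!r}")
            if level not in _LEVEL_ORDER[var]:
                raise DomainError(f"{level!r} is not a level of {var!r}")
            refs[var] = level

    df = table.data
    w = df["weight"].to_numpy(float)
    cols: dict[str, np.ndarray] = {}
    variable_of: dict[str, str] = {}
    for var, levels in _LEVEL_ORDER.items():
        observed = set(df[var].astype(str))
        if not observed <= set(levels):
            raise DomainError(
                f"{var} contains level(s) outside its domain: {sorted(observed - set(levels))}")
        for level in levels:
            if level == refs[var]:
                continue
            name = _SLUGS[(var, level)]
            cols[name] = (df[var].astype(str) == level).to_numpy().astype(float)
            variable_of[name] = var
    X = pd.DataFrame(cols, index=df.index)
    means = pd.Series({c: weighted_mean(X[c].to_numpy(), w) for c in X.columns})
    return DesignMatrix(X=X, reference_levels=refs, means=means, variable_of=variable_of)


def _prepare_X(design: DesignMatrix) -> pd.DataFrame:
    """Drop constant dummy columns (logged), keep the rest."""
    X = design.X
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if constant:
        logger.warning("dropping constant regressor column(s): %s", ", ".join(constant))
        X = X.drop(columns=constant)
    return X


def _check_rank(Xc: pd.DataFrame) -> None:
    mat = Xc.to_numpy(float)
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # name columns whose removal restores full column rank
        culprits = [c for c in Xc.columns if c != "const"
                    and np.linalg.matrix_rank(Xc.drop(columns=[c]).to_numpy(float))
                    == np.linalg.matrix_rank(mat)]
        raise EstimationError(f"design matrix is rank deficient; collinear column(s): "
                              f"{', '.join(culprits) or 'unidentified'}")


def fit_lpm(y, design: DesignMatrix, weights) -> CoefficientSet:
    """Weighted least-squares linear probability model.

    The weighted mean of the residuals is zero (the fit includes an
    intercept), which is what makes the decomposition identity exact.
    Coefficients are invariant to rescaling all weights by a constant.
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    X = _prepare_X(design)
    Xc = sm.add_constant(X, has_constant="add")
    _check_rank(Xc)
    res = sm.WLS(y, Xc, weights=w).fit()
    fitted = np.asarray(res.fittedvalues, dtype=float)
    params = res.params
    beta = {c: float(params[c]) for c in X.columns}
    return CoefficientSet(model_kind="lpm", intercept=float(params["const"]),
                          beta=beta, fitted=fitted, residuals=y - fitted)


def fit_logit_ame(y, design: DesignMatrix, weights,
                  maxiter: int = 100) -> CoefficientSet:
    """Weighted logit with finite-difference average marginal effects.

    For each dummy :math:`x_k` the AME is the weighted mean over records of
    :math:`\\hat p(x_k \\leftarrow 1) - \\hat p(x_k \\leftarrow 0)` with the
    other regressors held at their observed values — the discrete analogue of
    Δy/Δx.  On a saturated single-dummy design this reproduces the difference
    in weighted cell proportions.  Quasi-separation triggers a warning and a
    fall-back to the linear probability model; non-convergence raises.
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    X = _prepare_X(design)
    Xc = sm.add_constant(X, has_constant="add")
    _check_rank(Xc)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(y, Xc, family=sm.families.Binomial(), var_weights=w)
            res = model.fit(maxiter=maxiter)
        converged = bool(getattr(res, "converged", True))
        # IRLS converges silently under separation with exploding log-odds;
        # |linear predictor| > 20 means fitted probabilities within 2e-9 of 0/1
        separated = np.max(np.abs(np.asarray(Xc.to_numpy() @ res.params))) > 20.0
    except Exception as exc:  # perfect separation raises inside IRLS
        logger.warning("logit fit failed (%s); falling back to the linear probability model", exc)
        return fit_lpm(y, design, weights)
    if separated:
        logger.warning("quasi-separation detected in logit fit; "
                       "falling back to the linear probability model")
        return fit_lpm(y, design, weights)
    if not converged:
        raise EstimationError(f"logit did not converge within {maxiter} iterations")

    fitted = np.asarray(res.predict(Xc), dtype=float)
    wn = w / np.sum(w)
    beta: dict[str, float] = {}
    for c in X.columns:
        X1 = Xc.copy(); X1[c] = 1.0
        X0 = Xc.copy(); X0[c] = 0.0
        beta[c] = float(np.sum(wn * (np.asarray(res.predict(X1))
                                     - np.asarray(res.predict(X0)))))
    return CoefficientSet(model_kind="logit_ame", intercept=None, beta=beta,
                          fitted=fitted, residuals=y - fitted)


def generalized_ci(residuals, ranks, weights) -> float:
    """Generalized (unscaled) concentration index, 2·cov_w(ε, R)."""
    e = np.asarray(residuals, dtype=float)
    R = np.asarray(ranks, dtype=float)
    w = np.asarray(weights, dtype=float)
    if not (e.shape == R.shape == w.shape):
        raise DataError("residuals, ranks and weights must have equal length")
    return 2.0 * weighted_cov(e, R, w)


def wagstaff_decompose(y, design: DesignMatrix, weights, ranks,
                       model_kind: str = "lpm") -> DecompositionResult:
    """Decompose the outcome's concentration index into factor contributions.

    Each retained regressor contributes elasticity × its own concentration
    index, both computed with the shared ranks and weights; the explained
    part is the sum of contributions and the residual is GCε/μ for the
    linear probability model (exact additivity) or total − explained for
    the logit-AME variant.
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    R = np.asarray(ranks, dtype=float)
    if not (y.shape == w.shape == R.shape):
        raise DataError("y, weights and ranks must have equal length")
    mu = weighted_mean(y, w)
    if mu <= 0:
        raise DataError("decomposition undefined: weighted mean of outcome is not positive")

    if model_kind == "lpm":
        coefs = fit_lpm(y, design, w)
    elif model_kind == "logit_ame":
        coefs = fit_logit_ame(y, design, w)
    else:
        raise DomainError(f"unknown model kind {model_kind!r}")

    total = concentration_index(y, R, w).index
    rows: list[DecompositionRow] = []
    for name, bk in coefs.beta.items():
        xk = design.X[name].to_numpy(float)
        xbar = weighted_mean(xk, w)
        ck = concentration_index(xk, R, w).index if xbar > 0 else 0.0
        elasticity = bk * xbar / mu
        rows.append(DecompositionRow(regressor=name, beta=bk, mean=xbar, ck=ck,
                                     elasticity=elasticity,
                                     contribution=elasticity * ck))
    explained = float(sum(r.contribution for r in rows))
    if coefs.model_kind == "lpm":
        residual = generalized_ci(coefs.residuals, R, w) / mu
    else:
        residual = total - explained
    return DecompositionResult(rows=rows, explained=explained, residual=residual,
                               total=total, model_kind=coefs.model_kind, mu=mu)


def percent_contributions(result: DecompositionResult,
                          denominator: str = "total") -> dict[str, float]:
    """Per-regressor percentage contributions to the chosen denominator.

    ``denominator`` is the total concentration index (default) or the
    explained part only.  A zero denominator yields NaN with a warning.
    """
    if denominator not in ("total", "explained"):
        raise DomainError(f"denominator must be 'total' or 'explained', got {denominator!r}")
    denom = result.total if denominator == "total" else result.explained
    if denom == 0:
        logger.warning("percentage contributions undefined: %s CI is zero", denominator)
        return {r.regressor: float("nan") for r in result.rows}
    return {r.regressor: 100.0 * r.contribution / denom for r in result.rows}


def recover_planted_structure(scenario, seed: int, outcome: str = "full_anc",
                              model_kind: str = "lpm") -> dict:
    """Validation harness: decompose a synthetic table with known structure.

    Generates a population from ``scenario``, runs the full rank + model +
    decomposition chain on ``outcome``, and reports the total and explained
    indices together with the share of the explained part pooled by source
    covariate — on a scenario where a single covariate drives the outcome,
    that covariate's pooled share should dominate.
    """
    from .simulate import generate_population  # deferred: avoids import cycle
    from .ranking import ranks_for_table
    from .survey import derive_indicators

    table = derive_indicators(generate_population(scenario, seed))
    df = table.data
    w = df["weight"].to_numpy(float)
    ranks = ranks_for_table(table)
    design = build_design(table)
    result = wagstaff_decompose(df[outcome].to_numpy(float), design, w, ranks,
                                model_kind=model_kind)
    by_variable: dict[str, float] = {}
    for row in result.rows:
        var = design.variable_of.get(row.regressor, row.regressor)
        by_variable[var] = by_variable.get(var, 0.0) + row.contribution
    shares = {v: (c / result.explained if result.explained != 0 else float("nan"))
              for v, c in by_variable.items()}
    return {
        "outcome": outcome,
        "n": len(df),
        "mu": result.mu,
        "total": result.total,
        "explained": result.explained,
        "residual": result.residual,
        "contribution_by_variable": by_variable,
        "explained_share_by_variable": shares,
        "result": result,
    }
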