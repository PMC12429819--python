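"""Fixed multivariable logistic model of BCPR on exposure and confounders.

The model is ``bcpr ~ alert_issued + age + gender + witness_type + call_time +
arrest_location + first_rhythm`` with dummy coding against fixed reference
levels. The complete-case path, the design-matrix construction (including the
missingness-indicator extra terms) and the maximum-likelihood fit live here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import schema

#: Model terms in fixed order (intercept excluded).
MODEL_TERMS = (
    "alert_issued",
    "male",
    "age",
    "witness_family",
    "witness_healthcare",
    "witness_lay",
    "calltime_06_18",
    "calltime_19_23",
    "location_public",
    "rhythm_shockable",
    "rhythm_unknown",
)

#: Missingness-indicator terms, appended after MODEL_TERMS when present.
MXI_TERMS = ("age_missing", "witness_missing", "calltime_missing")

#: Reference level of each categorical variable (absorbed by the intercept).
REFERENCE_LEVELS = {
    "gender": "female",
    "witness_type": "not_witnessed",
    "arrest_location": "home",
    "call_time": "t00_05",
    "first_rhythm": "non_shockable",
}

#: term -> (variable, level) for the dummy-coded terms.
_DUMMY_TERMS = {
    "male": ("gender", "male"),
    "witness_family": ("witness_type", "family"),
    "witness_healthcare": ("witness_type", "healthcare"),
    "witness_lay": ("witness_type", "lay"),
    "calltime_06_18": ("call_time", "t06_18"),
    "calltime_19_23": ("call_time", "t19_23"),
    "location_public": ("arrest_location", "public"),
    "rhythm_shockable": ("first_rhythm", "shockable"),
    "rhythm_unknown": ("first_rhythm", "unknown"),
}

_MXI_LEVEL_TERMS = {
    "witness_missing": ("witness_type", schema.MISSING_LEVEL),
    "calltime_missing": ("call_time", schema.MISSING_LEVEL),
}

#: CI multiplier for 95% normal-approximation intervals.
Z_95 = 1.96

#: Absolute coefficient magnitude treated as evidence of separation when the
#: score has not vanished.
SEPARATION_BETA = 15.0


@dataclass(frozen=True)
class ModelSpec:
    """Term order and reference levels of the association model."""

    outcome: str = "bcpr"
    terms: tuple[str, ...] = MODEL_TERMS
    reference_levels: dict[str, str] = field(default_factory=lambda: dict(REFERENCE_LEVELS))


@dataclass
class FitResult:
    """Per-term estimates and fit metrics of one logistic fit.

    ``beta``/``se``/``ci_low``/``ci_high`` are keyed by term name plus
    ``"intercept"``. CIs are Wald: beta +- 1.96 * se.
    """

    terms: tuple[str, ...]
    beta: dict[str, float]
    se: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    loglik: float
    aic: float
    rmse: float
    n_used: int
    converged: bool

    def to_dict(self) -> dict:
        return {
            "terms": list(self.terms),
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "loglik": self.loglik,
            "aic": self.aic,
            "rmse": self.rmse,
            "n_used": self.n_used,
            "converged": self.converged,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        return cls(
            terms=tuple(d["terms"]),
            beta=dict(d["beta"]),
            se=dict(d["se"]),
            ci_low=dict(d["ci_low"]),
            ci_high=dict(d["ci_high"]),
            loglik=float(d["loglik"]),
            aic=float(d["aic"]),
            rmse=float(d["rmse"]),
            n_used=int(d["n_used"]),
            converged=bool(d["converged"]),
        )


def complete_case_filter(table: pd.DataFrame) -> pd.DataFrame:
    """Drop every row with at least one missing model variable.

    Row order is preserved. Raises ``ValueError`` if nothing survives.
    """
    model_cols = [c for c in schema.COLUMNS if c != "case_id"]
    keep = ~table[model_cols].isna().any(axis=1)
    out = table.loc[keep].copy()
    if out.empty:
        raise ValueError("complete-case filter removed every row")
    return out


def build_design(table: pd.DataFrame, spec: ModelSpec | None = None) -> pd.DataFrame:
    """Numeric design matrix (no intercept column) in fixed term order.

    Missingness-indicator extras are appended automatically when the table
    carries an ``age_missing`` column or a ``missing`` categorical level.
    Unseen categorical levels (other than the sanctioned ``missing`` level)
    raise ``ValueError``.
    """
    spec = spec or ModelSpec()
    cols: dict[str, np.ndarray] = {}
    cols["alert_issued"] = table["alert_issued"].to_numpy(dtype=float)
    cols["age"] = table["age"].to_numpy(dtype=float)
    for term, (var, level) in _DUMMY_TERMS.items():
        cols[term] = (table[var] == level).to_numpy(dtype=float)

    extra: list[str] = []
    if schema.AGE_MISSING_COLUMN in table.columns:
        cols["age_missing"] = table[schema.AGE_MISSING_COLUMN].to_numpy(dtype=float)
        extra.append("age_missing")
    for term, (var, level) in _MXI_LEVEL_TERMS.items():
        if (table[var] == level).any():
            cols[term] = (table[var] == level).to_numpy(dtype=float)
            extra.append(term)

    for var, domain in schema.DOMAINS.items():
        allowed = set(domain) | {schema.MISSING_LEVEL}
        vals = table[var]
        bad = ~(vals.isin(allowed) | vals.isna())
        if bad.any():
            raise ValueError(f"unseen level {vals[bad].iloc[0]!r} in {var!r}")

    order = [t for t in spec.terms] + [t for t in MXI_TERMS if t in extra]
    return pd.DataFrame({t: cols[t] for t in order}, index=table.index)


def fit_logistic(design: pd.DataFrame, outcome: np.ndarray | pd.Series) -> FitResult:
    """Maximum-likelihood logistic fit with Wald 95% CIs.

    Newton iterations, score tolerance 1e-8, at most 100 iterations. A fit
    showing diverging coefficients (|beta| > 15) with a non-vanishing score is
    flagged ``converged=False``; callers exclude such fits from summaries.
    """
    y = np.asarray(outcome, dtype=float)
    if design.isna().any().any():
        raise ValueError("design matrix contains missing values; impute or filter first")
    if y.min() == y.max():
        raise ValueError("outcome has a single class")
    X = sm.add_constant(design, has_constant="add")
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.Logit(y, X)
            res = model.fit(method="newton", maxiter=100, tol=1e-8, disp=0)
        params = np.asarray(res.params, dtype=float)
        bse = np.asarray(res.bse, dtype=float)
        score = np.asarray(model.score(params), dtype=float)
        grad_norm = float(np.max(np.abs(score))) if np.all(np.isfinite(score)) else np.inf
        converged = bool(res.mle_retvals.get("converged", False)) and np.all(np.isfinite(bse))
        if np.any(np.abs(params) > SEPARATION_BETA) and grad_norm > 1e-4:
            converged = False
        p_hat = np.asarray(res.predict(X), dtype=float)
        loglik = float(res.llf)
    except Exception:
        k = design.shape[1] + 1
        nan = {t: float("nan") for t in ("intercept", *design.columns)}
        return FitResult(
            terms=tuple(design.columns),
            beta=dict(nan),
            se=dict(nan),
            ci_low=dict(nan),
            ci_high=dict(nan),
            loglik=float("nan"),
            aic=float("nan"),
            rmse=float("nan"),
            n_used=len(y),
            converged=False,
        )

    names = ["intercept"] + list(design.columns)
    beta = {n: float(b) for n, b in zip(names, params)}
    se = {n: float(s) for n, s in zip(names, bse)}
    ci_low = {n: beta[n] - Z_95 * se[n] for n in names}
    ci_high = {n: beta[n] + Z_95 * se[n] for n in names}
    k = len(names)
    return FitResult(
        terms=tuple(design.columns),
        beta=beta,
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        loglik=loglik,
        aic=2.0 * k - 2.0 * loglik,
        rmse=model_rmse(y, p_hat),
        n_used=len(y),
        converged=bool(converged),
    )


def model_rmse(outcome: np.ndarray, fitted_probabilities: np.ndarray) -> float:
    """Root mean squared error on the probability scale (Brier root)."""
    y = np.asarray(outcome, dtype=float)
    p = np.asarray(fitted_probabilities, dtype=float)
    return float(np.sqrt(np.mean((y - p) ** 2)))


def fit_cohort(table: pd.DataFrame, method: str = "reference") -> FitResult:
    """Fit the association model to a cohort table.

    ``method="cc"`` applies the complete-case filter first; all other methods
    require a fully imputed table (missingness-indicator extras are picked up
    from the table itself).
    """
    if method == "cc":
        table = complete_case_filter(table)
    design = build_design(table)
    return fit_logistic(design, table["bcpr"])
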