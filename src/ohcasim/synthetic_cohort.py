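"""Synthetic OHCA-like cohort generators.

Two modes:

* **table-faithful** — reproduces a packaged stratified count table exactly at
  ``scale=1`` (stratum totals and every covariate-level count per stratum),
  with covariates sampled independently of one another within a stratum and
  age drawn from a log-normal fitted to the stratum's printed quartiles.
* **model-based** — covariates are sampled from the whole-cohort marginals and
  the binary outcome from a logistic model with known coefficients, so the
  data-generating truth is available for estimand evaluation. The intercept is
  calibrated by monotone root-finding to hit a target outcome prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm

from . import schema
from .association_model import MODEL_TERMS, build_design

__all__ = [
    "TrueCoefficients",
    "Table1Counts",
    "StratumCounts",
    "DEFAULT_TRUE_BETA",
    "generate_table_faithful",
    "generate_model_based",
    "calibrate_intercept",
]

#: Reference log-odds coefficients of the data-generating model (one entry per
#: non-intercept model term).
DEFAULT_TRUE_BETA: dict[str, float] = {
    "alert_issued": 2.43,
    "male": -0.11,
    "age": 0.0015,
    "witness_family": 0.17,
    "witness_healthcare": 2.16,
    "witness_lay": -0.11,
    "calltime_06_18": 0.011,
    "calltime_19_23": -0.063,
    "location_public": 1.03,
    "rhythm_shockable": 0.58,
    "rhythm_unknown": 2.03,
}

#: Default outcome prevalence targeted by the model-based generator.
DEFAULT_TARGET_PREVALENCE = 0.653

_Z75 = float(norm.ppf(0.75))


@dataclass
class TrueCoefficients:
    """Data-generating log-odds coefficients of the outcome model."""

    intercept: float | None = None
    beta: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TRUE_BETA))

    def validate(self) -> None:
        missing = [t for t in MODEL_TERMS if t not in self.beta]
        if missing:
            raise ValueError(f"beta lacks model terms: {missing}")
        bad = [t for t, v in self.beta.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite beta for terms: {bad}")


@dataclass
class StratumCounts:
    """Counts and age quartiles of one exposure-by-outcome stratum."""

    alert_issued: int
    bcpr: int
    total: int
    age_quartiles: tuple[float, float, float]  # (q1, median, q3)
    levels: dict[str, dict[str, int]]  # covariate -> level -> count

    @property
    def key(self) -> tuple[int, int]:
        return (self.alert_issued, self.bcpr)


@dataclass
class Table1Counts:
    """Stratified characteristic counts driving the table-faithful generator."""

    total: int
    strata: list[StratumCounts]
    age_by_alert: dict[int, tuple[float, float, float]]

    @classmethod
    def default(cls) -> "Table1Counts":
        """Load the packaged count fixture."""
        text = resources.files("ohcasim").joinpath("data/table1_counts.yaml").read_text()
        raw = yaml.safe_load(text)
        strata = [
            StratumCounts(
                alert_issued=int(s["alert_issued"]),
                bcpr=int(s["bcpr"]),
                total=int(s["total"]),
                age_quartiles=(float(s["age"]["q1"]), float(s["age"]["median"]), float(s["age"]["q3"])),
                levels={cov: {lv: int(c) for lv, c in s[cov].items()} for cov in schema.CATEGORICAL},
            )
            for s in raw["strata"]
        ]
        age_by_alert = {
            0: tuple(raw["age_by_alert"]["alert0"][k] for k in ("q1", "median", "q3")),
            1: tuple(raw["age_by_alert"]["alert1"][k] for k in ("q1", "median", "q3")),
        }
        return cls(total=int(raw["total"]), strata=strata, age_by_alert=age_by_alert)

    def validate(self) -> None:
        if sum(s.total for s in self.strata) != self.total:
            raise ValueError(
                f"stratum totals sum to {sum(s.total for s in self.strata)}, expected {self.total}"
            )
        for s in self.strata:
            for cov, level_counts in s.levels.items():
                unknown = set(level_counts) - set(schema.DOMAINS[cov])
                if unknown:
                    raise ValueError(
                        f"stratum (alert={s.alert_issued}, bcpr={s.bcpr}): unknown {cov} levels {sorted(unknown)}"
                    )
                got = sum(level_counts.values())
                if got != s.total:
                    raise ValueError(
                        f"stratum (alert={s.alert_issued}, bcpr={s.bcpr}): {cov} counts sum to {got}, "
                        f"expected {s.total}"
                    )

    def marginal_level_counts(self, covariate: str) -> dict[str, int]:
        """Whole-cohort level counts of one covariate (sum over strata)."""
        out = {lv: 0 for lv in schema.DOMAINS[covariate]}
        for s in self.strata:
            for lv, c in s.levels[covariate].items():
                out[lv] += c
        return out

    def exposure_count(self) -> int:
        return sum(s.total for s in self.strata if s.alert_issued == 1)


def _apportion(counts: np.ndarray, n_target: int) -> np.ndarray:
    """Largest-remainder apportionment of ``counts`` to sum ``n_target``."""
    counts = np.asarray(counts, dtype=float)
    quota = counts * n_target / counts.sum()
    base = np.floor(quota).astype(int)
    short = n_target - int(base.sum())
    if short > 0:
        order = np.argsort(-(quota - base), kind="stable")
        base[order[:short]] += 1
    return base


def _lognormal_params(q1: float, median: float, q3: float) -> tuple[float, float]:
    """(mu, sigma) of the log-normal matching the median and IQR ratio."""
    if not (0 < q1 <= median <= q3):
        raise ValueError(f"inconsistent quartiles ({q1}, {median}, {q3})")
    mu = np.log(median)
    sigma = np.log(q3 / q1) / (2.0 * _Z75)
    return mu, sigma


def _sample_truncated_lognormal(
    rng: np.random.Generator,
    n: int,
    quartiles: tuple[float, float, float],
    lo: float = schema.AGE_MIN,
    hi: float = schema.AGE_MAX,
) -> np.ndarray:
    mu, sigma = _lognormal_params(*quartiles)
    out = np.empty(n)
    need = np.arange(n)
    # rejection sampling; acceptance rate is ~0.99 for the printed quartiles
    while need.size:
        draw = rng.lognormal(mu, sigma, size=need.size)
        ok = (draw >= lo) & (draw <= hi)
        out[need[ok]] = draw[ok]
        need = need[~ok]
    return out


def generate_table_faithful(
    counts: Table1Counts | None = None,
    scale: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a cohort whose stratum and covariate-level counts match ``counts``.

    At ``scale=1`` every count is reproduced exactly; at smaller scales counts
    are apportioned by largest remainder so sums stay consistent. Covariates
    are shuffled independently within each stratum (no cross-covariate
    dependence beyond the stratification), and age is drawn from a truncated
    log-normal fitted to the stratum quartiles.
    """
    if not (0.0 < scale <= 1.0):
        raise ValueError(f"scale must be in (0, 1], got {scale}")
    counts = counts or Table1Counts.default()
    counts.validate()
    rng = np.random.default_rng(seed)

    n_total = int(round(counts.total * scale))
    if n_total < 1:
        raise ValueError(f"scale {scale} yields an empty cohort")
    stratum_sizes = _apportion(np.array([s.total for s in counts.strata]), n_total)

    frames = []
    for s, n_s in zip(counts.strata, stratum_sizes):
        if n_s == 0:
            continue
        cols: dict[str, np.ndarray] = {}
        for cov in schema.CATEGORICAL:
            domain = schema.DOMAINS[cov]
            level_counts = _apportion(
                np.array([s.levels[cov].get(lv, 0) for lv in domain]), n_s
            )
            vals = np.repeat(np.array(domain, dtype=object), level_counts)
            cols[cov] = rng.permutation(vals)
        cols["age"] = _sample_truncated_lognormal(rng, n_s, s.age_quartiles)
        cols["alert_issued"] = np.full(n_s, s.alert_issued, dtype=int)
        cols["bcpr"] = np.full(n_s, s.bcpr, dtype=int)
        frames.append(pd.DataFrame(cols))

    table = pd.concat(frames, ignore_index=True)
    table = table.iloc[rng.permutation(len(table))].reset_index(drop=True)
    table.insert(0, "case_id", np.arange(1, len(table) + 1))
    table = table[list(schema.COLUMNS)]
    schema.validate_cohort(table)
    return table


def _design_score(table: pd.DataFrame, beta: dict[str, float]) -> np.ndarray:
    design = build_design(table)
    b = np.array([beta[t] for t in design.columns])
    return design.to_numpy() @ b


def calibrate_intercept(
    table: pd.DataFrame,
    beta: dict[str, float],
    target_prevalence: float,
) -> float:
    """Intercept such that mean inverse-logit(intercept + x.beta) hits the target.

    The mean probability is strictly increasing in the intercept, so the root
    is unique; it is found by Brent's method to well below 1e-8.
    """
    if not (0.0 < target_prevalence < 1.0):
        raise ValueError(f"target_prevalence must be in (0, 1), got {target_prevalence}")
    scores = _design_score(table, beta)
    return _calibrate_from_scores(scores, target_prevalence)


def _calibrate_from_scores(scores: np.ndarray, target: float) -> float:
    def f(a: float) -> float:
        return float(np.mean(expit(a + scores))) - target

    lo, hi = -60.0, 60.0
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16))


def generate_model_based(
    n: int,
    coefs: TrueCoefficients | None = None,
    target_prevalence: float | None = None,
    seed: int = 0,
    counts: Table1Counts | None = None,
) -> tuple[pd.DataFrame, TrueCoefficients]:
    """Generate a cohort with a logistic-model outcome and known coefficients.

    Covariates are sampled independently from the whole-cohort marginals of
    ``counts``; age is drawn conditionally on exposure from the marginal
    quartiles of each exposure group. The outcome is Bernoulli with
    probability ``expit(intercept + x.beta)``. When ``coefs.intercept`` is
    ``None`` the intercept is calibrated to ``target_prevalence`` (default
    0.653) and returned in the ``TrueCoefficients``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    coefs = coefs or TrueCoefficients()
    coefs.validate()
    if coefs.intercept is None:
        target_prevalence = (
            DEFAULT_TARGET_PREVALENCE if target_prevalence is None else target_prevalence
        )
        if not (0.0 < target_prevalence < 1.0):
            raise ValueError(f"target_prevalence must be in (0, 1), got {target_prevalence}")
    counts = counts or Table1Counts.default()
    counts.validate()
    rng = np.random.default_rng(seed)

    p_alert = counts.exposure_count() / counts.total
    alert = (rng.random(n) < p_alert).astype(int)

    cols: dict[str, np.ndarray] = {"alert_issued": alert}
    for cov in schema.CATEGORICAL:
        domain = schema.DOMAINS[cov]
        marg = counts.marginal_level_counts(cov)
        probs = np.array([marg[lv] for lv in domain], dtype=float)
        probs /= probs.sum()
        cols[cov] = rng.choice(np.array(domain, dtype=object), size=n, p=probs)

    age = np.empty(n)
    for a in (0, 1):
        idx = np.flatnonzero(alert == a)
        if idx.size:
            age[idx] = _sample_truncated_lognormal(rng, idx.size, counts.age_by_alert[a])
    cols["age"] = age
    cols["bcpr"] = np.zeros(n, dtype=int)  # placeholder until scored

    table = pd.DataFrame(cols)
    table.insert(0, "case_id", np.arange(1, n + 1))
    table = table[list(schema.COLUMNS)]

    scores = _design_score(table, coefs.beta)
    intercept = (
        coefs.intercept
        if coefs.intercept is not None
        else _calibrate_from_scores(scores, target_prevalence)
    )
    table["bcpr"] = (rng.random(n) < expit(intercept + scores)).astype(int)
    schema.validate_cohort(table)
    return table, TrueCoefficients(intercept=float(intercept), beta=dict(coefs.beta))
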