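"""Simulation harness: repeat ampute -> impute -> analyse and summarise.

Each repetition draws one amputed table from the reference cohort, applies
every requested method once to that same table, and fits the association
model. Summaries report, per method x term x missingness proportion: mean
coefficient, bias against the truth, empirical SE, 95% CI coverage, mean AIC
and RMSE, with Monte-Carlo standard errors, computed over converged
repetitions only (failures are counted, never silently dropped).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import schema
from .amputer import AmputationSpec, ampute
from .association_model import MODEL_TERMS, Z_95, FitResult, fit_cohort
from .imputers import (
    ForestConfig,
    KnnConfig,
    impute_knn,
    impute_mean_mode,
    impute_missforest,
    impute_missingness_indicator,
)
from .synthetic_cohort import TrueCoefficients

logger = logging.getLogger(__name__)

__all__ = ["SimulationConfig", "run_one_rep", "summarize", "run_simulation"]

METHODS = ("cc", "mm", "mxi", "mf", "knn")

#: Columns of the long per-repetition record.
REP_COLUMNS = (
    "proportion",
    "rep",
    "method",
    "term",
    "beta",
    "se",
    "converged",
    "aic",
    "rmse",
    "n_used",
)


@dataclass
class SimulationConfig:
    """Full design of a simulation run."""

    reps: int = 200
    proportions: tuple[float, ...] = (0.10, 0.20, 0.30, 0.40)
    methods: tuple[str, ...] = METHODS
    base_seed: int = 0
    pattern_freqs: dict[str, float] | None = None
    weights: dict[str, dict[str, float]] | None = None
    knn: KnnConfig = field(default_factory=KnnConfig)
    forest: ForestConfig = field(default_factory=ForestConfig)

    def __post_init__(self) -> None:
        if self.reps < 2:
            raise ValueError(f"reps must be >= 2, got {self.reps}")
        bad = [p for p in self.proportions if not (0.0 < p < 1.0)]
        if bad:
            raise ValueError(f"proportions outside (0, 1): {bad}")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")

    def amputation_spec(self, proportion: float) -> AmputationSpec:
        kwargs: dict = {"proportion": proportion}
        if self.pattern_freqs is not None:
            kwargs["pattern_freqs"] = dict(self.pattern_freqs)
        if self.weights is not None:
            kwargs["weights"] = {p: dict(w) for p, w in self.weights.items()}
        return AmputationSpec(**kwargs)


def run_one_rep(
    reference: pd.DataFrame,
    spec: AmputationSpec,
    methods: tuple[str, ...] = METHODS,
    seed: int = 0,
    knn_cfg: KnnConfig | None = None,
    forest_cfg: ForestConfig | None = None,
) -> dict[str, FitResult]:
    """One amputation draw, every method applied to it, one fit per method."""
    amputed, _mask = ampute(reference, spec, seed=seed)
    results: dict[str, FitResult] = {}
    for method in methods:
        try:
            if method == "cc":
                results["cc"] = fit_cohort(amputed, method="cc")
                continue
            if method == "mm":
                imputed = impute_mean_mode(amputed)
            elif method == "mxi":
                imputed = impute_missingness_indicator(amputed)
            elif method == "mf":
                fc = forest_cfg or ForestConfig()
                fc = ForestConfig(
                    n_trees=fc.n_trees,
                    max_iter=fc.max_iter,
                    min_leaf=fc.min_leaf,
                    max_samples=fc.max_samples,
                    seed=seed,
                    variables=fc.variables,
                )
                imputed = impute_missforest(amputed, fc)
            elif method == "knn":
                imputed = impute_knn(amputed, knn_cfg)
            else:
                raise ValueError(f"unknown method {method!r}")
            results[method] = fit_cohort(imputed.table, method=method)
        except Exception as exc:  # propagate with rep context
            raise RuntimeError(f"method {method!r} failed (seed {seed}): {exc}") from exc
    return results


def _rep_records(proportion: float, rep: int, fits: dict[str, FitResult]) -> list[dict]:
    rows = []
    for method, fit in fits.items():
        for term in fit.terms:
            rows.append(
                {
                    "proportion": proportion,
                    "rep": rep,
                    "method": method,
                    "term": term,
                    "beta": fit.beta[term],
                    "se": fit.se[term],
                    "converged": fit.converged,
                    "aic": fit.aic,
                    "rmse": fit.rmse,
                    "n_used": fit.n_used,
                }
            )
    return rows


def summarize(rep_results: pd.DataFrame, true: TrueCoefficients) -> pd.DataFrame:
    """Per (method, term, proportion) simulation estimands.

    ``rep_results`` is the long frame produced by :func:`run_simulation`
    (columns :data:`REP_COLUMNS`). Cells with fewer than two converged reps
    are reported with NaN estimands rather than fabricated values. Terms
    without a defined truth (missingness-indicator extras) get NaN bias and
    coverage.
    """
    df = rep_results.copy()
    rows = []
    for (proportion, method, term), cell in df.groupby(["proportion", "method", "term"], sort=True):
        ok = cell[cell["converged"].astype(bool)]
        n_reps = cell["rep"].nunique()
        n_failed = n_reps - ok["rep"].nunique()
        beta_true = true.beta.get(term, np.nan)
        if len(ok) < 2:
            rows.append(
                {
                    "method": method,
                    "term": term,
                    "proportion": proportion,
                    "mean_beta": np.nan,
                    "bias": np.nan,
                    "emp_se": np.nan,
                    "coverage": np.nan,
                    "mean_aic": np.nan,
                    "mean_rmse": np.nan,
                    "mean_n_used": np.nan,
                    "mc_se_bias": np.nan,
                    "mc_se_coverage": np.nan,
                    "n_reps": n_reps,
                    "n_failed": n_failed,
                }
            )
            continue
        beta = ok["beta"].to_numpy(dtype=float)
        se = ok["se"].to_numpy(dtype=float)
        r = len(beta)
        mean_beta = float(beta.mean())
        emp_se = float(beta.std(ddof=1))
        if np.isfinite(beta_true):
            covered = (beta - Z_95 * se <= beta_true) & (beta_true <= beta + Z_95 * se)
            coverage = float(covered.mean())
            bias = mean_beta - float(beta_true)
            mc_se_cov = float(np.sqrt(coverage * (1.0 - coverage) / r))
        else:
            coverage = bias = mc_se_cov = np.nan
        rows.append(
            {
                "method": method,
                "term": term,
                "proportion": proportion,
                "mean_beta": mean_beta,
                "bias": bias,
                "emp_se": emp_se,
                "coverage": coverage,
                "mean_aic": float(ok["aic"].mean()),
                "mean_rmse": float(ok["rmse"].mean()),
                "mean_n_used": float(ok["n_used"].mean()),
                "mc_se_bias": emp_se / np.sqrt(r),
                "mc_se_coverage": mc_se_cov,
                "n_reps": n_reps,
                "n_failed": n_failed,
            }
        )
    return pd.DataFrame(rows)


def run_simulation(
    reference: pd.DataFrame,
    true: TrueCoefficients,
    cfg: SimulationConfig,
    out_dir: str | Path | None = None,
    cohort_factory=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full design; returns (summary, per-rep long frame).

    Repetition ``r`` uses seed ``base_seed + r`` so runs are individually
    replayable. With a fixed ``reference`` every repetition amputes the same
    cohort (the design used when the reference data are a fixed registry and
    the truth is the reference fit). For exact-truth estimands — coverage in
    particular — pass ``cohort_factory``, a callable mapping the rep seed to
    a freshly drawn complete cohort from the model with coefficients
    ``true``; each repetition then carries full sampling variability and the
    generator coefficients are the estimand truth. When ``out_dir`` is given,
    per-rep records are appended to ``reps.csv`` as they complete and
    already-present (proportion, rep) cells are skipped on restart; the
    summary is written to ``summary.csv``.
    """
    if not schema.is_complete(reference):
        raise ValueError("reference cohort must be complete")
    out_path = Path(out_dir) if out_dir is not None else None
    reps_file = out_path / "reps.csv" if out_path else None

    done: set[tuple[float, int]] = set()
    records: list[dict] = []
    if reps_file is not None and reps_file.exists():
        existing = pd.read_csv(reps_file)
        if len(existing):
            records = existing.to_dict("records")
            done = {(float(p), int(r)) for p, r in zip(existing["proportion"], existing["rep"])}
            logger.info("resuming: %d completed cells found", len(done))
    elif reps_file is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(columns=list(REP_COLUMNS)).to_csv(reps_file, index=False)

    for proportion in cfg.proportions:
        spec = cfg.amputation_spec(proportion)
        for rep in range(cfg.reps):
            if (float(proportion), rep) in done:
                continue
            seed = cfg.base_seed + rep
            cohort = reference if cohort_factory is None else cohort_factory(seed)
            fits = run_one_rep(
                cohort, spec, cfg.methods, seed=seed, knn_cfg=cfg.knn, forest_cfg=cfg.forest
            )
            n_bad = sum(not f.converged for f in fits.values())
            if n_bad:
                logger.warning(
                    "proportion %.2f rep %d: %d non-converged fits", proportion, rep, n_bad
                )
            new = _rep_records(float(proportion), rep, fits)
            records.extend(new)
            if reps_file is not None:
                pd.DataFrame(new).to_csv(reps_file, mode="a", header=False, index=False)

    reps_df = pd.DataFrame(records, columns=list(REP_COLUMNS))
    summary = summarize(reps_df, true)
    for _, row in summary.iterrows():
        if row["n_reps"] and row["n_failed"] == row["n_reps"]:
            logger.warning(
                "cell (%s, %s, %.2f): all reps failed", row["method"], row["term"], row["proportion"]
            )
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out_path / "summary.csv", index=False)
    return summary, reps_df
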