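"""Single-imputation methods: mean/mode, missingness-indicator, Gower KNN,
and an iterative random-forest imputer.

All imputers leave observed cells untouched, preserve row count and order,
and return an :class:`ImputedCohort` carrying the method tag, the provenance
missingness mask, and (for the missingness-indicator method) the extra model
terms it introduces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from . import schema

logger = logging.getLogger(__name__)

__all__ = [
    "ImputedCohort",
    "KnnConfig",
    "ForestConfig",
    "impute_mean_mode",
    "impute_missingness_indicator",
    "impute_knn",
    "impute_missforest",
    "gower_distance",
]

#: Variables entering the Gower distance and the forest predictors. The
#: outcome is included so imputation preserves covariate-outcome association;
#: pass an explicit variable list to switch it off.
DEFAULT_PREDICTOR_VARIABLES = (
    "age",
    "gender",
    "witness_type",
    "arrest_location",
    "call_time",
    "first_rhythm",
    "alert_issued",
    "bcpr",
)


@dataclass
class ImputedCohort:
    """A cohort after imputation, with provenance."""

    table: pd.DataFrame
    method: str
    mask: pd.DataFrame  # case_id, pattern
    extra_terms: list[str] = field(default_factory=list)


@dataclass
class KnnConfig:
    """K-nearest-neighbour imputation settings (Gower distance)."""

    k: int = 5
    variables: tuple[str, ...] | None = None  # None -> DEFAULT_PREDICTOR_VARIABLES

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")


@dataclass
class ForestConfig:
    """Iterative random-forest imputation settings."""

    n_trees: int = 100
    max_iter: int = 10
    min_leaf: int = 10
    max_samples: float | None = 0.2  # per-tree bootstrap fraction
    seed: int = 0
    variables: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError(f"n_trees must be >= 1, got {self.n_trees}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be >= 1, got {self.max_iter}")


def _provenance_mask(table: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        {"case_id": table["case_id"].to_numpy(), "pattern": schema.missing_pattern(table).to_numpy()}
    )


def _mode_domain_order(values, domain: tuple[str, ...]) -> str:
    """Most frequent level; ties broken by position in the declared domain."""
    counts: dict[str, int] = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    best, best_count = None, 0
    for level in domain:
        c = counts.get(level, 0)
        if c > best_count:
            best, best_count = level, c
    if best is None:
        raise ValueError("no observed values to take a mode over")
    return best


def _fill_mean_mode(table: pd.DataFrame) -> pd.DataFrame:
    filled = table.copy()
    for var in schema.AMPUTABLE:
        gaps = filled[var].isna()
        if not gaps.any():
            continue
        observed = filled.loc[~gaps, var]
        if observed.empty:
            raise ValueError(f"column {var!r} is fully missing; cannot impute")
        if var == "age":
            filled.loc[gaps, var] = float(observed.mean())
        else:
            filled.loc[gaps, var] = _mode_domain_order(observed, schema.DOMAINS[var])
    return filled


def impute_mean_mode(table: pd.DataFrame) -> ImputedCohort:
    """Replace gaps with the column mean (continuous) or mode (categorical)."""
    mask = _provenance_mask(table)
    return ImputedCohort(table=_fill_mean_mode(table), method="mm", mask=mask)


def impute_missingness_indicator(table: pd.DataFrame) -> ImputedCohort:
    """Fill gaps with a sentinel and record missingness as extra model terms.

    Continuous age: fill 0 and add a binary ``age_missing`` column.
    Categoricals: add an explicit ``missing`` level (equivalent to fill plus
    indicator in the design matrix).
    """
    mask = _provenance_mask(table)
    out = table.copy()
    extra: list[str] = []
    age_gaps = out["age"].isna()
    if age_gaps.any():
        out["age"] = out["age"].fillna(0.0)
        out[schema.AGE_MISSING_COLUMN] = age_gaps.astype(int)
        extra.append("age_missing")
    for var, term in (("witness_type", "witness_missing"), ("call_time", "calltime_missing")):
        gaps = out[var].isna()
        if gaps.any():
            out.loc[gaps, var] = schema.MISSING_LEVEL
            extra.append(term)
    return ImputedCohort(table=out, method="mxi", mask=mask, extra_terms=extra)


# ---------------------------------------------------------------------------
# Gower distance / KNN


def _variable_codes(table: pd.DataFrame, variables: tuple[str, ...]):
    """Numeric coding of ``variables`` for Gower distance.

    Returns (codes matrix with NaN for missing, continuous flags, ranges).
    Ordinal call_time is coded as ranks scaled to [0, 1]; categoricals as
    level indices compared by mismatch.
    """
    n = len(table)
    codes = np.full((n, len(variables)), np.nan)
    continuous = np.zeros(len(variables), dtype=bool)
    ranges = np.ones(len(variables))
    for j, var in enumerate(variables):
        if var == "age":
            x = table["age"].to_numpy(dtype=float)
            codes[:, j] = x
            continuous[j] = True
            obs = x[~np.isnan(x)]
            if obs.size:
                span = float(obs.max() - obs.min())
                ranges[j] = span if span > 0 else 1.0
        elif var == "call_time":
            domain = schema.DOMAINS[var]
            mapping = {lv: i / (len(domain) - 1) for i, lv in enumerate(domain)}
            codes[:, j] = table[var].map(mapping).to_numpy(dtype=float)
            continuous[j] = True
        elif var in schema.DOMAINS:
            mapping = {lv: float(i) for i, lv in enumerate(schema.DOMAINS[var])}
            codes[:, j] = table[var].map(mapping).to_numpy(dtype=float)
        else:
            codes[:, j] = table[var].to_numpy(dtype=float)
    return codes, continuous, ranges


def gower_distance(
    row_a,
    row_b,
    numeric_ranges: dict[str, float] | None = None,
    variables: tuple[str, ...] = DEFAULT_PREDICTOR_VARIABLES,
) -> float:
    """Gower dissimilarity in [0, 1] between two cases (mapping-like rows).

    Mean over variables observed in both rows of: scaled absolute difference
    (continuous; ordinal call_time as ranks in [0, 1]) or 0/1 mismatch
    (categorical). Raises ``ValueError`` when no variable is shared.
    """
    numeric_ranges = numeric_ranges or {}
    total, used = 0.0, 0
    calltime_rank = {
        lv: i / (len(schema.DOMAINS["call_time"]) - 1)
        for i, lv in enumerate(schema.DOMAINS["call_time"])
    }
    for var in variables:
        a, b = row_a[var], row_b[var]
        if pd.isna(a) or pd.isna(b):
            continue
        if var == "age":
            span = float(numeric_ranges.get("age", 1.0))
            if span <= 0:
                raise ValueError("numeric range for 'age' must be positive")
            total += abs(float(a) - float(b)) / span
        elif var == "call_time":
            total += abs(calltime_rank[a] - calltime_rank[b])
        else:
            total += float(a != b)
        used += 1
    if used == 0:
        raise ValueError("no usable shared variable between rows")
    return total / used


def _gower_block(A: np.ndarray, B: np.ndarray, continuous: np.ndarray, ranges: np.ndarray) -> np.ndarray:
    """Pairwise Gower distances between row blocks A (g x V) and B (d x V)."""
    g, V = A.shape
    d = B.shape[0]
    num = np.zeros((g, d), dtype=np.float32)
    cnt = np.zeros((g, d), dtype=np.float32)
    for j in range(V):
        a = A[:, j][:, None]
        b = B[:, j][None, :]
        valid = ~np.isnan(a) & ~np.isnan(b)
        if continuous[j]:
            with np.errstate(invalid="ignore"):
                c = np.abs(a - b) / ranges[j]
            c = np.where(valid, c, 0.0).astype(np.float32)
        else:
            with np.errstate(invalid="ignore"):
                c = np.where(valid, (a != b), False).astype(np.float32)
        num += c
        cnt += valid
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / cnt
    out[cnt == 0] = np.inf  # no shared variable
    return out


def _pairwise_gower(
    codes: np.ndarray,
    continuous: np.ndarray,
    ranges: np.ndarray,
    gap_idx: np.ndarray,
    donor_idx: np.ndarray,
    keep: list[int],
) -> np.ndarray:
    """Gower distances between gap rows and donors over the ``keep`` variables.

    Fast path: fully observed categorical variables are collapsed into a row
    profile so their joint mismatch count comes from one table lookup; only
    variables with missing cells (at most two, by the one-gap-per-row
    construction) need pairwise work. Gap rows observe every kept variable,
    so the pair-validity count depends on the donor alone.
    """
    if np.isnan(codes[np.ix_(gap_idx, keep)]).any():
        # gap rows missing a non-target variable: fall back to the generic path
        return _gower_block(
            codes[np.ix_(gap_idx, keep)],
            codes[np.ix_(donor_idx, keep)],
            continuous[keep],
            ranges[keep],
        )

    # split kept variables into profile-able (few distinct values) and broadcast
    prof_cols: list[int] = []
    bcast_cols: list[int] = []
    col_levels: dict[int, np.ndarray] = {}
    for j in keep:
        vals = np.unique(codes[:, j])
        vals = vals[~np.isnan(vals)]
        if vals.size <= 16:
            prof_cols.append(j)
            col_levels[j] = vals
        else:
            bcast_cols.append(j)

    n = codes.shape[0]
    g, d = gap_idx.size, donor_idx.size
    if prof_cols:
        enc = np.zeros((n, len(prof_cols)), dtype=np.int16)
        for t, j in enumerate(prof_cols):
            col = codes[:, j]
            isn = np.isnan(col)
            e = np.searchsorted(col_levels[j], np.where(isn, col_levels[j][0], col))
            e[isn] = col_levels[j].size  # sentinel level for missing
            enc[:, t] = e
        uniq, inv = np.unique(enc, axis=0, return_inverse=True)
        u = uniq.shape[0]
        lut = np.zeros((u, u), dtype=np.float32)
        valid_per_profile = np.zeros(u, dtype=np.float32)
        for t, j in enumerate(prof_cols):
            levels = col_levels[j]
            vcol = np.where(uniq[:, t] == levels.size, np.nan, levels[np.minimum(uniq[:, t], levels.size - 1)])
            valid = ~np.isnan(vcol)
            pair_valid = valid[:, None] & valid[None, :]
            if continuous[j]:
                base = np.abs(vcol[:, None] - vcol[None, :]) / ranges[j]
            else:
                base = (vcol[:, None] != vcol[None, :]).astype(float)
            lut += np.where(pair_valid, base, 0.0)
            valid_per_profile += valid
        num = lut[inv[gap_idx]][:, inv[donor_idx]]
        cnt = valid_per_profile[inv[donor_idx]].copy()
    else:
        num = np.zeros((g, d), dtype=np.float32)
        cnt = np.zeros(d, dtype=np.float32)

    for j in bcast_cols:
        a = codes[gap_idx, j].astype(np.float32)[:, None]
        b = codes[donor_idx, j].astype(np.float32)
        valid = ~np.isnan(b)
        b_safe = np.where(valid, b, 0.0)[None, :]
        if continuous[j]:
            c = np.abs(a - b_safe) / np.float32(ranges[j])
        else:
            c = (a != b_safe).astype(np.float32)
        c *= valid[None, :]
        num += c
        cnt += valid
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / cnt[None, :]
    out[:, cnt == 0] = np.inf
    return out


def impute_knn(table: pd.DataFrame, cfg: KnnConfig | None = None) -> ImputedCohort:
    """Fill each gap from its k Gower-nearest donors (median / mode).

    Donors are rows observing the target variable; the target itself never
    enters the distance. Deterministic: distance ties break by lower case_id,
    mode ties by domain order.
    """
    cfg = cfg or KnnConfig()
    mask = _provenance_mask(table)
    out = table.copy()
    variables = tuple(cfg.variables) if cfg.variables else DEFAULT_PREDICTOR_VARIABLES
    codes, continuous, ranges = _variable_codes(table, variables)
    case_ids = table["case_id"].to_numpy()

    for target in schema.AMPUTABLE:
        gap = table[target].isna().to_numpy()
        if not gap.any():
            continue
        donor_idx = np.flatnonzero(~gap)
        gap_idx = np.flatnonzero(gap)
        if donor_idx.size == 0:
            raise ValueError(f"no donors observe {target!r}")
        k = cfg.k
        if donor_idx.size < k:
            logger.warning(
                "only %d donors for %r (k=%d); using all donors", donor_idx.size, target, k
            )
            k = donor_idx.size
        keep = [j for j, v in enumerate(variables) if v != target]
        donor_ids = case_ids[donor_idx]
        donor_vals = table[target].to_numpy()[donor_idx]

        # gap rows with identical kept-variable values share the same donors
        # and hence the same fill; deduplicate when that pays off
        work_idx, expand = gap_idx, None
        sub = codes[np.ix_(gap_idx, keep)]
        if not np.isnan(sub).any():
            uniq, inv = np.unique(sub, axis=0, return_inverse=True)
            if uniq.shape[0] * 4 < gap_idx.size:
                first = np.zeros(uniq.shape[0], dtype=int)
                first[inv[::-1]] = gap_idx[::-1]
                work_idx, expand = first, inv

        fills = (
            np.empty(work_idx.size, dtype=float)
            if target == "age"
            else np.empty(work_idx.size, dtype=object)
        )
        chunk = 1024
        for start in range(0, work_idx.size, chunk):
            block = work_idx[start : start + chunk]
            D = _pairwise_gower(codes, continuous, ranges, block, donor_idx, keep)
            g = D.shape[0]
            if k < D.shape[1]:
                part = np.argpartition(D, k - 1, axis=1)[:, :k]
            else:
                part = np.broadcast_to(np.arange(D.shape[1]), (g, D.shape[1]))
            dk = D[np.arange(g)[:, None], part].max(axis=1)
            n_at_or_below = (D <= dk[:, None]).sum(axis=1)
            for r in range(g):
                dist = D[r]
                if not np.isfinite(dk[r]) and not np.isfinite(dist).any():
                    raise ValueError(f"no usable shared variable for a {target!r} gap row")
                if n_at_or_below[r] == k:
                    sel = part[r]  # the k-nearest set is unique; order irrelevant
                else:
                    cand = np.flatnonzero(dist <= dk[r])
                    order = np.lexsort((donor_ids[cand], dist[cand]))
                    sel = cand[order[:k]]
                vals = donor_vals[sel]
                if target == "age":
                    fills[start + r] = float(np.median(vals.astype(float)))
                else:
                    fills[start + r] = _mode_domain_order(vals, schema.DOMAINS[target])
        if expand is not None:
            fills = fills[expand]
        col = out[target].to_numpy().copy()
        col[gap_idx] = fills
        out[target] = col
    return ImputedCohort(table=out, method="knn", mask=mask)


# ---------------------------------------------------------------------------
# Iterative random-forest imputation


def _encode_predictors(table: pd.DataFrame, variables: tuple[str, ...], exclude: str) -> np.ndarray:
    """One-hot style numeric matrix of all predictor variables except ``exclude``."""
    cols: list[np.ndarray] = []
    for var in variables:
        if var == exclude:
            continue
        if var in schema.DOMAINS:
            vals = table[var]
            for level in schema.DOMAINS[var]:
                cols.append((vals == level).to_numpy(dtype=np.float32))
        else:
            cols.append(table[var].to_numpy(dtype=np.float32))
    return np.column_stack(cols)


def impute_missforest(table: pd.DataFrame, cfg: ForestConfig | None = None) -> ImputedCohort:
    """Iterative random-forest imputation (mean/mode start, forest refits).

    Variables are visited in order of increasing missingness. After each
    sweep the normalized squared change (continuous) and the proportion of
    changed categories (categorical) between successive fills are computed;
    iteration stops the first time every applicable criterion increases, and
    the previous sweep's fill is returned. Hitting ``max_iter`` returns the
    last fill with a logged warning.
    """
    cfg = cfg or ForestConfig()
    mask = _provenance_mask(table)
    variables = tuple(cfg.variables) if cfg.variables else DEFAULT_PREDICTOR_VARIABLES

    gaps = {
        var: table[var].isna().to_numpy()
        for var in schema.AMPUTABLE
        if table[var].isna().any()
    }
    if not gaps:
        return ImputedCohort(table=table.copy(), method="mf", mask=mask)

    filled = _fill_mean_mode(table)
    order = sorted(gaps, key=lambda v: int(gaps[v].sum()))
    seeds = iter(np.random.SeedSequence(cfg.seed).generate_state(cfg.max_iter * len(order) * 2))
    n = len(table)
    max_samples = cfg.max_samples
    if max_samples is not None and n * max_samples < 30:
        max_samples = None  # too small for per-tree subsampling

    cont_vars = [v for v in order if v == "age"]
    cat_vars = [v for v in order if v != "age"]
    prev_cont = prev_cat = None
    snapshot = filled.copy()

    for iteration in range(cfg.max_iter):
        before = filled.copy()
        for var in order:
            X = _encode_predictors(filled, variables, exclude=var)
            obs = ~gaps[var]
            common = dict(
                n_estimators=cfg.n_trees,
                min_samples_leaf=cfg.min_leaf,
                max_samples=max_samples,
                max_features="sqrt",
                n_jobs=1,
                random_state=int(next(seeds)),
            )
            if var == "age":
                forest = RandomForestRegressor(**common)
                forest.fit(X[obs], filled.loc[obs, "age"].to_numpy(dtype=float))
                filled.loc[gaps[var], "age"] = forest.predict(X[gaps[var]])
            else:
                domain = schema.DOMAINS[var]
                mapping = {lv: i for i, lv in enumerate(domain)}
                y = filled.loc[obs, var].map(mapping).to_numpy(dtype=int)
                forest = RandomForestClassifier(**common)
                forest.fit(X[obs], y)
                pred = forest.predict(X[gaps[var]])
                filled.loc[gaps[var], var] = np.array(domain, dtype=object)[pred]

        cont_d = None
        if cont_vars:
            new = filled.loc[gaps["age"], "age"].to_numpy(dtype=float)
            old = before.loc[gaps["age"], "age"].to_numpy(dtype=float)
            denom = float(np.sum(new**2))
            cont_d = float(np.sum((new - old) ** 2) / denom) if denom > 0 else 0.0
        cat_d = None
        if cat_vars:
            changed = total = 0
            for var in cat_vars:
                changed += int((filled.loc[gaps[var], var] != before.loc[gaps[var], var]).sum())
                total += int(gaps[var].sum())
            cat_d = changed / total

        cont_up = cont_d is None or (prev_cont is not None and cont_d > prev_cont)
        cat_up = cat_d is None or (prev_cat is not None and cat_d > prev_cat)
        have_history = (prev_cont is not None) or (prev_cat is not None)
        if have_history and cont_up and cat_up:
            return ImputedCohort(table=snapshot, method="mf", mask=mask)
        snapshot = filled.copy()
        prev_cont, prev_cat = cont_d, cat_d
        if cat_d == 0 and (cont_d is None or cont_d == 0):
            break  # fixed point

    else:
        logger.warning("missforest did not converge within max_iter=%d", cfg.max_iter)
    return ImputedCohort(table=filled, method="mf", mask=mask)
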