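"""MAR amputation: introduce missing values into a complete cohort.

Each case receives one candidate pattern (which single variable *could* go
missing) by multinomial draw, then missingness fires Bernoulli with a
probability driven by fully observed covariates through a logistic link:

    p_i = expit(intercept_shift + sum_j w_j * z_ij)

where ``z`` are centred/scaled codings of the pattern's predictors. The
per-pattern intercept shift is solved by monotone root-finding so the expected
overall missing proportion equals the target. The candidate-then-Bernoulli
scheme guarantees at most one missing cell per row, and the probability never
depends on the value being removed (MAR by construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from . import schema

__all__ = [
    "AmputationSpec",
    "assign_patterns",
    "missingness_probability",
    "ampute",
    "DEFAULT_PATTERN_FREQS",
    "DEFAULT_WEIGHTS",
]

#: Relative frequency of each missingness pattern; age missingness is the
#: least frequent of the three.
DEFAULT_PATTERN_FREQS: dict[str, float] = {"age": 0.2, "witness_type": 0.4, "call_time": 0.4}

#: Predictor weights per pattern: age missingness depends on gender, witness
#: type and call time missingness on arrest location (more likely in public).
DEFAULT_WEIGHTS: dict[str, dict[str, float]] = {
    "age": {"gender": 1.0},
    "witness_type": {"arrest_location": 1.0},
    "call_time": {"arrest_location": 1.0},
}

#: Numeric codings of the fully observed predictors (before standardisation).
_PREDICTOR_CODES: dict[str, dict[str, float]] = {
    "gender": {"female": 0.0, "male": 1.0},
    "arrest_location": {"home": 0.0, "public": 1.0},
    "first_rhythm": {"non_shockable": 0.0, "shockable": 1.0, "unknown": 2.0},
}


@dataclass
class AmputationSpec:
    """Definition of the MAR amputation mechanism."""

    proportion: float
    pattern_freqs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PATTERN_FREQS))
    weights: dict[str, dict[str, float]] = field(
        default_factory=lambda: {p: dict(w) for p, w in DEFAULT_WEIGHTS.items()}
    )
    mechanism: str = "MAR"

    def __post_init__(self) -> None:
        if not (0.0 < self.proportion < 1.0):
            raise ValueError(f"proportion must be in (0, 1), got {self.proportion}")
        unknown = set(self.pattern_freqs) - set(schema.AMPUTABLE)
        if unknown:
            raise ValueError(f"unknown patterns in pattern_freqs: {sorted(unknown)}")
        freqs = np.array([self.pattern_freqs.get(p, 0.0) for p in schema.AMPUTABLE])
        if (freqs < 0).any():
            raise ValueError("pattern_freqs must be nonnegative")
        if abs(freqs.sum() - 1.0) > 1e-12:
            raise ValueError(f"pattern_freqs must sum to 1, got {freqs.sum()!r}")
        for pattern, wmap in self.weights.items():
            if pattern not in schema.AMPUTABLE:
                raise ValueError(f"weights given for unknown pattern {pattern!r}")
            bad = set(wmap) - set(schema.FULLY_OBSERVED)
            if bad:
                raise ValueError(
                    f"pattern {pattern!r} weights reference non-fully-observed "
                    f"predictors {sorted(bad)}; allowed: {list(schema.FULLY_OBSERVED)}"
                )
        if self.mechanism != "MAR":
            raise ValueError(f"only the MAR mechanism is supported, got {self.mechanism!r}")


def assign_patterns(table: pd.DataFrame, spec: AmputationSpec, seed: int = 0) -> pd.Series:
    """Assign one candidate missingness pattern to every case (multinomial)."""
    rng = np.random.default_rng(seed)
    patterns = np.array(schema.AMPUTABLE, dtype=object)
    probs = np.array([spec.pattern_freqs.get(p, 0.0) for p in schema.AMPUTABLE])
    draw = rng.choice(patterns, size=len(table), p=probs)
    return pd.Series(draw, index=table.index, name="candidate_pattern")


def _pattern_scores(table: pd.DataFrame, pattern: str, spec: AmputationSpec) -> np.ndarray:
    """Weighted sum of centred/scaled predictor codings for one pattern."""
    wmap = spec.weights.get(pattern, {})
    scores = np.zeros(len(table))
    for predictor, weight in wmap.items():
        codes = _PREDICTOR_CODES.get(predictor)
        if codes is None:
            raise ValueError(
                f"unknown predictor {predictor!r}; allowed: {list(_PREDICTOR_CODES)}"
            )
        x = table[predictor].map(codes).to_numpy(dtype=float)
        sd = x.std()
        z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
        scores += weight * z
    return scores


def missingness_probability(
    table: pd.DataFrame,
    pattern: str,
    spec: AmputationSpec,
    intercept_shift: float = 0.0,
) -> np.ndarray:
    """Per-case probability of the pattern firing, given an intercept shift.

    Depends only on fully observed covariates — never on the value that would
    be removed.
    """
    if pattern not in schema.AMPUTABLE:
        raise ValueError(f"unknown pattern {pattern!r}")
    return expit(intercept_shift + _pattern_scores(table, pattern, spec))


def _solve_intercept_shift(scores: np.ndarray, target: float) -> float:
    def f(a: float) -> float:
        return float(np.mean(expit(a + scores))) - target

    return float(brentq(f, -700.0, 700.0, xtol=1e-12, rtol=8.9e-16))


def ampute(
    table: pd.DataFrame,
    spec: AmputationSpec,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Introduce MAR missingness; returns (amputed table, missingness mask).

    The mask is a ``case_id, pattern`` frame where ``pattern`` is ``none`` or
    the name of the single variable removed from that row.
    """
    if not schema.is_complete(table):
        raise ValueError("ampute requires a complete cohort")
    rng = np.random.default_rng(seed)

    candidates = assign_patterns(table, spec, seed=int(rng.integers(0, 2**32)))
    u = rng.random(len(table))

    amputed = table.copy()
    mask = pd.Series("none", index=table.index, dtype=object)
    for pattern in schema.AMPUTABLE:
        sel = (candidates == pattern).to_numpy()
        if not sel.any():
            continue
        scores = _pattern_scores(table, pattern, spec)
        shift = _solve_intercept_shift(scores, spec.proportion)
        p = expit(shift + scores)
        fired = sel & (u < p)
        if fired.any():
            amputed.loc[fired, pattern] = np.nan
            mask[fired] = pattern

    mask_frame = pd.DataFrame({"case_id": table["case_id"].to_numpy(), "pattern": mask.to_numpy()})
    return amputed, mask_frame
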