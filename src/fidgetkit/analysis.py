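"""Trial-grouped comparisons, median splits, rating-scale totals and
six-predictor linear-model correlations.

Correct-vs-incorrect and Q1-vs-Q4 comparisons are paired (each
participant contributes both conditions); participants lacking a
condition are dropped from that comparison only.  No multiple-testing
correction is applied; reports carry the number of comparisons run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from fidgetkit.metrics import FidgetMetrics
from fidgetkit.rt import ExGaussianParams
from fidgetkit.task import TrialEvent

#: legal total ranges per scale
SCALE_RANGES = {"baars": (18, 72), "bdefs_sec5": (13, 52), "ari": (0, 12)}

#: (item count, per-item minimum, per-item maximum) per scale
SCALE_ITEMS = {"baars": (18, 1, 4), "bdefs_sec5": (13, 1, 4), "ari": (6, 0, 2)}

SPLIT_SCHEMES = ("correctness", "trial_type", "quartile")
MEDIAN_KEYS = ("mu", "sigma", "tau")


@dataclass(frozen=True)
class ParticipantRecord:
    """Per-participant aggregates feeding the cohort analyses."""

    participant_id: str
    fidget_arm: FidgetMetrics
    fidget_leg: FidgetMetrics
    rt_params: ExGaussianParams
    flanker_total: int
    baars: float
    bdefs_sec5: float
    ari: float
    digit_span: float
    stroop_color: float
    stroop_color_word: float
    fidget_subsets: dict | None = None

    def __post_init__(self) -> None:
        for scale, (lo, hi) in SCALE_RANGES.items():
            val = getattr(self, scale)
            if not (lo <= val <= hi):
                raise ValueError(f"{scale} total {val} outside legal range [{lo}, {hi}]")

    def predictor_vector(self) -> np.ndarray:
        """The six fidget predictors: arm then leg, each
        (n_fidgets, variability, intensity)."""
        return np.array(
            [
                self.fidget_arm.number_of_fidgets,
                self.fidget_arm.fidget_time_variability,
                self.fidget_arm.fidget_intensity,
                self.fidget_leg.number_of_fidgets,
                self.fidget_leg.fidget_time_variability,
                self.fidget_leg.fidget_intensity,
            ],
            dtype=float,
        )


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    t_value: float
    p_value: float
    paired: bool
    zero_variance: bool = False


@dataclass(frozen=True)
class LinearFitResult:
    coefficients: np.ndarray  # intercept first, then the 6 predictors
    r: float
    r_squared: float
    p_value: float
    n: int
    rank_deficient: bool = False


def scale_total(items: Sequence[float], scale: str) -> int:
    """Sum of item scores after validating count and per-item range."""
    if scale not in SCALE_ITEMS:
        raise ValueError(f"unknown scale {scale!r}")
    count, lo, hi = SCALE_ITEMS[scale]
    items = list(items)
    if len(items) != count:
        raise ValueError(f"{scale} expects {count} items, got {len(items)}")
    for v in items:
        if not (lo <= v <= hi) or v != int(v):
            raise ValueError(f"{scale} item {v} outside legal range [{lo}, {hi}]")
    return int(sum(items))


def split_trials(events: list[TrialEvent], scheme: str) -> dict[str, list[TrialEvent]]:
    """Label trial subsets by correctness, trial type, or first/last
    quarter of the presentation order.

    Omissions belong to neither correctness group.  Quartile subsets are
    the first and last quarter (30 trials each for a 120-trial session).
    """
    if scheme not in SPLIT_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    ordered = sorted(events, key=lambda e: e.onset_ms)
    if scheme == "correctness":
        return {
            "correct": [e for e in ordered if e.correct],
            "incorrect": [e for e in ordered if not e.correct and not e.omitted],
        }
    if scheme == "trial_type":
        types = sorted({e.trial_type for e in ordered})
        return {t: [e for e in ordered if e.trial_type == t] for t in types}
    q = len(ordered) // 4
    if q == 0:
        raise ValueError("too few trials for a quartile split")
    return {"Q1": ordered[:q], "Q4": ordered[-q:]}


def compare_groups(a: Sequence[float], b: Sequence[float], paired: bool) -> GroupComparison:
    """Paired t on differences, or Welch t for independent groups;
    two-sided p from the t distribution.

    Zero variance with identical means yields t = 0, p = 1; zero
    variance with differing means is flagged as an infinite t.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired and a.size != b.size:
        raise ValueError("paired comparison requires equal-length groups")
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")

    if paired:
        d = a - b
        n = d.size
        sd = d.std(ddof=1)
        if sd == 0:
            t = 0.0 if d.mean() == 0 else np.inf * np.sign(d.mean())
            p = 1.0 if d.mean() == 0 else 0.0
            zero_var = True
        else:
            t = d.mean() / (sd / np.sqrt(n))
            p = 2 * stats.t.sf(abs(t), df=n - 1)
            zero_var = False
    else:
        va, vb = a.var(ddof=1), b.var(ddof=1)
        if va == 0 and vb == 0:
            t = 0.0 if a.mean() == b.mean() else np.inf * np.sign(a.mean() - b.mean())
            p = 1.0 if a.mean() == b.mean() else 0.0
            zero_var = True
        else:
            se = np.sqrt(va / a.size + vb / b.size)
            t = (a.mean() - b.mean()) / se
            df = se**4 / (
                (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
            )
            p = 2 * stats.t.sf(abs(t), df=df)
            zero_var = False
    return GroupComparison(
        group_a="a",
        group_b="b",
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        n_a=int(a.size),
        n_b=int(b.size),
        t_value=float(t),
        p_value=float(min(p, 1.0)) if np.isfinite(p) else 0.0,
        paired=paired,
        zero_variance=zero_var,
    )


def median_split(
    cohort: list[ParticipantRecord], key: str
) -> tuple[list[ParticipantRecord], list[ParticipantRecord]]:
    """Split a cohort at the median of an ex-Gaussian parameter.

    Values strictly below the median go low, values at or above go high;
    ties straddling the median therefore land high, and a warning records
    any resulting imbalance.
    """
    if key not in MEDIAN_KEYS:
        raise ValueError(f"key must be one of {MEDIAN_KEYS}")
    if len(cohort) < 4:
        raise ValueError("cohort too small for a median split")
    values = np.array([getattr(p.rt_params, key) for p in cohort])
    med = float(np.median(values))
    low = [p for p, v in zip(cohort, values) if v < med]
    high = [p for p, v in zip(cohort, values) if v >= med]
    if abs(len(low) - len(high)) > len(cohort) % 2:
        warnings.warn(
            f"median ties produce unbalanced groups ({len(low)} low / {len(high)} high)",
            stacklevel=2,
        )
    return low, high


def fit_linear_model(predictors: np.ndarray, response: Sequence[float]) -> LinearFitResult:
    """Ordinary least squares of a response on six predictors.

    R = sqrt(1 - RSS/TSS); the overall p comes from the F statistic with
    (k, n - k - 1) degrees of freedom.  Rank deficiency (perfectly
    collinear predictors) is flagged, not fatal.
    """
    X = np.asarray(predictors, dtype=float)
    y = np.asarray(response, dtype=float)
    if X.ndim != 2:
        raise ValueError("predictors must be a 2-d array (n, k)")
    n, k = X.shape
    if n <= k + 1:
        raise ValueError(f"need n > {k + 1} observations for {k} predictors")
    design = np.column_stack([np.ones(n), X])
    coefs, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    rank_deficient = rank < k + 1
    if rank_deficient:
        warnings.warn("rank-deficient predictor matrix", stacklevel=2)
    fitted = design @ coefs
    rss = float(np.sum((y - fitted) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if tss == 0 else max(0.0, 1.0 - rss / tss)
    df_model, df_resid = rank - 1, n - rank
    if r2 >= 1.0 or df_resid <= 0:
        p = 0.0
    else:
        f_stat = (r2 / df_model) / ((1 - r2) / df_resid)
        p = float(stats.f.sf(f_stat, df_model, df_resid))
    return LinearFitResult(
        coefficients=coefs,
        r=float(np.sqrt(r2)),
        r_squared=float(r2),
        p_value=p,
        n=n,
        rank_deficient=rank_deficient,
    )


def cohort_predictor_matrix(cohort: list[ParticipantRecord]) -> np.ndarray:
    """Stack the six fidget predictors over a cohort."""
    return np.vstack([p.predictor_vector() for p in cohort])


def scale_correlations(cohort: list[ParticipantRecord]) -> dict[str, LinearFitResult]:
    """Fit each rating-scale total on the six fidget predictors."""
    X = cohort_predictor_matrix(cohort)
    return {
        scale: fit_linear_model(X, [getattr(p, scale) for p in cohort])
        for scale in SCALE_RANGES
    }
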