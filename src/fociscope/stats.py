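"""Association statistics: rank tests, Spearman CI, Cox PH, Bonferroni.

The battery mirrors the original analysis: paired Wilcoxon signed rank
for within-subject contrasts, Spearman correlation with a Fisher-z 95% CI
for continuous covariates, Wilcoxon rank sum for gender, Kruskal-Wallis
for diagnosis subgroup, and a Cox proportional-hazards model (Efron ties,
adjusted for age at onset and diagnosis subgroup) for survival after
onset.  Each family of similar tests is Bonferroni-corrected; a family of
13 tests at alpha 0.05 yields the displayed threshold 0.0038 and a family
of 14 yields 0.0036.

Small-sample rank tests are exact: the full permutation null is built by
dynamic programming over (doubled, tie-safe) ranks, which is equivalent
to complete enumeration of sign assignments / group labelings.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatResult",
    "CoxResult",
    "AssociationResult",
    "paired_wilcoxon",
    "ranksum",
    "kruskal_wallis",
    "spearman_ci",
    "cox_model",
    "bonferroni_threshold",
    "display_threshold",
    "default_families",
    "run_association_suite",
]


@dataclasses.dataclass
class StatResult:
    estimate: float
    p_value: float
    ci_low: float | None = None
    ci_high: float | None = None
    n: int = 0
    method: str = ""


# ---------------------------------------------------------------------------
# exact rank-test machinery
# ---------------------------------------------------------------------------

def _doubled_ranks(values: np.ndarray) -> np.ndarray:
    """Mid-ranks times two -- always integral, even with ties."""
    doubled = np.round(2 * sps.rankdata(values)).astype(np.int64)
    return doubled


def _signed_rank_null(doubled: np.ndarray) -> np.ndarray:
    """Counts of each doubled signed-rank sum over all 2^n sign choices."""
    total = int(doubled.sum())
    dist = np.zeros(total + 1, dtype=np.float64)
    dist[0] = 1.0
    for d in doubled:
        shifted = np.zeros_like(dist)
        shifted[d:] = dist[: total + 1 - d]
        dist = dist + shifted
    return dist


def paired_wilcoxon(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Two-sided paired Wilcoxon signed rank test.

    Incomplete pairs and zero differences are dropped.  With 25 or fewer
    effective pairs the p-value comes from the exact null (all sign
    assignments); above that a normal approximation with continuity
    correction and tie-safe variance is used.  All-zero differences give
    p = 1 with a warning.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    diff = x[ok] - y[ok]
    diff = diff[diff != 0]
    n = diff.size
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return StatResult(estimate=0.0, p_value=1.0, n=0, method="wilcoxon_signed_rank")
    if n < 3:
        raise ValueError("need at least 3 nonzero paired differences")
    doubled = _doubled_ranks(np.abs(diff))
    w2 = int(doubled[diff > 0].sum())  # doubled positive-rank sum
    statistic = w2 / 2.0
    if n <= 25:
        dist = _signed_rank_null(doubled)
        total = dist.sum()
        p_le = dist[: w2 + 1].sum() / total
        p_ge = dist[w2:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        mean = doubled.sum() / 4.0  # E[W+] with W+ = w2/2
        var = (doubled.astype(np.float64) ** 2).sum() / 16.0
        z = (statistic - mean - 0.5 * np.sign(statistic - mean)) / math.sqrt(var)
        p = 2.0 * sps.norm.sf(abs(z))
    return StatResult(
        estimate=statistic, p_value=float(p), n=n, method="wilcoxon_signed_rank"
    )


def _ranksum_null(doubled: np.ndarray, n1: int) -> np.ndarray:
    """Counts of doubled rank sums over all C(N, n1) group labelings."""
    total = int(doubled.sum())
    dist = np.zeros((n1 + 1, total + 1), dtype=np.float64)
    dist[0, 0] = 1.0
    for d in doubled:
        # iterate sizes downward so each item is used at most once
        for k in range(n1 - 1, -1, -1):
            row = dist[k]
            nz = row.nonzero()[0]
            if nz.size:
                dist[k + 1, nz + d] += row[nz]
    return dist[n1]


def ranksum(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Two-sided Wilcoxon rank sum test (tie-corrected).

    Exact permutation null when the pooled sample has at most 20
    observations, normal approximation with continuity correction and tie
    correction otherwise.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([x, y])
    doubled = _doubled_ranks(pooled)
    w2 = int(doubled[:n1].sum())
    statistic = w2 / 2.0
    N = n1 + n2
    if N <= 20:
        dist = _ranksum_null(doubled, n1)
        total = dist.sum()
        p_le = dist[: w2 + 1].sum() / total
        p_ge = dist[w2:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        ranks = doubled / 2.0
        mean = n1 * (N + 1) / 2.0
        S = (ranks**2).sum()
        var = n1 * n2 / (N * (N - 1.0)) * (S - N * (N + 1.0) ** 2 / 4.0)
        if var <= 0:
            p = 1.0
        else:
            z = (statistic - mean - 0.5 * np.sign(statistic - mean)) / math.sqrt(var)
            p = 2.0 * sps.norm.sf(abs(z))
    return StatResult(estimate=statistic, p_value=float(p), n=N, method="ranksum")


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> StatResult:
    """Tie-corrected Kruskal-Wallis H with chi-square p-value."""
    cleaned = []
    for g in groups:
        arr = np.asarray(g, dtype=np.float64)
        arr = arr[~np.isnan(arr)]
        if arr.size == 0:
            raise ValueError("empty group in Kruskal-Wallis test")
        cleaned.append(arr)
    if len(cleaned) < 2:
        raise ValueError("need at least 2 groups")
    h, p = sps.kruskal(*cleaned)
    return StatResult(
        estimate=float(h),
        p_value=float(p),
        n=int(sum(a.size for a in cleaned)),
        method="kruskal_wallis",
    )


def spearman_ci(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Spearman correlation with Fisher-z 95% CI and t-approximation p.

    The coefficient is Pearson's r on mid-ranks (tie-safe).  The CI uses
    ``atanh(r) +/- 1.96 / sqrt(n - 3)``, capped at [-1, 1]; the p-value
    uses the Fieller-corrected z statistic ``atanh(r) * sqrt((n-3)/1.06)``.
    Constant inputs leave the correlation undefined (NaN estimate, p NaN).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 5:
        raise ValueError("Spearman needs at least 5 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return StatResult(
            estimate=float("nan"), p_value=float("nan"), n=n, method="spearman"
        )
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    r = float(np.corrcoef(rx, ry)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) > 1.0 - 1e-12:  # snap numerically perfect correlations
        r = math.copysign(1.0, r)
    if abs(r) == 1.0 or n <= 3:
        p = 0.0
    else:
        # Fieller-corrected Fisher z (variance 1.06/(n-3)): calibrated in the
        # far tail, where the plain t approximation is anticonservative
        z_stat = math.atanh(r) / math.sqrt(1.06 / (n - 3))
        p = 2.0 * sps.norm.sf(abs(z_stat))
    if abs(r) == 1.0 or n <= 3:
        lo, hi = r, r
    else:
        z = math.atanh(r)
        half = 1.959963984540054 / math.sqrt(n - 3)
        lo = math.tanh(z - half)
        hi = math.tanh(z + half)
    return StatResult(
        estimate=r,
        p_value=float(p),
        ci_low=max(-1.0, lo),
        ci_high=min(1.0, hi),
        n=n,
        method="spearman",
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CoxResult:
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    n_events: int
    converged: bool
    method: str = "cox_efron"


def cox_model(
    time: Sequence[float],
    event: Sequence[int],
    predictor: Sequence[float],
    covariates: pd.DataFrame | None = None,
    dichotomize: bool = True,
    min_events: int = 10,
) -> CoxResult:
    """Cox PH hazard ratio for a foci measurement against survival.

    By default the predictor is dichotomized at its in-sample median
    (high-burden vs low-burden); pass ``dichotomize=False`` for the
    continuous predictor.  Ties are handled with the Efron approximation
    and the partial likelihood maximized by Newton iterations (via
    lifelines).  Non-convergence or separation yields a flagged result
    with NaN estimates rather than an exception.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    time = np.asarray(time, dtype=np.float64)
    event = np.asarray(event, dtype=np.int64)
    predictor = np.asarray(predictor, dtype=np.float64)
    frame = pd.DataFrame({"time": time, "event": event, "predictor": predictor})
    if covariates is not None:
        cov = covariates.reset_index(drop=True)
        frame = pd.concat([frame.reset_index(drop=True), cov], axis=1)
    frame = frame.dropna()
    n_events = int(frame["event"].sum())
    if n_events < min_events:
        raise ValueError(f"need at least {min_events} events, got {n_events}")
    if dichotomize:
        cutoff = frame["predictor"].median()
        frame["predictor"] = (frame["predictor"] >= cutoff).astype(float)

    fitter = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(frame, duration_col="time", event_col="event")
    except (ConvergenceError, ValueError, np.linalg.LinAlgError):
        return CoxResult(
            hazard_ratio=float("nan"),
            ci_low=float("nan"),
            ci_high=float("nan"),
            p_value=float("nan"),
            n=len(frame),
            n_events=n_events,
            converged=False,
        )
    row = fitter.summary.loc["predictor"]
    return CoxResult(
        hazard_ratio=float(np.exp(row["coef"])),
        ci_low=float(np.exp(row["coef lower 95%"])),
        ci_high=float(np.exp(row["coef upper 95%"])),
        p_value=float(row["p"]),
        n=len(frame),
        n_events=n_events,
        converged=True,
    )


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold ``alpha / m`` (exact)."""
    if m < 1:
        raise ValueError("family size m must be >= 1")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    return alpha / m


def display_threshold(threshold: float) -> float:
    """Round a threshold to two significant figures for display."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return float(f"{threshold:.1e}")


# ---------------------------------------------------------------------------
# association grid
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class AssociationResult:
    """One cell of the association grid."""

    measurement: str
    stratum: str  # "region/population/probe"
    variable: str
    method: str
    estimate: float | None
    ci_low: float | None
    ci_high: float | None
    p_value: float | None
    family_size: int
    alpha: float
    significant_after_bonferroni: bool
    n: int = 0

    def __post_init__(self) -> None:
        if self.family_size < 1:
            raise ValueError("family_size must be >= 1")
        if (
            self.estimate is not None
            and self.ci_low is not None
            and self.ci_high is not None
            and not (math.isnan(self.estimate) or math.isnan(self.ci_low))
        ):
            if not (self.ci_low - 1e-9 <= self.estimate <= self.ci_high + 1e-9):
                raise ValueError("estimate must lie within its CI")
        if self.p_value is not None and not math.isnan(self.p_value):
            expected = self.p_value < self.alpha / self.family_size
            if self.significant_after_bonferroni != expected:
                raise ValueError("Bonferroni flag inconsistent with p and alpha/m")
        elif self.significant_after_bonferroni:
            raise ValueError("missing p-value cannot be significant")


CONTINUOUS_VARIABLES = (
    "age_onset_years",
    "age_death_years",
    "repeat_length",
    "transcripts_total",
    "transcripts_v1",
    "transcripts_v2",
    "transcripts_v3",
    "transcripts_intron1a",
    "transcripts_intron1b",
    "polyGP",
    "polyGA",
)


def default_families() -> dict:
    """Default association families: 13 tests frontal, 14 cerebellar.

    The cerebellar family adds poly(GA) as the one extra association.
    """
    frontal = [v for v in CONTINUOUS_VARIABLES if v != "polyGA"] + [
        "gender",
        "diagnosis",
        "survival",
    ]
    cerebellum = list(CONTINUOUS_VARIABLES) + ["gender", "diagnosis", "survival"]
    return {
        "alpha": 0.05,
        "frontal_cortex": {"m": len(frontal), "variables": frontal},
        "cerebellum": {"m": len(cerebellum), "variables": cerebellum},
    }


def _one_association(
    variable: str,
    values: pd.Series,
    clinical: pd.DataFrame,
    alpha: float,
    m: int,
    measurement: str,
    stratum: str,
) -> AssociationResult:
    def missing() -> AssociationResult:
        return AssociationResult(
            measurement=measurement,
            stratum=stratum,
            variable=variable,
            method="missing",
            estimate=None,
            ci_low=None,
            ci_high=None,
            p_value=None,
            family_size=m,
            alpha=alpha,
            significant_after_bonferroni=False,
            n=0,
        )

    def build(method, estimate, ci_low, ci_high, p, n):
        sig = bool(p is not None and not math.isnan(p) and p < alpha / m)
        return AssociationResult(
            measurement=measurement,
            stratum=stratum,
            variable=variable,
            method=method,
            estimate=estimate,
            ci_low=ci_low,
            ci_high=ci_high,
            p_value=p,
            family_size=m,
            alpha=alpha,
            significant_after_bonferroni=sig,
            n=n,
        )

    if variable == "gender":
        groups = [
            values[clinical["gender"] == level].dropna().to_numpy()
            for level in ("male", "female")
        ]
        if any(g.size < 2 for g in groups):
            return missing()
        res = ranksum(groups[0], groups[1])
        return build(res.method, res.estimate, None, None, res.p_value, res.n)

    if variable == "diagnosis":
        groups = [
            grp.dropna().to_numpy()
            for _, grp in values.groupby(clinical["diagnosis"])
            if grp.dropna().size >= 2
        ]
        if len(groups) < 2:
            return missing()
        res = kruskal_wallis(groups)
        return build(res.method, res.estimate, None, None, res.p_value, res.n)

    if variable == "survival":
        keep = clinical[["survival_years", "event_indicator", "age_onset_years"]].copy()
        keep["predictor"] = values
        dummies = pd.get_dummies(
            clinical["diagnosis"], prefix="dx", drop_first=True, dtype=float
        )
        covariates = pd.concat([keep[["age_onset_years"]], dummies], axis=1)
        complete = keep.dropna(subset=["survival_years", "predictor"])
        if len(complete) < 10:
            return missing()
        try:
            res = cox_model(
                keep["survival_years"],
                keep["event_indicator"].fillna(0),
                keep["predictor"],
                covariates=covariates,
            )
        except ValueError:
            return missing()
        if not res.converged:
            return missing()
        return build(
            res.method,
            res.hazard_ratio,
            res.ci_low,
            res.ci_high,
            res.p_value,
            res.n,
        )

    # continuous covariate -> Spearman
    cov = pd.to_numeric(clinical[variable], errors="coerce")
    pair = pd.DataFrame({"x": cov, "y": values}).dropna()
    if len(pair) < 5:
        return missing()
    res = spearman_ci(pair["x"], pair["y"])
    if math.isnan(res.estimate):
        return missing()
    return build(
        res.method, res.estimate, res.ci_low, res.ci_high, res.p_value, res.n
    )


def run_association_suite(
    summaries: pd.DataFrame,
    clinical: pd.DataFrame,
    families: Mapping | None = None,
) -> list:
    """Run the full association grid over every stratum and measurement.

    ``summaries`` is a per-subject frame with ``subject_id, region,
    population, probe`` and the five measurement columns; ``clinical``
    follows the SubjectClinical schema.  Family sizes and variable lists
    come from ``families`` (defaults: 13 frontal, 14 cerebellar tests at
    alpha 0.05).  Missing covariates are dropped pairwise, never imputed.
    """
    from .metrics import MEASUREMENTS

    config = dict(default_families())
    if families:
        config.update(families)
    alpha = config["alpha"]
    results: list[AssociationResult] = []
    for (region, population, probe), grp in summaries.groupby(
        ["region", "population", "probe"], sort=True
    ):
        if region not in config:
            raise ValueError(f"no family configured for region {region!r}")
        family = config[region]
        m = int(family["m"])
        stratum = f"{region}/{population}/{probe}"
        merged = grp.merge(clinical, on="subject_id", how="inner", validate="1:1")
        for measurement in MEASUREMENTS:
            values = pd.to_numeric(merged[measurement], errors="coerce")
            for variable in family["variables"]:
                if variable not in ("gender", "diagnosis", "survival") and (
                    variable not in merged.columns
                ):
                    raise ValueError(f"unknown variable {variable!r} in family config")
                results.append(
                    _one_association(
                        variable, values, merged, alpha, m, measurement, stratum
                    )
                )
    return results
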