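"""Per-subject RNA-foci outcome measurements and concordance validation.

Five outcomes are computed from the per-cell focus counts of one
(subject, region, cell population, probe) stratum: the fraction of
foci-positive cells, the mean count over all cells, the mean count over
positive cells, the maximum count, and the total count.  Cells are pooled
across a subject's fields before measuring, which makes the measurements
invariant to how cells are split across fields.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import spearman_ci

logger = logging.getLogger(__name__)

__all__ = [
    "SampleFociSummary",
    "summarize",
    "aggregate_subject",
    "concordance",
    "build_table2",
    "MEASUREMENTS",
]

MEASUREMENTS = (
    "pct_positive",
    "mean_foci_all",
    "mean_foci_pos",
    "max_foci",
    "total_foci",
)


@dataclasses.dataclass
class SampleFociSummary:
    """The five foci measurements for one subject/stratum."""

    subject_id: str
    region: str
    population: str
    probe: str
    n_cells: int
    n_positive: int
    pct_positive: float
    mean_foci_all: float
    mean_foci_pos: float | None  # None when no positive cells
    max_foci: int
    total_foci: int

    def __post_init__(self) -> None:
        if self.n_positive > self.n_cells:
            raise ValueError("n_positive cannot exceed n_cells")
        if not math.isclose(self.pct_positive, self.n_positive / self.n_cells):
            raise ValueError("pct_positive != n_positive / n_cells")
        if not math.isclose(self.mean_foci_all, self.total_foci / self.n_cells):
            raise ValueError("mean_foci_all != total_foci / n_cells")
        if self.n_positive > 0:
            if self.mean_foci_pos is None or not math.isclose(
                self.mean_foci_pos, self.total_foci / self.n_positive
            ):
                raise ValueError("mean_foci_pos != total_foci / n_positive")
            if self.mean_foci_pos + 1e-12 < self.mean_foci_all:
                raise ValueError("mean_foci_pos must be >= mean_foci_all")
        elif self.mean_foci_pos is not None:
            raise ValueError("mean_foci_pos must be missing when no positive cells")
        if self.max_foci > self.total_foci:
            raise ValueError("max_foci cannot exceed total_foci")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def summarize(
    counts: Sequence[int],
    subject_id: str = "",
    region: str = "frontal_cortex",
    population: str = "all_cells",
    probe: str = "sense",
) -> SampleFociSummary:
    """Compute the five measurements from per-cell counts.

    An empty count vector is an error; a stratum with no positive cells
    reports ``mean_foci_pos`` as missing (never zero).
    """
    arr = np.asarray(counts, dtype=np.int64)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty count vector")
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    n = int(arr.size)
    n_pos = int((arr > 0).sum())
    total = int(arr.sum())
    return SampleFociSummary(
        subject_id=subject_id,
        region=region,
        population=population,
        probe=probe,
        n_cells=n,
        n_positive=n_pos,
        pct_positive=n_pos / n,
        mean_foci_all=total / n,
        mean_foci_pos=total / n_pos if n_pos > 0 else None,
        max_foci=int(arr.max()),
        total_foci=total,
    )


def aggregate_subject(
    field_counts: Mapping[str, Sequence[int]] | pd.DataFrame,
    subject_id: str = "",
    region: str = "frontal_cortex",
    population: str = "all_cells",
    probe: str = "sense",
) -> SampleFociSummary:
    """Pool a subject's cells across fields, then measure.

    Accepts either a mapping ``field_id -> per-cell counts`` or a frame
    with ``field_id, nucleus_id, foci_count`` columns.  Duplicate
    ``(field_id, nucleus_id)`` pairs are an error.
    """
    if isinstance(field_counts, pd.DataFrame):
        dup = field_counts.duplicated(subset=["field_id", "nucleus_id"])
        if dup.any():
            bad = field_counts.loc[dup, ["field_id", "nucleus_id"]].iloc[0]
            raise ValueError(
                f"duplicate cell: field {bad.field_id!r} nucleus {bad.nucleus_id}"
            )
        pooled = field_counts["foci_count"].to_numpy()
    else:
        if not field_counts:
            raise ValueError("no fields to aggregate")
        pooled = np.concatenate(
            [np.asarray(v, dtype=np.int64) for v in field_counts.values()]
        )
    return summarize(
        pooled,
        subject_id=subject_id,
        region=region,
        population=population,
        probe=probe,
    )


def concordance(
    auto_counts: Sequence[float], reference_counts: Sequence[float]
) -> tuple:
    """Spearman rank correlation between automated and reference totals.

    Requires at least 5 pairs; a constant vector leaves the correlation
    undefined and is reported as ``(nan, nan)``.
    """
    x = np.asarray(auto_counts, dtype=np.float64)
    y = np.asarray(reference_counts, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    if x.size < 5:
        raise ValueError("concordance needs at least 5 paired fields")
    res = spearman_ci(x, y)
    return res.estimate, res.p_value


def _quantiles(values: np.ndarray) -> tuple:
    # linear interpolation (type-7), the default of the original analysis stack
    q25, q50, q75 = np.percentile(values, [25, 50, 75])
    return float(q50), float(q25), float(q75)


def build_table2(summaries: Iterable[SampleFociSummary]) -> pd.DataFrame:
    """Cohort medians and IQRs per (region, population, probe) stratum.

    One output row per stratum and measurement with ``median, q25, q75``
    and the subject count; strata with no subjects are omitted with a
    warning, strata with fewer than 3 subjects raise.
    """
    frame = pd.DataFrame([s.as_dict() for s in summaries])
    if frame.empty:
        raise ValueError("no summaries supplied")
    rows = []
    for (region, population, probe), grp in frame.groupby(
        ["region", "population", "probe"], sort=True
    ):
        if len(grp) < 3:
            raise ValueError(
                f"stratum ({region}, {population}, {probe}) has fewer than 3 subjects"
            )
        for measurement in MEASUREMENTS:
            values = grp[measurement].dropna().to_numpy(dtype=np.float64)
            if values.size == 0:
                logger.warning(
                    "stratum (%s, %s, %s) measurement %s empty; row omitted",
                    region,
                    population,
                    probe,
                    measurement,
                )
                continue
            median, q25, q75 = _quantiles(values)
            rows.append(
                dict(
                    region=region,
                    population=population,
                    probe=probe,
                    measurement=measurement,
                    median=median,
                    q25=q25,
                    q75=q75,
                    n_subjects=int(values.size),
                )
            )
    return pd.DataFrame(rows)
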