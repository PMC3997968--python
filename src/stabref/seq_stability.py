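"""Sequencing-side screen for stably expressed miRNAs.

A small-RNA-seq count table is normalized to a common library size,
log2-transformed with a pseudocount, and every designated stress-vs-control
sample pair is compared by fitting a regression line with slope fixed at 1
through the paired log2 expression values.  The intercept of that line
absorbs any residual library-size bias between the two samples; each
miRNA's residual is its library-bias-corrected log2 fold change.  A miRNA
is called stable for a condition when the percent variation implied by its
residuals stays at or below a threshold (default 7%) in every comparison of
the group AND its normalized abundance clears a floor (default 500 reads)
in every sample of the group.  Stable sets from several conditions are then
intersected to find condition-independent reference candidates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RawCountMatrix",
    "NormalizedCountMatrix",
    "SlopeOneFit",
    "StabilityReport",
    "ConditionIntersection",
    "normalize_counts",
    "fit_slope1",
    "pairwise_fold_change",
    "percent_variation",
    "direct_percent_variation",
    "filter_stable",
    "intersect_conditions",
    "tier_by_abundance",
]


@dataclass(frozen=True)
class RawCountMatrix:
    """miRNA x sample read counts as produced by a small-RNA quantifier.

    Counts are non-negative reals: quantifiers may emit fractional counts
    for multi-mapping reads, and supplementary tables printed with decimal
    commas parse to floats.
    """

    counts: pd.DataFrame  # index: miRNA ids, columns: sample ids

    def __post_init__(self) -> None:
        c = self.counts
        if c.shape[0] < 1 or c.shape[1] < 1:
            raise ValueError("count matrix needs at least one miRNA and one sample")
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate miRNA ids: {dups}")
        if c.columns.has_duplicates:
            dups = c.columns[c.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        vals = c.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("counts must be finite")
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass(frozen=True)
class NormalizedCountMatrix:
    """Library-size-normalized expression with a lazy log2 layer.

    ``linear`` holds normalized reads (per-sample totals all equal the mean
    raw total); the pseudocount enters only the log2 layer, immediately
    before the transform.
    """

    linear: pd.DataFrame
    pseudocount: float = 10.0

    def __post_init__(self) -> None:
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")

    @property
    def log2(self) -> pd.DataFrame:
        return np.log2(self.linear + self.pseudocount)

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.linear.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.linear.columns)


def normalize_counts(
    raw: RawCountMatrix | pd.DataFrame, pseudocount: float = 10.0
) -> NormalizedCountMatrix:
    """Normalize each sample to the mean total miRNA read count.

    Every sample's counts are divided by that sample's total and multiplied
    by the mean of all samples' totals, so per-sample totals become equal
    while the overall scale stays in read-count units.  The operation is
    idempotent and invariant to rescaling any single sample.

    Raises
    ------
    ValueError
        If any sample has a zero total (named in the message) or counts are
        invalid.
    """
    counts = raw.counts if isinstance(raw, RawCountMatrix) else RawCountMatrix(raw).counts
    totals = counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total miRNA reads: {list(zero.index)}")
    linear = counts.div(totals, axis=1) * totals.mean()
    return NormalizedCountMatrix(linear=linear, pseudocount=float(pseudocount))


@dataclass(frozen=True)
class SlopeOneFit:
    """Least-squares fit of y = x + b between two samples' log2 expression.

    The residuals (y - x - b) are the per-miRNA log2 fold changes after the
    intercept has soaked up the global library-size ratio; they sum to zero
    by construction.
    """

    sample_a: str
    sample_b: str
    intercept: float
    residuals: pd.Series

    def __post_init__(self) -> None:
        if not np.isfinite(self.intercept):
            raise ValueError("non-finite intercept")


def fit_slope1(
    x: Sequence[float] | pd.Series,
    y: Sequence[float] | pd.Series,
    sample_a: str = "x",
    sample_b: str = "y",
) -> SlopeOneFit:
    """Fit a slope-1 regression line y = x + b; b = mean(y - x).

    With the slope pinned at 1, the least-squares intercept is the mean
    difference, and each point's residual is its deviation from the line.
    """
    xs = pd.Series(np.asarray(x, dtype=float)) if not isinstance(x, pd.Series) else x.astype(float)
    ys = pd.Series(np.asarray(y, dtype=float)) if not isinstance(y, pd.Series) else y.astype(float)
    if len(xs) != len(ys):
        raise ValueError(f"length mismatch: {len(xs)} vs {len(ys)}")
    if len(xs) == 0:
        raise ValueError("empty input")
    if not (np.all(np.isfinite(xs.to_numpy())) and np.all(np.isfinite(ys.to_numpy()))):
        raise ValueError("non-finite values in input")
    diff = ys.to_numpy() - xs.to_numpy()
    intercept = float(diff.mean())
    index = ys.index if isinstance(y, pd.Series) else xs.index
    residuals = pd.Series(diff - intercept, index=index)
    return SlopeOneFit(sample_a=sample_a, sample_b=sample_b, intercept=intercept, residuals=residuals)


def pairwise_fold_change(
    norm: NormalizedCountMatrix, sample_a: str, sample_b: str
) -> SlopeOneFit:
    """Slope-1 fit of sample_b's log2 expression against sample_a's."""
    for s in (sample_a, sample_b):
        if s not in norm.linear.columns:
            raise KeyError(f"unknown sample id: {s!r}")
    log2 = norm.log2
    return fit_slope1(log2[sample_a], log2[sample_b], sample_a=sample_a, sample_b=sample_b)


def percent_variation(fit: SlopeOneFit | pd.Series | np.ndarray) -> pd.Series:
    """Percent expression variation implied by a log2 residual.

    A residual r corresponds to a 2^|r|-fold deviation from the slope-1
    line, i.e. (2^|r| - 1) x 100 percent; a residual of 1 (a 2-fold
    change) maps to 100%.
    """
    res = fit.residuals if isinstance(fit, SlopeOneFit) else pd.Series(fit)
    return (np.exp2(res.abs()) - 1.0) * 100.0


def direct_percent_variation(
    norm: NormalizedCountMatrix, sample_a: str, sample_b: str
) -> pd.Series:
    """Naive percent difference of normalized reads, |N_a - N_b| / N_b x 100."""
    a = norm.linear[sample_a]
    b = norm.linear[sample_b]
    with np.errstate(divide="ignore", invalid="ignore"):
        v = (a - b).abs() / b * 100.0
    return v.where(b > 0, np.inf)


@dataclass(frozen=True)
class StabilityReport:
    """Outcome of the stability filter for one condition group."""

    condition: str
    comparisons: tuple[tuple[str, str], ...]
    variation_pct: pd.Series  # max percent variation over the group's comparisons
    abundance_ok: pd.Series  # floor met in every sample of the group
    passed: frozenset[str]
    var_threshold_pct: float
    min_reads: float
    variation_metric: str = "residual"

    def to_frame(self) -> pd.DataFrame:
        """Per-miRNA table: variation%, abundance flag, passed flag."""
        return pd.DataFrame(
            {
                "variation_pct": self.variation_pct,
                "abundance_ok": self.abundance_ok,
                "passed": self.variation_pct.index.isin(sorted(self.passed)),
            }
        )

    def to_json_dict(self) -> dict:
        return {
            "condition": self.condition,
            "comparisons": [list(p) for p in self.comparisons],
            "var_threshold_pct": self.var_threshold_pct,
            "min_reads": self.min_reads,
            "variation_metric": self.variation_metric,
            "n_passed": len(self.passed),
            "passed": sorted(self.passed),
            "variation_pct": {k: float(v) for k, v in self.variation_pct.items()},
        }


def filter_stable(
    norm: NormalizedCountMatrix,
    comparisons: Sequence[tuple[str, str]],
    var_threshold_pct: float = 7.0,
    min_reads: float = 500.0,
    variation_metric: str = "residual",
    condition: str = "",
) -> StabilityReport:
    """Call stable miRNAs for a group of pairwise sample comparisons.

    A miRNA passes iff its maximum percent variation over all of the
    group's comparisons is <= ``var_threshold_pct`` AND its linear
    normalized reads are >= ``min_reads`` in every sample the group
    touches.  ``variation_metric`` selects the residual-implied variation
    (slope-1 fit, default) or the naive direct percent difference.
    """
    if len(comparisons) == 0:
        raise ValueError("empty comparison group")
    if variation_metric not in ("residual", "direct"):
        raise ValueError(f"unknown variation_metric: {variation_metric!r}")
    samples: list[str] = []
    for a, b in comparisons:
        for s in (a, b):
            if s not in norm.linear.columns:
                raise KeyError(f"unknown sample id in comparisons: {s!r}")
            if s not in samples:
                samples.append(s)

    per_comparison = []
    for a, b in comparisons:
        if variation_metric == "residual":
            per_comparison.append(percent_variation(pairwise_fold_change(norm, a, b)))
        else:
            per_comparison.append(direct_percent_variation(norm, a, b))
    variation = pd.concat(per_comparison, axis=1).max(axis=1)
    abundance_ok = (norm.linear[samples] >= min_reads).all(axis=1)
    passed = frozenset(variation.index[(variation <= var_threshold_pct) & abundance_ok])
    return StabilityReport(
        condition=condition,
        comparisons=tuple((a, b) for a, b in comparisons),
        variation_pct=variation,
        abundance_ok=abundance_ok,
        passed=passed,
        var_threshold_pct=float(var_threshold_pct),
        min_reads=float(min_reads),
        variation_metric=variation_metric,
    )


@dataclass(frozen=True)
class ConditionIntersection:
    """Stable sets per condition plus their full disjoint Venn partition.

    ``venn_partition`` maps a region label (condition names joined by '+')
    to the miRNAs stable in exactly those conditions; regions are disjoint
    and union to the union of all per-condition sets.
    """

    per_condition: dict[str, frozenset[str]]
    all_conditions: frozenset[str]
    venn_partition: dict[str, frozenset[str]]

    def to_json_dict(self) -> dict:
        return {
            "per_condition": {c: sorted(s) for c, s in self.per_condition.items()},
            "all_conditions": sorted(self.all_conditions),
            "venn_partition": {k: sorted(v) for k, v in self.venn_partition.items()},
        }


def intersect_conditions(
    reports: Mapping[str, StabilityReport | Iterable[str]],
) -> ConditionIntersection:
    """Intersect per-condition stable sets and build the Venn partition."""
    if len(reports) < 2:
        raise ValueError("need at least 2 conditions to intersect")
    per_condition = {
        c: frozenset(r.passed if isinstance(r, StabilityReport) else r)
        for c, r in reports.items()
    }
    names = sorted(per_condition)
    universe = frozenset().union(*per_condition.values())
    all_conditions = frozenset.intersection(*per_condition.values())
    venn: dict[str, frozenset[str]] = {}
    for k in range(1, len(names) + 1):
        for subset in itertools.combinations(names, k):
            inside = frozenset.intersection(*(per_condition[c] for c in subset))
            outside = frozenset().union(
                *(per_condition[c] for c in names if c not in subset), frozenset()
            )
            region = inside - outside
            venn["+".join(subset)] = region
    assert frozenset().union(*venn.values(), frozenset()) == universe
    return ConditionIntersection(
        per_condition=per_condition, all_conditions=all_conditions, venn_partition=venn
    )


def tier_by_abundance(
    norm: NormalizedCountMatrix,
    candidates: Iterable[str],
    boundaries: tuple[float, float] = (2000.0, 100000.0),
    samples: Sequence[str] | None = None,
) -> dict[str, frozenset[str]]:
    """Partition candidates into low/medium/high abundance tiers.

    Tiering uses the mean linear normalized reads over ``samples`` (all
    samples by default).  A value exactly on a boundary goes to the higher
    tier.
    """
    lo, hi = boundaries
    if not lo < hi:
        raise ValueError("boundaries must be strictly increasing")
    candidates = list(candidates)
    missing = [c for c in candidates if c not in norm.linear.index]
    if missing:
        raise KeyError(f"candidate miRNA(s) absent from matrix: {missing}")
    cols = list(samples) if samples is not None else list(norm.linear.columns)
    means = norm.linear.loc[candidates, cols].mean(axis=1)
    tiers = {
        "low": frozenset(means.index[means < lo]),
        "medium": frozenset(means.index[(means >= lo) & (means < hi)]),
        "high": frozenset(means.index[means >= hi]),
    }
    return tiers
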