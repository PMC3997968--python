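"""geNorm reference-gene stability analysis, implemented from scratch.

Given a matrix of positive relative quantities (genes x samples), the
stability measure M of gene j is the average, over every other candidate
k, of the standard deviation across samples of the log2 ratio
q_j / q_k.  A perfectly co-regulated (or perfectly stable) pair has a
constant log ratio and hence contributes zero.  Candidates are ranked by
stepwise exclusion: the gene with the highest M is removed and M is
recomputed until two genes — the jointly most stable pair — remain.

To decide how many reference genes suffice, normalization factors NF_n
(per-sample geometric means of the n best-ranked genes) are compared:
V(n/n+1) is the standard deviation across samples of
log2(NF_n / NF_{n+1}).  The smallest n with V below a cut-off
(conventionally 0.15) is recommended; when no V clears the cut-off all
candidates are recommended.  A per-gene coefficient of variation of the
NF-normalized quantities complements M (values < 0.2 are conventionally
considered stable), and M values are classified against a cut-off of 0.5
(strictly below passes).

All statistics use sample (n-1) standard deviations and log base 2, and
are invariant to positive rescaling of any gene or any sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .qpcr import RelativeQuantityMatrix

__all__ = [
    "StabilityRanking",
    "PairwiseVariationSeries",
    "m_values",
    "stepwise_rank",
    "normalization_factor",
    "pairwise_variation",
    "recommend_reference_count",
    "coefficient_of_variation",
    "classify_m",
]


def _as_quantity_frame(rq: RelativeQuantityMatrix | pd.DataFrame) -> pd.DataFrame:
    q = rq.quantities if isinstance(rq, RelativeQuantityMatrix) else rq
    vals = q.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)) or (vals <= 0).any():
        raise ValueError("relative quantities must be finite and positive")
    return q


def m_values(rq: RelativeQuantityMatrix | pd.DataFrame) -> pd.Series:
    """Per-gene geNorm stability measure M.

    M_j = mean over k != j of sd_i( log2(q_ij / q_ik) ), sample (n-1)
    standard deviation across samples i.  Lower M = more stable.
    """
    q = _as_quantity_frame(rq)
    if q.shape[0] < 2 or q.shape[1] < 2:
        raise ValueError("need at least 2 genes and 2 samples")
    log_q = np.log2(q.to_numpy(dtype=float))  # genes x samples
    # pairwise log-ratio SDs, vectorized over gene pairs
    diffs = log_q[:, None, :] - log_q[None, :, :]  # j x k x samples
    v = diffs.std(axis=2, ddof=1)  # j x k
    g = q.shape[0]
    m = (v.sum(axis=1)) / (g - 1)  # diagonal is zero
    return pd.Series(m, index=q.index, name="M")


@dataclass(frozen=True)
class StabilityRanking:
    """Stepwise-exclusion geNorm ranking.

    ``m_by_stage`` holds the M values computed at each stage (stage 0 =
    all genes); ``exclusion_order`` lists genes from least stable (removed
    first) onward; ``final_pair`` is the jointly most stable pair, which
    shares rank 1-2 and a single M value.
    """

    m_by_stage: tuple[pd.Series, ...]
    exclusion_order: tuple[str, ...]
    final_pair: tuple[str, str]

    @property
    def ranked(self) -> list[str]:
        """Genes best to worst: the final pair, then exclusions reversed."""
        return list(self.final_pair) + list(reversed(self.exclusion_order))

    @property
    def final_m(self) -> float:
        """The single M value shared by the final pair."""
        return float(self.m_by_stage[-1].iloc[0])


def stepwise_rank(rq: RelativeQuantityMatrix | pd.DataFrame) -> StabilityRanking:
    """Rank genes by iteratively excluding the least stable candidate.

    At each stage the gene with the highest M is removed and M recomputed
    on the remainder, until two genes are left.  Ties on M break by
    lexicographic gene id, making runs deterministic.  With exactly two
    genes the ranking degenerates: both form the final pair.
    """
    q = _as_quantity_frame(rq)
    if q.shape[0] < 2:
        raise ValueError("need at least 2 genes to rank")
    stages: list[pd.Series] = []
    excluded: list[str] = []
    current = q
    while True:
        m = m_values(current)
        stages.append(m)
        if current.shape[0] == 2:
            pair = tuple(sorted(current.index))
            break
        # highest M leaves; lexicographically smallest id wins ties
        worst_m = m.max()
        worst = sorted(m.index[m == worst_m])[0]
        excluded.append(worst)
        current = current.drop(index=worst)
    return StabilityRanking(
        m_by_stage=tuple(stages),
        exclusion_order=tuple(excluded),
        final_pair=pair,  # type: ignore[arg-type]
    )


def normalization_factor(
    rq: RelativeQuantityMatrix | pd.DataFrame, genes: Sequence[str]
) -> pd.Series:
    """Per-sample geometric mean of the given genes' relative quantities."""
    q = _as_quantity_frame(rq)
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene subset")
    missing = [g for g in genes if g not in q.index]
    if missing:
        raise KeyError(f"gene(s) absent from quantity matrix: {missing}")
    sub = np.log(q.loc[genes].to_numpy(dtype=float))
    return pd.Series(np.exp(sub.mean(axis=0)), index=q.columns, name="NF")


def recommend_reference_count(
    v_values: Mapping[int, float], n_genes: int, cutoff: float = 0.15
) -> int:
    """Smallest n with V(n/n+1) below the cut-off, else all ``n_genes``.

    Mirrors the conventional decision rule: once adding the (n+1)-th
    ranked gene no longer changes the normalization factor appreciably
    (V < cutoff), n genes suffice.  If no V clears the cut-off, all
    candidates are recommended (with a warning).
    """
    for n in sorted(v_values):
        if v_values[n] < cutoff:
            return int(n)
    warnings.warn(
        f"no pairwise variation below cut-off {cutoff}; "
        f"recommending all {n_genes} candidates",
        stacklevel=2,
    )
    return int(n_genes)


@dataclass(frozen=True)
class PairwiseVariationSeries:
    """V(n/n+1) series with the recommended number of reference genes."""

    v_values: dict[int, float]
    cutoff: float
    recommended_n: int


def pairwise_variation(
    rq: RelativeQuantityMatrix | pd.DataFrame,
    ranking: StabilityRanking | None = None,
    cutoff: float = 0.15,
) -> PairwiseVariationSeries:
    """Pairwise variation V(n/n+1) for n = 2 .. G-1 over the ranked genes.

    V(n/n+1) = sd across samples (n-1 denominator) of
    log2(NF_n / NF_{n+1}), where NF_n is built from the n best-ranked
    genes.
    """
    q = _as_quantity_frame(rq)
    g = q.shape[0]
    if g < 3:
        raise ValueError("need at least 3 genes for pairwise variation")
    if ranking is None:
        ranking = stepwise_rank(q)
    order = ranking.ranked
    v: dict[int, float] = {}
    for n in range(2, g):
        nf_n = normalization_factor(q, order[:n])
        nf_n1 = normalization_factor(q, order[: n + 1])
        ratio = np.log2(nf_n.to_numpy() / nf_n1.to_numpy())
        v[n] = float(np.std(ratio, ddof=1))
    return PairwiseVariationSeries(
        v_values=v, cutoff=float(cutoff),
        recommended_n=recommend_reference_count(v, g, cutoff),
    )


def coefficient_of_variation(
    rq: RelativeQuantityMatrix | pd.DataFrame, nf: pd.Series
) -> pd.Series:
    """Per-gene CV (sd/mean, linear scale) of NF-normalized quantities.

    The normalization factor should come from the recommended reference
    subset; a gene proportional to NF across samples has CV 0.
    """
    q = _as_quantity_frame(rq)
    if (nf.to_numpy(dtype=float) <= 0).any():
        raise ValueError("normalization factors must be positive")
    normalized = q.div(nf, axis=1)
    mean = normalized.mean(axis=1)
    assert (mean > 0).all()  # guaranteed by positive quantities
    return (normalized.std(axis=1, ddof=1) / mean).rename("CV")


def classify_m(m: Mapping[str, float] | pd.Series, cutoff: float = 0.5) -> pd.Series:
    """Stability call per gene: True iff M is strictly below the cut-off."""
    m = pd.Series(dict(m)) if not isinstance(m, pd.Series) else m
    if (m < 0).any():
        raise ValueError("M values must be non-negative")
    return (m < cutoff).rename("stable")
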