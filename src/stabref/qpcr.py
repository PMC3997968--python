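"""RT-qPCR quantification: efficiency fitting and relative quantities.

Amplification efficiency E of a primer pair is estimated from a serial
dilution of a representative cDNA sample: Cq regressed on log10(dilution
factor) gives a slope of +log10-per-dilution-decade, and
E% = (10^(1/slope) - 1) x 100 (a slope of 3.3219 is perfect doubling,
E = 100%).  Cq panels (gene x biological sample x technical replicate)
are collapsed to mean Cq per (gene, sample) on the Cq scale, then turned
into efficiency-corrected relative quantities
Q = (1 + E/100)^(Cq_ref - Cq), referenced per gene to its minimum (or
mean) Cq so the most abundant sample has Q = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CqPanel",
    "CollapsedCq",
    "DilutionSeries",
    "EfficiencyFit",
    "RelativeQuantityMatrix",
    "collapse_replicates",
    "fit_efficiency",
    "relative_quantities",
]

_PANEL_COLUMNS = ("gene", "sample", "replicate", "cq")


@dataclass(frozen=True)
class CqPanel:
    """Long-format quantification-cycle table.

    One row per technical replicate: (gene, biological sample, technical
    replicate, Cq).  The study design behind the defaults is three
    technical replicates for each of three biological samples per
    condition.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _PANEL_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"Cq panel missing column(s): {missing}")
        if len(self.data) == 0:
            raise ValueError("empty Cq panel")
        cq = self.data["cq"].to_numpy(dtype=float)
        if not np.all(np.isfinite(cq)):
            raise ValueError("non-finite Cq values in panel")

    @property
    def genes(self) -> list[str]:
        return sorted(self.data["gene"].unique())

    @property
    def samples(self) -> list[str]:
        return sorted(self.data["sample"].unique())


@dataclass(frozen=True)
class CollapsedCq:
    """Technical replicates averaged per (gene, biological sample).

    ``sd`` keeps the replicate spread as a QC layer; ``n`` the replicate
    counts.
    """

    mean_cq: pd.DataFrame  # genes x samples
    sd: pd.DataFrame
    n: pd.DataFrame


def collapse_replicates(panel: CqPanel) -> CollapsedCq:
    """Arithmetic mean of technical-replicate Cq per (gene, sample).

    Averaging happens on the Cq scale, before any exponential transform.
    Missing (gene, sample) combinations are an error listing the gaps, not
    silently dropped.
    """
    grouped = panel.data.groupby(["gene", "sample"])["cq"]
    mean = grouped.mean().unstack("sample")
    gaps = [(g, s) for (g, s) in
            ((g, s) for g in mean.index for s in mean.columns)
            if pd.isna(mean.loc[g, s])]
    if gaps:
        raise ValueError(f"missing (gene, sample) combination(s): {gaps}")
    sd = grouped.std(ddof=1).unstack("sample")
    n = grouped.size().unstack("sample").fillna(0).astype(int)
    return CollapsedCq(mean_cq=mean, sd=sd, n=n)


@dataclass(frozen=True)
class DilutionSeries:
    """Serial-dilution Cq measurements for one primer pair.

    ``table`` has columns ``dilution_factor`` (positive; 1 = undiluted,
    larger = more dilute) and ``cq``; replicate rows per dilution are
    allowed and enter the fit as individual points.
    """

    gene: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("dilution_factor", "cq"):
            if col not in self.table.columns:
                raise ValueError(f"dilution series missing column {col!r}")
        d = self.table["dilution_factor"].to_numpy(dtype=float)
        if (d <= 0).any() or not np.all(np.isfinite(d)):
            raise ValueError("dilution factors must be positive and finite")
        if not np.all(np.isfinite(self.table["cq"].to_numpy(dtype=float))):
            raise ValueError("non-finite Cq in dilution series")


@dataclass(frozen=True)
class EfficiencyFit:
    """Standard-curve fit: slope (Cq per log10 dilution), E%, R^2."""

    gene: str
    slope: float
    efficiency_pct: float
    r_squared: float

    @property
    def amplification_base(self) -> float:
        """Per-cycle gain, 1 + E/100 (2.0 at perfect doubling)."""
        return 1.0 + self.efficiency_pct / 100.0


def fit_efficiency(series: DilutionSeries, min_dilutions: int = 3) -> EfficiencyFit:
    """Estimate amplification efficiency from a dilution series.

    Ordinary least squares of Cq against log10(dilution factor): Cq rises
    with dilution, so the slope is positive (about +3.32 per decade for
    perfect doubling) and E% = (10^(1/slope) - 1) x 100 applies as
    printed.  A negative fitted slope triggers a warning, as it usually
    means the dilution factors were encoded as concentrations.
    """
    d = series.table["dilution_factor"].to_numpy(dtype=float)
    cq = series.table["cq"].to_numpy(dtype=float)
    if len(np.unique(d)) < min_dilutions:
        raise ValueError(
            f"{series.gene}: need >= {min_dilutions} distinct dilution factors, "
            f"got {len(np.unique(d))}"
        )
    fit = stats.linregress(np.log10(d), cq)
    slope = float(fit.slope)
    if slope == 0.0:
        raise ValueError(f"{series.gene}: zero slope, cannot compute efficiency")
    if slope < 0:
        warnings.warn(
            f"{series.gene}: negative standard-curve slope ({slope:.3f}); "
            "dilution factors may be encoded as concentrations",
            stacklevel=2,
        )
    efficiency = (10.0 ** (1.0 / slope) - 1.0) * 100.0
    r2 = float(fit.rvalue) ** 2
    return EfficiencyFit(
        gene=series.gene, slope=slope, efficiency_pct=float(efficiency), r_squared=r2
    )


@dataclass(frozen=True)
class RelativeQuantityMatrix:
    """Efficiency-corrected relative quantities, genes x samples.

    All entries are positive; with the (default) minimum-Cq reference,
    each gene's maximum quantity is exactly 1 at its reference sample.
    """

    quantities: pd.DataFrame
    reference_cq: pd.Series  # per gene
    efficiency_pct: pd.Series  # per gene

    def __post_init__(self) -> None:
        if (self.quantities.to_numpy(dtype=float) <= 0).any():
            raise ValueError("relative quantities must be positive")


def relative_quantities(
    mean_cq: pd.DataFrame | CollapsedCq,
    efficiencies: Mapping[str, EfficiencyFit | float],
    ref: str = "min",
) -> RelativeQuantityMatrix:
    """Convert mean Cq values into efficiency-corrected relative quantities.

    Q[g, s] = (1 + E_g/100)^(Cq_ref(g) - Cq[g, s]) with Cq_ref the gene's
    minimum mean Cq across samples (``ref='mean'`` uses the mean instead).
    At E = 100% this is exactly the classic 2^(-dCq) computation.  Shifting
    a gene's Cq values by a constant leaves its quantities unchanged, since
    the reference shifts with the data.
    """
    cq = mean_cq.mean_cq if isinstance(mean_cq, CollapsedCq) else mean_cq
    if ref not in ("min", "mean"):
        raise ValueError(f"ref must be 'min' or 'mean', got {ref!r}")
    if not np.all(np.isfinite(cq.to_numpy(dtype=float))):
        raise ValueError("non-finite Cq values")
    missing = [g for g in cq.index if g not in efficiencies]
    if missing:
        raise KeyError(f"gene(s) without an efficiency estimate: {missing}")
    eff = pd.Series(
        {
            g: (e.efficiency_pct if isinstance(e, EfficiencyFit) else float(e))
            for g, e in efficiencies.items()
            if g in cq.index
        }
    ).loc[cq.index]
    if (eff <= -100.0).any():
        bad = list(eff.index[eff <= -100.0])
        raise ValueError(f"efficiency must exceed -100%: {bad}")
    ref_cq = cq.min(axis=1) if ref == "min" else cq.mean(axis=1)
    base = 1.0 + eff / 100.0
    # log-space for numerical robustness at extreme dCq
    log2_q = cq.rsub(ref_cq, axis=0).mul(np.log2(base), axis=0)
    return RelativeQuantityMatrix(
        quantities=np.exp2(log2_q), reference_cq=ref_cq, efficiency_pct=eff
    )
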