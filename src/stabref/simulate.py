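"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates the study design the pipeline targets: one
small-RNA-seq sample per condition (a shared control, UV, heat, hypoxia in
wild type, and hypoxia in a hif-1 mutant with its own control), then a
qPCR validation arm with three technical replicates of each of several
biological samples, plus serial dilutions for efficiency fitting.  Planted
stable genes carry zero condition effect; unstable genes get per-condition
log2 fold changes drawn from a normal distribution.  Every draw is
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .qpcr import CqPanel, DilutionSeries
from .seq_stability import RawCountMatrix

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "PanelTruth",
    "simulate_counts",
    "simulate_quantities",
    "simulate_cq_panel",
    "simulate_dilution_series",
]


def _default_comparisons() -> dict[str, list[tuple[str, str]]]:
    # stress-vs-matching-control pairs per condition group; the
    # hypoxia+hif-1 group pools the wild-type and mutant comparisons
    return {
        "UV": [("control", "UV")],
        "heat": [("control", "heat")],
        "hypoxia": [("control", "hypoxia_n2")],
        "hypoxia_hif1": [("control", "hypoxia_n2"), ("hif1_control", "hypoxia_hif1")],
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study, with defaults mirroring the target design.

    ``dispersion`` is the multiplicative coefficient of variation of the
    count draw (0.02 = 2% technical CV); 0 disables count noise entirely
    so counts equal rounded expected means.  ``mean_expression_range``
    spans roughly the read-count range the screen operates over (~500 to
    ~375,000 reads).  ``unstable_lfc_sd`` is the log2-unit SD of planted
    condition effects.  ``quantity_cv`` is the biological-sample CV of
    stable genes on the qPCR side; ``technical_sd`` the Cq-unit SD of
    technical replicates.
    """

    n_mirnas: int = 200
    stable_fraction: float = 0.3
    mean_expression_range: tuple[float, float] = (500.0, 375000.0)
    dispersion: float = 0.02
    distribution: str = "lognormal"  # or "nb" (gamma-Poisson)
    library_size_range: tuple[float, float] = (0.5, 2.0)
    # Count arm: modest genome-wide condition effects.  Slope-1 intercept
    # correction, like any global normalization, assumes the bulk of the
    # expression-weighted transcriptome is not shifting; an SD of 0.3 log2
    # units keeps that assumption tenable while ~70% of variable genes
    # still exceed the 7% variation threshold.
    unstable_lfc_sd: float = 0.3
    # qPCR validation panels: planted unstable genes carry stronger,
    # per-biological-sample condition effects.
    panel_lfc_sd: float = 0.5
    comparisons: Mapping[str, Sequence[tuple[str, str]]] = field(
        default_factory=_default_comparisons
    )
    baseline_samples: tuple[str, ...] = ("control", "hif1_control")
    # qPCR arm
    quantity_cv: float = 0.02
    technical_sd: float = 0.15
    n_technical: int = 3
    cq_intercept_range: tuple[float, float] = (18.0, 30.0)
    efficiency_range: tuple[float, float] = (89.0, 120.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mirnas < 1:
            raise ValueError("need at least 1 miRNA")
        if not 0.0 <= self.stable_fraction <= 1.0:
            raise ValueError("stable_fraction must lie in [0, 1]")
        lo, hi = self.mean_expression_range
        if not (0 < lo <= hi):
            raise ValueError("invalid mean_expression_range")
        if self.dispersion < 0 or self.quantity_cv < 0 or self.technical_sd < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.distribution not in ("lognormal", "nb"):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if not self.comparisons:
            raise ValueError("empty comparison design")

    @property
    def samples(self) -> list[str]:
        seen: list[str] = []
        for pairs in self.comparisons.values():
            for a, b in pairs:
                for s in (a, b):
                    if s not in seen:
                        seen.append(s)
        return seen


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted parameters emitted alongside a simulated count matrix."""

    stable_set: frozenset[str]
    lfc: pd.DataFrame  # genes x samples, log2 condition effects
    base_means: pd.Series
    library_factors: pd.Series

    def stable_for(self, comparisons: Sequence[tuple[str, str]]) -> frozenset[str]:
        """Genes with zero planted effect in every sample of the group."""
        cols = sorted({s for pair in comparisons for s in pair})
        mask = (self.lfc[cols] == 0).all(axis=1)
        return frozenset(self.lfc.index[mask])

    def to_json_dict(self) -> dict:
        return {
            "stable_set": sorted(self.stable_set),
            "lfc": {g: self.lfc.loc[g].to_dict() for g in self.lfc.index},
            "base_means": self.base_means.to_dict(),
            "library_factors": self.library_factors.to_dict(),
        }


def _noisy_counts(mean: np.ndarray, cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.dispersion == 0:
        return np.rint(mean)
    if cfg.distribution == "nb":
        shape = 1.0 / cfg.dispersion**2
        return rng.poisson(rng.gamma(shape, mean / shape)).astype(float)
    # mean-preserving log-normal jitter, then rounding
    sigma = np.sqrt(np.log1p(cfg.dispersion**2))
    noise = rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=mean.shape)
    return np.rint(mean * noise)


def simulate_counts(cfg: SimulationConfig) -> tuple[RawCountMatrix, SyntheticTruth]:
    """Simulate a raw miRNA count matrix with planted stable genes.

    Expected count of gene i in sample s is
    base_i x 2^lfc[i, s] x library_factor_s; stable genes have lfc = 0
    everywhere, unstable genes draw an independent lfc per non-baseline
    sample.  The count draw adds multiplicative overdispersion per
    ``cfg.distribution``.
    """
    rng = np.random.default_rng(cfg.seed)
    samples = cfg.samples
    genes = [f"miR-sim-{i + 1:03d}" for i in range(cfg.n_mirnas)]
    n_stable = int(round(cfg.stable_fraction * cfg.n_mirnas))
    stable_idx = rng.choice(cfg.n_mirnas, size=n_stable, replace=False)
    stable = frozenset(genes[i] for i in stable_idx)

    lo, hi = cfg.mean_expression_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=cfg.n_mirnas))
    lib = np.exp(rng.uniform(*np.log(cfg.library_size_range), size=len(samples)))

    lfc = np.zeros((cfg.n_mirnas, len(samples)))
    unstable_mask = ~np.isin(np.arange(cfg.n_mirnas), stable_idx)
    for j, s in enumerate(samples):
        if s in cfg.baseline_samples:
            continue
        lfc[unstable_mask, j] = rng.normal(0.0, cfg.unstable_lfc_sd, unstable_mask.sum())

    mean = base[:, None] * np.exp2(lfc) * lib[None, :]
    counts = _noisy_counts(mean, cfg, rng)
    raw = RawCountMatrix(pd.DataFrame(counts, index=genes, columns=samples))
    truth = SyntheticTruth(
        stable_set=stable,
        lfc=pd.DataFrame(lfc, index=genes, columns=samples),
        base_means=pd.Series(base, index=genes),
        library_factors=pd.Series(lib, index=samples),
    )
    return raw, truth


def simulate_quantities(
    cfg: SimulationConfig,
    n_stable: int = 4,
    n_unstable: int = 2,
    n_samples: int = 12,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, frozenset[str]]:
    """True relative quantities for a validation panel, genes x samples.

    Stable genes fluctuate with the technical CV (``cfg.quantity_cv``);
    unstable genes draw an independent log2 effect of SD
    ``cfg.panel_lfc_sd`` per biological sample.  Returns the quantity
    matrix and the planted stable set.
    """
    if n_stable + n_unstable < 2:
        raise ValueError("need at least 2 genes")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    genes = [f"stab-{i + 1}" for i in range(n_stable)] + [
        f"var-{i + 1}" for i in range(n_unstable)
    ]
    samples = [f"S{i + 1}" for i in range(n_samples)]
    sigma_stable = np.log2(1.0 + cfg.quantity_cv)
    q = np.empty((len(genes), n_samples))
    q[:n_stable] = np.exp2(rng.normal(0.0, sigma_stable, (n_stable, n_samples)))
    q[n_stable:] = np.exp2(
        rng.normal(0.0, cfg.panel_lfc_sd, (n_unstable, n_samples))
    )
    return (
        pd.DataFrame(q, index=genes, columns=samples),
        frozenset(genes[:n_stable]),
    )


@dataclass(frozen=True)
class PanelTruth:
    """Gene-level generative parameters behind a simulated Cq panel."""

    efficiency_pct: pd.Series
    intercept: pd.Series


def simulate_cq_panel(
    cfg: SimulationConfig,
    quantities: pd.DataFrame,
    efficiencies: Mapping[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[CqPanel, PanelTruth]:
    """Cq panel from true quantities: Cq = a_g - log_{1+E/100}(q) + noise.

    Each (gene, biological sample) gets ``cfg.n_technical`` technical
    replicates with Gaussian Cq noise of SD ``cfg.technical_sd``.  At
    E = 100% and zero noise, halving a quantity raises Cq by exactly one
    cycle.
    """
    if (quantities.to_numpy(dtype=float) <= 0).any():
        raise ValueError("quantities must be positive")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    genes = list(quantities.index)
    if efficiencies is None:
        eff = pd.Series(
            rng.uniform(*cfg.efficiency_range, size=len(genes)), index=genes
        )
    else:
        eff = pd.Series({g: float(efficiencies[g]) for g in genes})
    intercept = pd.Series(
        rng.uniform(*cfg.cq_intercept_range, size=len(genes)), index=genes
    )
    rows = []
    for g in genes:
        log_base = np.log2(1.0 + eff[g] / 100.0)
        for s in quantities.columns:
            ideal = intercept[g] - np.log2(quantities.loc[g, s]) / log_base
            noise = (
                rng.normal(0.0, cfg.technical_sd, cfg.n_technical)
                if cfg.technical_sd > 0
                else np.zeros(cfg.n_technical)
            )
            for r in range(cfg.n_technical):
                rows.append((g, s, r + 1, ideal + noise[r]))
    panel = CqPanel(pd.DataFrame(rows, columns=["gene", "sample", "replicate", "cq"]))
    return panel, PanelTruth(efficiency_pct=eff, intercept=intercept)


def simulate_dilution_series(
    e_true_pct: float,
    n_dilutions: int = 5,
    step: float = 5.0,
    sigma: float = 0.0,
    cq0: float = 15.0,
    n_replicates: int = 3,
    gene: str = "sim",
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> DilutionSeries:
    """Serial dilution with known true efficiency.

    Dilution factors are 1, step, step^2, ...; the noiseless Cq at
    dilution d is cq0 + log10(d) / log10(1 + E/100), so the standard-curve
    fit returns E exactly at sigma = 0.
    """
    if e_true_pct <= -100.0:
        raise ValueError("true efficiency must exceed -100%")
    if n_dilutions < 3:
        raise ValueError("need at least 3 dilutions")
    if step <= 1.0:
        raise ValueError("dilution step must exceed 1")
    rng = np.random.default_rng(seed) if rng is None else rng
    slope = 1.0 / np.log10(1.0 + e_true_pct / 100.0)
    rows = []
    for k in range(n_dilutions):
        d = step**k
        ideal = cq0 + np.log10(d) * slope
        for _ in range(n_replicates):
            noise = rng.normal(0.0, sigma) if sigma > 0 else 0.0
            rows.append((d, ideal + noise))
    return DilutionSeries(
        gene=gene, table=pd.DataFrame(rows, columns=["dilution_factor", "cq"])
    )
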