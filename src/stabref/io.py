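"""Readers and writers for the table formats the pipeline consumes.

All parsing goes through pandas; the count-table reader additionally
understands the miRDeep2-quantifier-style dialect (first column header
``#miRNA``, metadata columns dropped) and European decimal commas.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from .qpcr import CqPanel, DilutionSeries, EfficiencyFit, RelativeQuantityMatrix
from .seq_stability import ConditionIntersection, RawCountMatrix, StabilityReport

__all__ = [
    "read_count_table",
    "read_cq_table",
    "read_dilution_table",
    "write_stability_report",
    "write_intersection",
    "write_efficiency_table",
    "write_quantity_matrix",
]

# non-sample columns of a miRDeep2 quantifier csv
_MIRDEEP2_META = {"precursor", "total"}


def read_count_table(path: str | Path, decimal_comma: bool = False) -> RawCountMatrix:
    """Read a miRNA x sample count table (TSV or CSV, sniffed).

    First column holds miRNA ids; remaining columns one per sample.  A
    ``#miRNA`` id header marks the miRDeep2 quantifier dialect, whose
    ``precursor``/``total`` metadata columns are dropped.  With
    ``decimal_comma`` the comma is treated as the decimal separator.
    """
    kwargs: dict = {"sep": None, "engine": "python"}
    if decimal_comma:
        kwargs["decimal"] = ","
    df = pd.read_csv(path, **kwargs)
    id_col = df.columns[0]
    df = df.set_index(id_col)
    df.index.name = "mirna"
    if id_col == "#miRNA":
        df = df.drop(columns=[c for c in df.columns if c.lower() in _MIRDEEP2_META])
    df = df.apply(pd.to_numeric)
    return RawCountMatrix(df)


def read_cq_table(path: str | Path) -> CqPanel:
    """Long-format Cq CSV/TSV with columns gene, sample, replicate, cq."""
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    return CqPanel(df[["gene", "sample", "replicate", "cq"]])


def read_dilution_table(path: str | Path) -> dict[str, DilutionSeries]:
    """Dilution CSV/TSV with columns gene, dilution_factor, cq → per-gene series."""
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    return {
        gene: DilutionSeries(gene=gene, table=sub[["dilution_factor", "cq"]].reset_index(drop=True))
        for gene, sub in df.groupby("gene")
    }


def write_stability_report(
    report: StabilityReport, tsv_path: str | Path, json_path: str | Path | None = None
) -> None:
    report.to_frame().to_csv(tsv_path, sep="\t", index_label="mirna")
    if json_path is not None:
        Path(json_path).write_text(json.dumps(report.to_json_dict(), indent=2) + "\n")


def write_intersection(
    inter: ConditionIntersection, tsv_path: str | Path, json_path: str | Path | None = None
) -> None:
    rows = [
        {"region": region, "mirnas": ",".join(sorted(members)), "n": len(members)}
        for region, members in sorted(inter.venn_partition.items())
    ]
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(inter.to_json_dict(), indent=2) + "\n")


def write_efficiency_table(
    fits: Mapping[str, EfficiencyFit], path: str | Path
) -> None:
    """Efficiency table in the conventional (miRNA, Efficiency %, R square) layout."""
    df = pd.DataFrame(
        [
            {
                "miRNA": f.gene,
                "Efficiency (%)": round(f.efficiency_pct, 1),
                "R square": round(f.r_squared, 3),
                "slope": f.slope,
            }
            for f in fits.values()
        ]
    )
    df.to_csv(path, index=False)


def write_quantity_matrix(rq: RelativeQuantityMatrix, path: str | Path) -> None:
    rq.quantities.to_csv(path, sep="\t", index_label="gene")
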