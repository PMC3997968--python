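# stabref

**stabref** finds and validates stably expressed reference miRNAs for
RT-qPCR normalization. It is written for small-RNA biologists who have (or
simulate) two kinds of data:

1. **a small-RNA-seq count table** (miRNA × sample raw read counts from a
   quantifier), screened genome-wide for miRNAs whose expression barely
   moves between a stress condition and its control, and
2. **RT-qPCR measurements** (Cq panels plus serial-dilution standard
   curves) used to validate a handful of those candidates with the geNorm
   stability framework.

Unvalidated reference genes are one of the classic ways qPCR studies go
wrong: normalizing against a transcript that itself responds to the
treatment silently distorts every fold change downstream. The workflow
implemented here screens the whole miRNAome first and only then spends
qPCR reagents on the most promising candidates.

## The methods in brief

**Discovery (sequencing arm).** Counts are normalized per sample to the
mean total miRNA read count (`N_ij = c_ij / T_j × mean(T)`), a pseudocount
of 10 is added before log2 transformation, and every stress-vs-control
pair is compared by fitting a regression line with **slope fixed at 1**
through the paired log2 values. The intercept `b = mean(y − x)` absorbs
residual library-size bias; each miRNA's residual `r_i = y_i − x_i − b`
is its corrected log2 fold change, reported as a percent variation
`(2^|r| − 1) × 100`. A miRNA is called stable for a condition when its
variation stays ≤ 7% in every comparison of the group and its normalized
abundance is ≥ 500 reads in every sample. Per-condition stable sets are
intersected (full Venn partition) and tiered into low/medium/high
abundance so validation candidates span the expression range.

**Validation (qPCR arm).** Amplification efficiency per primer pair comes
from an ordinary least-squares fit of Cq against log10(dilution factor),
`E% = (10^(1/slope) − 1) × 100` (slope 3.32 ⇒ perfect doubling, E = 100%).
Technical replicates are averaged on the Cq scale, and relative
quantities are computed with efficiency correction,
`Q = (1 + E/100)^(Cq_ref − Cq)`, referenced to each gene's minimum Cq.

**geNorm, from scratch.** For genes *j*, *k* the pairwise variation
`V_jk = sd_i( log2(q_ij / q_ik) )` (n−1 denominator); the stability
measure is `M_j = mean_{k≠j} V_jk`. Genes are ranked by stepwise exclusion
of the highest-M gene. Normalization factors `NF_n` (geometric mean of the
*n* best genes per sample) give the pairwise variation series
`V(n/n+1) = sd_i( log2(NF_n / NF_{n+1}) )`; the smallest *n* with
`V < 0.15` is the recommended number of reference genes (all of them if
none clears the cut-off). M values below 0.5 and CVs of NF-normalized
quantities below 0.2 are the conventional stability calls.

A synthetic-data module generates count matrices, Cq panels and dilution
series with planted ground truth (stable sets, fold changes, true
efficiencies), so the whole pipeline is testable end to end without
external data.

## Worked example

```python
import stabref as st

cfg = st.SimulationConfig(n_mirnas=120, seed=7)
raw, truth = st.simulate_counts(cfg)
config = st.Config(comparisons={c: list(p) for c, p in cfg.comparisons.items()})
result = st.run_discovery(raw, config)
for condition, report in result.reports.items():
    planted = truth.stable_for(cfg.comparisons[condition])
    print(condition, len(report.passed), "stable calls,",
          len(report.passed & planted), "of", len(planted), "planted recovered")
print("stable in all conditions:", len(result.intersection.all_conditions))
```

prints

```
UV 54 stable calls, 34 of 36 planted recovered
heat 64 stable calls, 34 of 36 planted recovered
hypoxia 55 stable calls, 35 of 36 planted recovered
hypoxia_hif1 36 stable calls, 31 of 36 planted recovered
stable in all conditions: 30
```

i.e. the 7%/500 filter recovers nearly all planted stable miRNAs per
condition (extra calls are variable genes whose drawn effect happened to
be small), and 30 miRNAs survive every condition — the candidates one
would take to qPCR. The `examples/` directory has narrative scripts for
each capability: the discovery screen (`01`), the qPCR validation arm with
efficiency fits, M/V ranking and CVs (`02`), and the worked decision rules
(`03`). A thin CLI mirrors the pipeline:

```bash
stabref simulate counts --seed 7 --out sim/
stabref run-discovery sim/counts.tsv --out results/
stabref run-validation --cq cq.csv --dilutions dilutions.csv --out val/
```

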