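# Methods

## Scope and data model

stabref implements a two-arm workflow for selecting reference miRNAs:

* **Discovery arm** — a raw count matrix (miRNA × sample, one sequencing
  sample per condition) is normalized, pairwise fold changes are
  estimated, and stability is called per condition and intersected across
  conditions.
* **Validation arm** — long-format Cq panels (gene × biological sample ×
  technical replicate) and per-gene dilution series are converted into
  efficiency-corrected relative quantities and analyzed with a from-scratch
  geNorm implementation.

Everything upstream of the count table (read trimming, mapping,
quantification) and of the Cq table (primer design, melting-curve QC) is
out of scope; the package consumes quantifier output and plate exports.

## Count normalization and residual fold change

Each sample's counts are divided by that sample's total miRNA reads and
multiplied by the mean total over all samples, so per-sample totals become
equal while values stay in read-count units. A pseudocount of 10 (default,
configurable) is added **only** in the log2 layer, immediately before the
transform; the linear layer used by the abundance filter is pseudocount-free.

Two samples are compared by least-squares fitting `y = x + b` through
their paired log2 values: `b = mean(y − x)` and residual
`r_i = y_i − x_i − b`. Fixing the slope at 1 makes the intercept a pure
library-bias term; the residual is the miRNA's corrected log2 fold change
and is reported as percent variation `(2^|r| − 1) × 100`.

Exact invariances (all asserted in tests):

* normalization is idempotent, and rescaling one sample changes the linear
  matrix only by a single global factor (within-sample profiles are exactly
  invariant);
* with pseudocount 0, percent variation is exactly invariant to the
  library-size ratio between the two samples; with pseudocount 10 the
  invariance is approximate, with deviations far below the 7% decision
  threshold at abundant counts.

A `variation_metric="direct"` switch replaces the residual-implied
variation by the naive percent difference `|N_a − N_b| / N_b × 100`. The
residual metric is the default because its intercept soaks up residual
library-size bias; the direct metric is useful for small candidate panels,
where a two-gene least-squares intercept would split a single gene's shift
across both genes.

## Stability filter, intersection, tiers

A miRNA is stable for a condition group iff (a) its maximum percent
variation over all of the group's designated stress-vs-control comparisons
is ≤ `var_threshold_pct` (default 7), and (b) its linear normalized reads
are ≥ `min_reads` (default 500) in **every** sample of the group — the
strictest reading of the abundance floor, so one low-coverage sample
cannot smuggle a miRNA through. The floor is applied to normalized (not
raw) reads so it means the same thing in every library.

Per-condition stable sets are combined into a full disjoint Venn
partition; the all-condition intersection is the candidate pool of
condition-independent references. Candidates are tiered by mean normalized
abundance into low/medium/high at boundaries (2000, 100000) by default,
values exactly on a boundary going to the higher tier; validation panels
should span all three tiers so reference behavior is confirmed across the
dynamic range.

## Efficiency and relative quantification

Dilution series are encoded with dilution **factors** (1 = undiluted,
larger = more dilute), so Cq rises with the regressor and the fitted slope
is positive (≈ +3.32/decade at perfect doubling) and
`E% = (10^(1/slope) − 1) × 100` applies as printed; a negative slope
triggers a warning since it usually means concentrations were supplied
instead. Replicate dilution points enter the ordinary least-squares fit
individually; `R²` is the squared correlation.

Technical replicates of a Cq panel are averaged on the Cq scale (the
replicate SD is kept as a QC column, and missing gene×sample combinations
are an error, never silently dropped). Relative quantities are
`Q = (1 + E/100)^(Cq_ref − Cq)` computed in log space, with `Cq_ref` the
gene's minimum mean Cq (so quantities peak at exactly 1; a `ref="mean"`
option exists). Because the reference shifts with the data, per-gene Cq
shifts leave quantities invariant, and at E = 100% the computation reduces
exactly to the classic `2^(−ΔCq)`. All geNorm statistics below are
invariant to the reference choice, which therefore only affects report
readability.

## geNorm statistics

With positive quantities `q` (genes × samples), log base 2 and sample
(n−1) standard deviations throughout:

* `V_jk = sd_i(log2 q_ij − log2 q_ik)`, `M_j = mean_{k≠j} V_jk`;
* stepwise ranking removes the highest-M gene and recomputes until two
  remain; ties break by lexicographic gene id so runs are deterministic;
  the final two genes share rank 1–2 and a single M value;
* `NF_n` is the per-sample geometric mean of the n best-ranked genes;
  `V(n/n+1) = sd_i(log2(NF_n,i / NF_{n+1,i}))` for n = 2..G−1;
* the recommended reference count is the smallest n with `V < 0.15`
  (configurable); if none clears the cut-off all G genes are recommended,
  with a warning — this rule is monotone in the cut-off by construction;
* per-gene CV = sd/mean (linear scale) of `q / NF` across samples, with NF
  built on the recommended subset; conventional call CV < 0.2;
* M classification is strict: `M < 0.5` passes, `M = 0.5` fails.

All M/V statistics are invariant to positive per-gene and per-sample
rescaling (log-ratio construction); the test suite asserts this on random
matrices and checks the entire stepwise computation against an
independently written brute-force implementation (explicit loops, stdlib
statistics) on 500 random matrices up to 7 genes × 10 samples.

## Synthetic data

The generator mirrors the target study design: six sequencing samples
(shared control; UV; heat; hypoxia in wild type; hypoxia and its own
control in a hypoxia-signaling mutant), with condition groups defined by
stress-vs-matching-control pairs, and a qPCR arm with three technical
replicates per biological sample.

**Counts.** Expected counts are `base_i × 2^lfc[i,s] × lib_s` with base
expression log-uniform on (500, 375000) — spanning the read-count range
the screen operates over — and library factors log-uniform on (0.5, 2).
Planted stable genes have `lfc = 0` everywhere; unstable genes draw an
independent `lfc ~ N(0, 0.3)` per stress sample. The default count draw is
`round(mean × LogNormal)` with a mean-preserving log-normal whose CV is
the `dispersion` parameter (default 0.02, i.e. 2% multiplicative noise);
`dispersion = 0` yields exactly rounded means, making noiseless
simulations fixed points of the pipeline (filters, efficiencies and
rankings recover the planted truth). A `distribution="nb"` option provides
a classic gamma–Poisson draw for users who want shot noise; note that
Poisson noise alone exceeds 2% CV below ~2500 reads, so the log-normal
parameterization is the one that can actually realize a specified small
CV at the abundance floor.

The count-arm effect-size default (0.3 log2 units, i.e. a median planted
fold change of ~1.23×, with ~70% of variable genes exceeding the 7%
stability threshold) is deliberately more modest than the validation-panel
default below: the slope-1 intercept — like every global normalization —
assumes the bulk of the expression-weighted miRNAome is not shifting.
**Known limitation:** when a large expression share does shift, the
intercept estimate degrades by roughly
`(1 − stable_fraction) × lfc_sd / √n_unstable` log2 units and stable
genes near the variation threshold start failing; the same composition
bias would affect real data from a globally perturbed transcriptome, and
no within-data correction exists short of spike-ins.

**qPCR panels.** True quantities for validation panels put 2% CV
(log-normal) on planted stable genes and per-biological-sample
`N(0, 0.5)` log2 effects on planted unstable genes. Cq values follow
`Cq = a_g − log_{1+E/100}(q) + N(0, σ_tech)` with per-gene intercepts
uniform on (18, 30), efficiencies uniform on (89, 120)% — the envelope
typical of validated miRNA primer pairs — and technical SD 0.15 cycles.
Dilution series are generated as the exact inverse of the efficiency fit,
so a zero-noise series returns its true efficiency to machine precision.

What the generator does **not** emulate: mapping artifacts and
multi-mapping ambiguity, guanine-content biases of library preparation,
inter-run plate effects, no-template/no-RT contamination, and biological
covariance structure between miRNAs (all planted effects are independent).
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated generative model, not robustness to those
real-data pathologies.

All generators are deterministic given a seed (numpy `default_rng`,
identical across platforms).

## Numerical and design choices

* Counts are accepted as non-negative reals (quantifiers emit fractional
  counts for multi-mapped reads; supplementary tables printed with decimal
  commas parse to floats). The reader handles both decimal dialects and
  the quantifier-style `#miRNA` header, dropping its metadata columns.
* Zero-total samples, duplicate identifiers, non-finite Cq values, missing
  replicate combinations and gene-coverage mismatches all fail loudly with
  the offending identifiers in the message; pipeline stages re-raise with
  the stage name attached.
* Geometric means and relative quantities are computed in log space.
* `filter_stable` with an infinite threshold and zero floor passes
  everything; with a zero threshold it passes only exactly-zero residuals.
* Problem sizes in the test suite (500 oracle matrices ≤ 7×10; 100 seeded
  count simulations of 200 miRNAs × 6 samples; 200 seeded validation
  panels of 6 genes × 12 samples) were chosen to give stable Monte-Carlo
  estimates of the recovery rates while keeping the default run fast.
* Every run directory gets a manifest (config snapshot, seed, stage
  timings, SHA-256 of each output); re-running with the same inputs and
  config reproduces byte-identical outputs.

## Limitations

* With only two genes in a comparison, the least-squares intercept splits
  one gene's shift across both — residual variation is only meaningful for
  genome-scale matrices; use the direct metric for tiny panels.
* The exact M and V values of any particular published study are not
  reproducible without its underlying Cq and dilution measurements; the
  package validates its statistics by oracle equivalence and
  planted-truth recovery instead, and reproduces published decision-rule
  outcomes (V(2/3) = 0.189 → use all 3; M = 0.573 → fails the 0.5 cut-off)
  at the rule level.
* geNorm assumes candidate references are not co-regulated; a co-regulated
  pair scores deceptively low M. Choosing candidates from different
  genomic loci and abundance tiers (the tiering step) mitigates but does
  not eliminate this.
* NormFinder- and BestKeeper-style analyses are not implemented.
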