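"""Validation arm: efficiency fitting, quantification, geNorm ranking.

Builds a synthetic qPCR validation study — dilution series per primer
pair and a Cq panel of four planted-stable plus two planted-unstable
genes — and runs the full validation pipeline.
"""

import numpy as np

import stabref as st

cfg = st.SimulationConfig(seed=11)
rng = np.random.default_rng(11)

quantities, stable = st.simulate_quantities(cfg, n_stable=4, n_unstable=2,
                                            n_samples=12, rng=rng)
panel, truth = st.simulate_cq_panel(cfg, quantities, rng=rng)
dilutions = {
    g: st.simulate_dilution_series(truth.efficiency_pct[g], sigma=0.1, gene=g, rng=rng)
    for g in quantities.index
}

result = st.run_validation(panel, dilutions)

print("primer efficiencies (fit vs truth):")
for g, fit in result.efficiencies.items():
    print(f"  {g:>7}: E = {fit.efficiency_pct:6.1f}%  (true {truth.efficiency_pct[g]:6.1f}%)"
          f"  R^2 = {fit.r_squared:.3f}")

print("\ngeNorm stability (lower M = more stable; < 0.5 passes):")
for g in result.ranking.ranked:
    flag = "pass" if result.m_pass[g] else "FAIL"
    print(f"  {g:>7}: M = {result.m_final[g]:.3f}  {flag}")
print("planted unstable genes:", sorted(set(quantities.index) - stable))

v = result.v_series
for n, val in sorted(v.v_values.items()):
    print(f"V{n}/{n + 1} = {val:.3f}")
print(f"recommended number of reference genes: {v.recommended_n} "
      f"(smallest n with V < {v.cutoff}, else all)")
print("CV of NF-normalized quantities (stable references sit below 0.2):")
print(result.cv.round(3).to_string())
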