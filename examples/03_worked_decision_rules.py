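"""The two decision rules on small worked inputs.

Shows the pairwise-variation reference-count rule and the M-value
stability classification on hand-sized numbers, including the boundary
cases.
"""

import warnings

import stabref as st

# A three-gene panel whose V(2/3) comes out at 0.189: above the 0.15
# cut-off, so two references are NOT enough and all three are recommended.
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    n = st.recommend_reference_count({2: 0.189}, n_genes=3, cutoff=0.15)
print(f"V(2/3) = 0.189, cut-off 0.15 -> use {n} reference genes")

# Had V(2/3) been 0.12, the two most stable genes would suffice.
n = st.recommend_reference_count({2: 0.12}, n_genes=3, cutoff=0.15)
print(f"V(2/3) = 0.120, cut-off 0.15 -> use {n} reference genes")

# M-value classification is strict: below 0.5 passes, 0.5 and above fails.
for m in (0.573, 0.5, 0.49, 0.0):
    verdict = "stable" if st.classify_m({"g": m}).loc["g"] else "not stable"
    print(f"M = {m:<5} -> {verdict}")
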