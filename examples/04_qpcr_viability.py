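"""Relative gene expression (2^-ddCt) and Alamar-blue viability.

Builds a Ct table with a known 6.89-fold induction normalized to a
housekeeping gene, recovers the fold with its SEM, and computes
blank-subtracted viability percentages from a simulated absorbance plate.
"""

from fluopop import (
    fold_change_ddct,
    simulate_qpcr,
    simulate_viability,
    viability_percent,
)

ct = simulate_qpcr({"CXCR4": 6.89, "VEGF": 3.48}, n_replicates=3, ct_noise_sd=0.1, seed=2)
for gene in ("CXCR4", "VEGF"):
    r = fold_change_ddct(ct, gene, "ACTB", "control", "hypoxia")
    print(f"{gene}: fold = {r.fold:.2f} +/- {r.sem:.2f} (n = {r.n_replicates})")

plate = simulate_viability({100.0: 78.0, 150.0: 62.33, 200.0: 45.0},
                           noise_sd=0.01, seed=2)
print(viability_percent(plate).to_string(index=False,
                                         float_format=lambda x: f"{x:.2f}"))

# Folds are per-replicate 2^-ddCt values (reference-gene and control
# normalized); viability is percent of the untreated control after blank
# subtraction, so the dose series reads directly as a survival curve.
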