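"""Single-cell biomarker evaluation with positivity stratification.

Simulates a myocyte-like single-cell experiment: every case cell carries a
weak repression shift, but only ~20% of case cells (and ~8% of control
cells, as spurious leak) burst the activation program.  After log/quantile
normalization the repression t-score discriminates case cells far better
than the activation score, and it keeps working on the activation-negative
cells where the activation biomarker is blind.
"""

from sigscore import (
    SimulationConfig,
    auc_z_test,
    call_positivity,
    delong_paired_test,
    log_transform,
    quantile_normalize,
    roc_curve,
    score_matrix,
    simulate_single_cell,
)

cfg = SimulationConfig.single_cell_default(seed=1, n_cases=2000, n_controls=800,
                                           n_genes=1200)
sim = simulate_single_cell(cfg)
normed = quantile_normalize(log_transform(sim.matrix))
sigs = {"PAX7": sim.signatures["PAX7"], "DUX4_114": sim.signatures["DUX4_114"]}
table = score_matrix(normed, sigs, sim.labels)
y = sim.labels.binary

calls = call_positivity(sim.matrix, sim.signatures["DUX4_114"], min_genes=1)
pos = calls["is_positive"].to_numpy()
print(f"cells: {cfg.n_cases} case + {cfg.n_controls} control")
print(f"activation-positive: {100 * pos[y == 1].mean():.1f}% of case cells, "
      f"{100 * pos[y == 0].mean():.1f}% of control cells")

rep = table["PAX7"].to_numpy()
act = table["DUX4_114"].to_numpy()
print(f"repression AUC: {roc_curve(rep, y).auc:.3f}   "
      f"activation AUC: {roc_curve(act, y).auc:.3f}")
cmp = delong_paired_test(rep, act, y)
print(f"paired DeLong (repression vs activation): z={cmp.z:.1f}, p={cmp.pvalue:.2e}")

neg = ~pos
auc_neg, z_neg, p_neg = auc_z_test(rep[neg], y[neg])
print(f"activation-negative subset (n={neg.sum()}): repression AUC={auc_neg:.3f}, "
      f"z={z_neg:.1f}, p={p_neg:.2e}")
print("# The repression biomarker reads a weak shift present in *every* case")
print("# cell, so it stays discriminative even among the ~80% of case cells")
print("# with zero detected activation-target genes.")
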