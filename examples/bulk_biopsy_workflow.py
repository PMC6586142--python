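"""Score and compare biomarkers on a synthetic bulk biopsy cohort.

Simulates a 34-case / 9-control cohort with a planted repression program
(two-sided signature, scored by the within-sample t-score) and activation
programs (up-only signatures, scored by mean log expression), then runs the
group tests, ROC analysis and the paired DeLong comparison.
"""

from sigscore import (
    SimulationConfig,
    delong_paired_test,
    mean_of_biomarkers,
    roc_curve,
    score_matrix,
    simulate_bulk,
    wilcoxon_rank_sum,
)

sim = simulate_bulk(SimulationConfig(seed=1))
table = score_matrix(sim.matrix, sim.signatures, sim.labels)
table["DUX4_mean"] = mean_of_biomarkers(
    table, [n for n in sim.signatures if n.startswith("DUX4")])
y = sim.labels.binary

print(f"cohort: {sim.labels.n_cases} cases, {sim.labels.n_controls} controls, "
      f"{sim.matrix.n_genes} genes")
print()
for name in [*sim.signatures, "DUX4_mean"]:
    scores = table[name].to_numpy()
    curve = roc_curve(scores, y)
    test = wilcoxon_rank_sum(scores[y == 1], scores[y == 0])
    print(f"{name:10s} AUC={curve.auc:.3f} (cases score {curve.positive_direction}) "
          f"Wilcoxon p={test.pvalue:.2e}")

cmp = delong_paired_test(table["PAX7"].to_numpy(), table["DUX4_mean"].to_numpy(), y,
                         name_a="PAX7", name_b="DUX4_mean")
print()
print(f"paired DeLong PAX7 vs DUX4_mean: z={cmp.z:.2f}, p={cmp.pvalue:.3f}")
print("# Every biomarker separates cases from controls (AUC near 1, tiny")
print("# rank-sum p); the DeLong p says whether the repression and activation")
print("# scores differ in discriminative power on these same samples.")
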