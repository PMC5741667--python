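"""Score tissue specificity with tau and compare gene groups.

tau = 1 - mean(expression ratio to the maximal tissue): 0 for uniform
expression, approaching 1 for single-tissue expression. The example
simulates a matrix with 20% planted tissue-specific genes and shows tau
separating them from broadly expressed genes.
"""

from repeatburst import compare_tau_groups, simulate_expression_matrix, tau_score, tau_table

print("tau of a uniform gene over 9 tissues :", tau_score([7.5] * 9))
print("tau of a one-tissue gene over 9      :", round(tau_score([9, 0, 0, 0, 0, 0, 0, 0, 0]), 4))
print("tau of (10, 5, 0, 0, 5)              :", tau_score([10, 5, 0, 0, 5]))

sim = simulate_expression_matrix(
    n_genes=600, n_tissues=9, frac_specific=0.2,
    fold_effect=8.0, dispersion=0.3, seed=13,
)
result = tau_table(sim.matrix, min_tpm=1.0)
spec_tau = result.tau[result.tau.index.isin(sim.specific_gene_ids)]
broad_tau = result.tau[result.tau.index.isin(sim.broad_gene_ids)]
cmp = compare_tau_groups(spec_tau, broad_tau)

print(f"\n{len(result.tau)} genes scored, {len(result.excluded_genes)} below the 1-TPM floor")
print(f"median tau, planted specific genes : {cmp['median_a']:.3f}")
print(f"median tau, broad genes            : {cmp['median_b']:.3f}")
print(f"rank-sum p-value                   : {cmp['p_value']:.2e}")
print()
print("An 8-fold concentration into one tissue pushes tau toward its")
print("single-tissue limit 1 - 1/9 ~ 0.89, while log-normal noise alone")
print("keeps broad genes near 0.2-0.4; the rank test separates the groups.")
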