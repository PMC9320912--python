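"""Relative gene expression by the 2^-ddCt method.

Simulates a Ct table for two cold-responsive genes in a resistant and a
sensitive genotype (reference gene included), then recovers the fold
changes.  A fold change of 4 means the transcript is four times more
abundant under cold stress than at the control temperature, after
normalising to the reference gene.
"""

from coldscore import fold_change_table, generate_qpcr

true_folds = {
    "SOD3": {"resistant": 6.0, "sensitive": 2.0},
    "ADC1": {"resistant": 4.5, "sensitive": 1.8},
}
ct = generate_qpcr(true_folds, n_replicates=3, ct_noise_sd=0.1, seed=1)
folds = fold_change_table(ct, reference_gene="REF")

print("estimated stress/control fold changes (truth in brackets):")
for row in folds.itertuples():
    truth = true_folds[row.gene][row.genotype]
    print(f"  {row.gene:5s} {row.genotype:10s} "
          f"{row.fold_change:5.2f} +/- {row.fold_sd:.2f}  [{truth}]")
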