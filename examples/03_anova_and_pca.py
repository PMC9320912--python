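"""Classical statistics on the cohort: factorial ANOVA, correlations, PCA.

The two-way fixed-effects ANOVA partitions each trait's variance into
genotype (G), temperature (T) and G x T interaction; the correlation and
PCA structure shows how strongly the 29 traits overlap.
"""

from coldscore import (
    GeneratorConfig, correlation_matrix, factorial_anova,
    generate_phenotypes, pca, replicate_means,
)

dataset, _ = generate_phenotypes(GeneratorConfig(seed=1))
means = replicate_means(dataset)

print("factorial ANOVA, seedling length:")
print(factorial_anova(dataset, "SL").table.to_string(float_format="%.3f"))
# A large T F-statistic says cold moves the trait; a large G x T one says
# genotypes differ in how much it moves — the raw material for screening.

for treatment in ("CK", "LT"):
    corr = correlation_matrix(means, treatment)
    print(f"\n{treatment}: {corr.n_significant_05} trait pairs significant at "
          f"p<0.05 ({corr.n_significant_01} at p<0.01) of 406")

result = pca(means, scope="pooled")
print(f"\nPCA retains {result.n_retained} components (eigenvalue > 1), "
      f"explaining {result.cumulative_percent[result.n_retained - 1]:.1f}% "
      "of total variance")
print("per-component share (%):",
      [round(float(p), 1) for p in result.percent_variance[:result.n_retained]])
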