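"""Score genotypes by fuzzy-membership comprehensive evaluation.

For each trait, the stress/control ratio (cold-resistance coefficient, CRC)
is min-max normalised across genotypes to a membership value in [0, 1] —
inverted for damage-indicating traits — and each genotype's comprehensive
score U_j is the unweighted mean over all 29 traits.  Higher U_j = more
cold resistant.
"""

from coldscore import GeneratorConfig, evaluate_cohort, generate_phenotypes

dataset, _ = generate_phenotypes(GeneratorConfig(seed=1))
evaluation = evaluate_cohort(dataset)

scores = evaluation.scores.sort_values(ascending=False)
print("top five genotypes by comprehensive cold-resistance score U_j:")
print(scores.head().to_string(float_format="%.3f"))
print("\nbottom five:")
print(scores.tail().to_string(float_format="%.3f"))
print(f"\nU_j range {scores.min():.3f}-{scores.max():.3f}, "
      f"coefficient of variation {evaluation.score_cv:.1f}%")
# U_j near 1 means the genotype sits at the favourable end of the CRC range
# for most traits; near 0, at the damaged end.
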