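"""Screen a ratio matrix for diurnal rhythms and classify peaking times.

Builds a small synthetic study (noise CV 10%, 3 replicates, five
conditions), assembles the 12C/13C ratio matrix, and runs the statistics
cascade: one-way ANOVA with a >1.5 fold-change gate, the midday-vs-
continuous-light t test, and peaking-time classification.
"""

from isodiel import (
    GeneratorConfig,
    anova_screen,
    build_abundance_matrix,
    generate_study,
    pair_with_internal_standard,
    pairwise_screen,
)

config = GeneratorConfig(seed=42, n_metabolites=20, n_unknown=0, n_background=10)
bundle = generate_study(config)
pairs = {s: pair_with_internal_standard(f) for s, f in bundle.mixed_features.items()}
matrix = build_abundance_matrix(pairs, bundle.design)

anova = anova_screen(matrix, bundle.design, alpha=0.05, fc_min=1.5)
significant = [r for r in anova if r.significant]
print(f"matrix: {matrix.shape[0]} features x {matrix.shape[1]} samples")
print(f"ANOVA significant (p<0.05, FC>1.5): {len(significant)}/{len(anova)}")
for r in significant[:5]:
    print(f"  p={r.p_value:8.2e}  FC={r.fold_change:5.2f}  peaks at {r.peaking}")

md_cl = pairwise_screen(matrix, bundle.design, "MD", "CL")
print(f"MD vs CL significant (t test): {sum(r.significant for r in md_cl)}/{len(md_cl)}")
# 16 of 20 compounds carry a planted 8-fold diurnal rhythm (the rest are
# flat); the screen recovers them and the peaking labels match the planted
# classes.
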