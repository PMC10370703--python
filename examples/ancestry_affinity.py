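"""Ancestry affinity: outgroup f3, f4 and PCA projection.

Drifts four populations on a known tree (outgroup O; A and B sisters; C
their cousin), samples genotypes, and shows that outgroup f3 ranks the
true sister first, the null f4 is consistent with zero, and degraded
pseudo-haploid copies of reference individuals project back onto their
own population's cluster.
"""

import numpy as np

from adnakit.fstats import estimate_frequencies, f3_outgroup, f4
from adnakit.pca import fit_pca, project_sample
from adnakit.simulate import (
    drift_tree,
    pseudo_haploidize,
    sample_population_genotypes,
    simulate_allele_frequencies,
    simulate_drifted_populations,
)

freqs, panel = simulate_allele_frequencies(20_000, a=0.1, b=0.9, seed=21)
tree = drift_tree(
    (0.0, [("O", 0.10), (0.02, [(0.03, [("A", 0.01), ("B", 0.01)]), ("C", 0.04)])])
)
pops = simulate_drifted_populations(tree, freqs, seed=22)
gm, assignment = sample_population_genotypes(pops, panel, n_per_pop=10, seed=23)
pf = estimate_frequencies(gm, assignment)

print("outgroup f3 (bigger = more shared drift with A):")
for other in ("B", "C"):
    r = f3_outgroup(pf, "O", "A", other)
    print(f"  f3(O; A, {other}) = {r.value:.5f} +/- {r.jackknife_se:.5f}")

r4 = f4(pf, "O", "C", "A", "B")
print(
    f"\nf4(O, C; A, B) = {r4.value:.6f}, Z = {r4.z:.2f} "
    "(|Z| < 3: A and B are symmetric with respect to C, as planted)"
)

model = fit_pca(gm, 2)
degraded = pseudo_haploidize(gm, missingness=0.5, seed=24)
label = gm.individuals[0]
coords = project_sample(model, degraded.calls[0])
ref = model.reference_coordinates[0]
print(
    f"\n{label}: fitted PC1/PC2 = ({ref[0]:.2f}, {ref[1]:.2f}); "
    f"50%-missing pseudo-haploid copy projects to "
    f"({coords[0]:.2f}, {coords[1]:.2f})"
)
print("Least-squares projection keeps degraded samples near their source.")
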