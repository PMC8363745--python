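"""Superimpose a synthetic molar cohort and compare sizes between groups.

Generalized Procrustes analysis removes location, scale and orientation;
what remains is shape. Size is carried separately as the natural log of
centroid size (lnCS), compared here between two populations with the
Mann-Whitney U test.
"""

import numpy as np

from dentomorph.gpa import generalized_procrustes
from dentomorph.inference import mann_whitney_u
from dentomorph.synthetic import CohortSpec, GroupSpec, generate_cohort

spec = CohortSpec(
    tooth_class="ldm2",
    feature_set="dentinal_crown",
    groups=[
        GroupSpec("Baka", 32, lncs_mean=3.06, lncs_sd=0.05),
        GroupSpec("European", 11, lncs_mean=2.96, lncs_sd=0.05),
    ],
    noise_sd=0.02,
    seed=7,
)
cohort = generate_cohort(spec)
res = generalized_procrustes(cohort)

print(f"specimens:        {res.n_specimens} (55 landmarks each)")
print(f"GPA iterations:   {res.iterations} (converged={res.converged})")

pops = np.array(cohort.populations())
baka = res.ln_centroid_sizes[pops == "Baka"]
eur = res.ln_centroid_sizes[pops == "European"]
print(f"mean lnCS  Baka:     {baka.mean():.3f}   European: {eur.mean():.3f}")
u, z, p = mann_whitney_u(baka, eur)
print(f"Mann-Whitney U test: Z = {z:.2f}, p = {p:.4f}")
# A small p confirms the planted size difference between the two groups.
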