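"""Slide curve semilandmarks along the EDJ marginal edge.

Semilandmarks on a curve carry no point-to-point homology of their own:
their position along the curve is arbitrary. Sliding moves each one along
its local tangent so that the thin-plate-spline bending energy of the
deformation from the sample consensus to each specimen is minimal, then
re-projects it onto the specimen's digitized curve.
"""

from dentomorph.synthetic import CohortSpec, GroupSpec, generate_cohort
from dentomorph.tps import slide_semilandmarks

spec = CohortSpec(
    tooth_class="udm2",
    feature_set="dentinal_crown",
    groups=[GroupSpec("Baka", 12)],
    noise_sd=0.02,
    seed=3,
)
cohort = generate_cohort(spec)
result = slide_semilandmarks(cohort, outer_iters=5)

print(f"specimens: {len(cohort)}  (47 slidable semilandmarks each)")
print("total bending energy toward the consensus, per outer iteration:")
for i, e in enumerate(result.energy_history, start=1):
    print(f"  iteration {i}: {e:.4f}")
drop = 100 * (1 - result.energy_history[-1] / result.energy_history[0])
print(f"energy reduced by {drop:.1f}% - the semilandmark placement noise that")
print("sliding removed; anatomical landmarks never moved.")
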