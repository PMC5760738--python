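"""Full inference pipeline on a synthetic four-treatment experiment.

Generates a seeded egestion-time experiment under the default study
conditions (four treatments: bacteria fed at low/high density to
axenic/gnotobiotic hosts, with known loss patterns), runs the empirical
pipeline (hourly distributions -> per-sample statistics -> proportion
egested -> day averaging -> t tests) and prints each treatment's inferred
spatiotemporal category. Detection is raised above the microscopy default
so the gradual treatment's moment reduction is resolvable.
"""

from dataclasses import replace

from gutflow import analyze_samples, generate_egestion_experiment
from gutflow.synth import default_design, design_inoculum

design = replace(default_design(seed=42), detection_fraction=0.02)
samples, truth = generate_egestion_experiment(design)
print(f"{len(samples)} vials generated; ground-truth proportions egested:")
for name, rec in sorted(truth["treatments"].items()):
    print(f"  {name}: {rec['proportion_egested']:.2f} "
          f"(bacterial mean egestion time {rec['mean_h']:.2f} h)")

per_sample, results = analyze_samples(samples, design_inoculum(design))
print()
for res in results:
    print(f"{res.treatment}: proportion {res.proportion_test.estimate:.2f} "
          f"(p={res.proportion_test.pvalue:.3f} vs 1), "
          f"paired mean-diff p={res.mean_test.pvalue:.3f} "
          f"-> {res.category}")
print()
print("LA/LG/HG lose cells in the fast proximal compartment: totals drop but")
print("egestion times match the microspheres. HA loses cells along the whole")
print("gut: the egestion-time statistics are visibly reduced.")
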