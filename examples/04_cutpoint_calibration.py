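"""ROC analysis and accuracy-optimal panel cut-point calibration.

Exome TMB is dichotomised at 10/Mb; each panel's TMB is swept to find the
threshold that classifies the most samples into the right category.
"""
from paneltmb import (
    SimulationConfig, build_exome_model, build_panel_footprint, build_profiles,
    roc_curve, simulate_cohort,
)

cohort = simulate_cohort(SimulationConfig(seed=7, n_samples=300))
designs = [build_panel_footprint(n, g, cohort.genome.genes)
           for n, g in cohort.panels.items()]
exome = build_exome_model(cohort.genome.genes, "cds")
types = dict(zip(cohort.metadata["sample_id"], cohort.metadata["tumour_type"]))
profiles = build_profiles(cohort.variants_by_sample, types, designs, exome)

print(f"{'panel':14s} {'AUC':>6s} {'cut-point':>10s} {'accuracy':>9s}")
for d in sorted(designs, key=lambda d: d.footprint_mb):
    roc = roc_curve(profiles, d.name, exome_cutoff=10.0)
    print(f"{d.name:14s} {roc.auc:6.3f} {roc.optimal_cutpoint:8.2f}/Mb "
          f"{roc.optimal_accuracy:8.1%}")
# Every calibrated cut-point exceeds the 10/Mb exome reference: panels are
# enriched for frequently mutated driver genes and systematically over-call,
# so each assay needs its own, higher threshold -- and by a panel-dependent
# amount, which is why a shared fixed cut-off misclassifies.

skin = roc_curve(profiles, designs[0].name, exome_cutoff=10.0, stratum="skin")
print(f"\n{designs[0].name} restricted to skin cancer: AUC {skin.auc:.3f}, "
      f"cut-point {skin.optimal_cutpoint:.2f}/Mb "
      f"({skin.n_positive}/{skin.n} TMB-high)")
# Per-tumour-type calibration differs again, reflecting each type's TMB
# distribution around the 10/Mb boundary.
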