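"""Build longest-ORF panel footprints from an annotation and gene lists.

Each panel's interrogated region is approximated by the transcript with the
largest summed CDS length per gene; footprint size in Mb is the panel-TMB
denominator.
"""
from paneltmb import (
    SimulationConfig, build_panel_footprint, build_exome_model, simulate_cohort,
)

cohort = simulate_cohort(SimulationConfig(seed=7, n_samples=1))
exome = build_exome_model(cohort.genome.genes)

print(f"exome: {exome.regions_mb:.3f} Mb CDS union, "
      f"{exome.denominator_mb:.0f} Mb conventional TMB denominator")
for name, genes in sorted(cohort.panels.items()):
    design = build_panel_footprint(name, genes, cohort.genome.genes)
    print(f"{name:14s} {len(design.matched_genes):4d} genes matched, "
          f"footprint {design.footprint_mb:.3f} Mb")
# Footprint sizes span a ~1.9x ratio between the smallest and largest panel,
# the relative spread of commercial panel designs; a mutation inside a small
# footprint moves that panel's TMB nearly twice as much as the largest one's.
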