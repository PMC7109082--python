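"""Synthetic cohort generator: determinism, structure and statistical behaviour."""
import math

import numpy as np
import pytest
from scipy import stats

from paneltmb import (
    GenomeSpec,
    SimulationConfig,
    TumourTypeTmb,
    build_exome_model,
    build_panel_footprint,
    exome_tmb,
    generate_annotation,
    generate_panels,
    panel_tmb,
    read_gene_models,
    simulate_cohort,
    simulate_sample,
)
from paneltmb.cohortsim import SimulationError, variants_to_vcf
from paneltmb.variants import read_somatic_vcf

SMALL_GENOME = GenomeSpec(n_genes=200, n_chromosomes=2)


def one_type_config(**kwargs):
    defaults = dict(
        seed=21,
        n_samples=50,
        tumour_type_mix={"lung": 1.0},
        tmb_distribution={"lung": TumourTypeTmb(math.log(9.0), 0.9, 0.0, 1.0)},
        genome=SMALL_GENOME,
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


class TestAnnotationGeneration:
    def test_deterministic_gtf_bytes(self):
        a = generate_annotation(SMALL_GENOME, seed=42)
        b = generate_annotation(SMALL_GENOME, seed=42)
        assert a.gtf == b.gtf
        assert generate_annotation(SMALL_GENOME, seed=43).gtf != a.gtf

    def test_cds_union_near_spec(self):
        spec = GenomeSpec(n_genes=500, mean_cds_length=1500.0)
        genome = generate_annotation(spec, seed=1)
        # 500 genes x 1.5 kb mean ORF: union ~0.75 Mb within sampling noise.
        assert genome.cds_union_mb == pytest.approx(0.75, rel=0.10)

    def test_minimal_genome_parses_back(self, tmp_path):
        genome = generate_annotation(GenomeSpec(n_genes=10, n_chromosomes=1), seed=3)
        path = tmp_path / "mini.gtf"
        path.write_text(genome.gtf)
        genes = read_gene_models(path)
        assert len(genes) == 10
        by_name = {g.gene_name: g for g in genes}
        for g in genome.genes:
            parsed = by_name[g.gene_name]
            assert {t.transcript_id for t in parsed.transcripts} == {
                t.transcript_id for t in g.transcripts
            }

    def test_too_few_genes_rejected(self):
        with pytest.raises(SimulationError, match=">= 10"):
            generate_annotation(GenomeSpec(n_genes=5), seed=0)

    def test_genes_do_not_overlap(self):
        genome = generate_annotation(SMALL_GENOME, seed=7)
        spans = {}
        for g in genome.genes:
            ivs = [iv for t in g.transcripts for iv in t.cds]
            chrom = ivs[0].chrom
            spans.setdefault(chrom, []).append(
                (min(iv.start for iv in ivs), max(iv.end for iv in ivs))
            )
        for chrom, ss in spans.items():
            ss.sort()
            assert all(b0 >= a1 for (_, a1), (b0, _) in zip(ss, ss[1:]))


class TestPanelGeneration:
    def test_seven_nested_panels_with_footprint_ratio(self):
        genome = generate_annotation(GenomeSpec(), seed=9)
        panels = generate_panels(genome, seed=9)
        assert len(panels) == 7
        names = {g.gene_name for g in genome.genes}
        gene_sets = sorted((set(v) for v in panels.values()), key=len)
        for gs in gene_sets:
            assert gs <= names
        for small, large in zip(gene_sets, gene_sets[1:]):
            assert small <= large
        designs = {
            name: build_panel_footprint(name, genes, genome.genes)
            for name, genes in panels.items()
        }
        sizes = [d.footprint_mb for d in designs.values()]
        assert max(sizes) / min(sizes) == pytest.approx(1.9, rel=0.15)

    def test_panels_driver_biased(self):
        genome = generate_annotation(SMALL_GENOME, seed=9)
        panels = generate_panels(genome, seed=9)
        smallest = min(panels.values(), key=len)
        # every driver gene is on every panel
        assert genome.driver_genes <= set(smallest)

    def test_oversized_panel_rejected(self):
        from paneltmb import PanelSpec

        genome = generate_annotation(SMALL_GENOME, seed=9)
        with pytest.raises(SimulationError, match="> 1"):
            generate_panels(genome, [PanelSpec("huge", 1.5)], seed=9)


class TestSampleSimulation:
    def test_deterministic_vcf_bytes(self):
        config = one_type_config()
        genome = generate_annotation(config.genome, config.seed)
        panels = generate_panels(genome, config.panels, config.seed)
        va, _ = simulate_sample(config, genome, panels, "S0001", "lung")
        vb, _ = simulate_sample(config, genome, panels, "S0001", "lung")
        text_a = variants_to_vcf(va, genome.chrom_lengths)
        assert text_a == variants_to_vcf(vb, genome.chrom_lengths)
        vc, _ = simulate_sample(config, genome, panels, "S0002", "lung")
        assert variants_to_vcf(vc, genome.chrom_lengths) != text_a

    def test_vcf_round_trip_preserves_variants(self, tmp_path):
        config = one_type_config()
        genome = generate_annotation(config.genome, config.seed)
        panels = generate_panels(genome, config.panels, config.seed)
        variants, truth = simulate_sample(config, genome, panels, "S0003", "lung")
        path = tmp_path / "S0003.vcf"
        path.write_text(variants_to_vcf(variants, genome.chrom_lengths))
        back = read_somatic_vcf(path, "S0003")
        assert len(back) == truth.n_exome
        assert [(v.chrom, v.pos, v.ref, v.alt, v.vclass, v.non_synonymous)
                for v in back] == [
            (v.chrom, v.pos, v.ref, v.alt, v.vclass, v.non_synonymous)
            for v in variants
        ]

    def test_unknown_tumour_type_errors(self):
        config = one_type_config()
        genome = generate_annotation(config.genome, config.seed)
        panels = generate_panels(genome, config.panels, config.seed)
        with pytest.raises(SimulationError, match="no TMB distribution"):
            simulate_sample(config, genome, panels, "S0", "kidney")

    def test_enrichment_free_panel_tmb_unbiased(self):
        """With enrichment 1 the mean panel-minus-exome TMB difference is
        within 3 Monte-Carlo standard errors of zero."""
        config = one_type_config(seed=31, n_samples=300, driver_enrichment=1.0)
        cohort = simulate_cohort(config)
        genome = cohort.genome
        designs = {
            n: build_panel_footprint(n, g, genome.genes)
            for n, g in cohort.panels.items()
        }
        exome = build_exome_model(genome.genes, "cds")
        diffs = []
        for sid, variants in cohort.variants_by_sample.items():
            p = panel_tmb(variants, designs["FoundationOne"])
            e = exome_tmb(variants, exome)
            diffs.append(p - e)
        diffs = np.array(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) <= 3 * se

    def test_enrichment_inflates_panel_tmb(self):
        """Enrichment 3 makes panel TMB exceed exome TMB density (one-sided
        paired t-test over 500 samples at alpha=0.001)."""
        config = one_type_config(seed=37, n_samples=500, driver_enrichment=3.0)
        cohort = simulate_cohort(config)
        designs = {
            n: build_panel_footprint(n, g, cohort.genome.genes)
            for n, g in cohort.panels.items()
        }
        exome = build_exome_model(cohort.genome.genes, "cds")
        diffs = np.array([
            panel_tmb(v, designs["FoundationOne"]) - exome_tmb(v, exome)
            for v in cohort.variants_by_sample.values()
        ])
        t = stats.ttest_1samp(diffs, 0.0, alternative="greater")
        assert t.pvalue < 0.001


class TestCohortSimulation:
    def test_type_counts_within_multinomial_band(self):
        config = SimulationConfig(seed=17, n_samples=200, genome=SMALL_GENOME)
        cohort = simulate_cohort(config)
        counts = cohort.metadata["tumour_type"].value_counts()
        for ttype, p in config.tumour_type_mix.items():
            lo, hi = stats.binom.ppf([0.005, 0.995], 200, p)
            assert lo <= counts.get(ttype, 0) <= hi

    def test_truth_matches_recounted_vcfs(self, small_cohort, small_cohort_dir):
        """Generator bookkeeping equals pipeline recounts, integer-exact."""
        genes = read_gene_models(small_cohort_dir / "annotation.gtf")
        designs = {
            n: build_panel_footprint(n, g, genes)
            for n, g in small_cohort.panels.items()
        }
        exome = build_exome_model(genes, "cds")
        truth = small_cohort.truth.set_index("sample_id")
        for sid in truth.index:
            variants = read_somatic_vcf(small_cohort_dir / "vcf" / f"{sid}.vcf", sid)
            row = truth.loc[sid]
            assert round(exome_tmb(variants, exome) * exome.denominator_mb) == row["n_exome"]
            for name, design in designs.items():
                recount = round(panel_tmb(variants, design) * design.footprint_mb)
                assert recount == row[f"n_panel_{name}"]
            assert sum(v.non_synonymous for v in variants) == row["n_nonsynonymous"]

    def test_empty_mix_rejected(self):
        with pytest.raises(SimulationError, match="must not be empty"):
            SimulationConfig(tumour_type_mix={}).validate()

    def test_mix_must_sum_to_one(self):
        with pytest.raises(SimulationError, match="sum to 1"):
            SimulationConfig(tumour_type_mix={"lung": 0.5, "skin": 0.4}).validate()
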