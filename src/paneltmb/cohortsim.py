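"""Synthetic metastatic-cohort generator.

Emulates, at desk scale, the structure of a WGS metastatic cohort used for
in-silico panel TMB assessment: a miniature genome annotation, seven nested
gene panels biased toward designated driver genes, and per-sample somatic
calls whose genome-wide rate follows tumour-type-specific log-normal TMB
distributions with an explicit hypermutator mixture (the heavy right tail
that makes 20-40/Mb cut-offs meaningful). A configurable driver-gene
enrichment factor multiplies the per-base mutation rate of driver genes,
reproducing the over-calling mechanism by which panels composed of
frequently mutated driver genes inflate TMB at low mutation burdens; the
total genome-wide count is preserved, so enrichment redistributes mutations
into panels without changing exome TMB.

Every sample draws from its own RNG stream keyed on (seed, sample_id) so
cohorts are reproducible (byte-identical VCFs) under any generation order.
Truth bookkeeping (per-sample exome count, per-panel counts via gene
membership, non-synonymous count) is recorded at generation time,
independently of the interval machinery that later recounts it.
"""
from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .annotation import GeneModel, Transcript
from .intervals import GenomicInterval, length_mb, merge_intervals
from .variants import INDEL, MNV, SNV, SomaticVariant, make_variant

BASES = np.array(list("ACGT"))


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class GenomeSpec:
    """Miniature genome layout. Defaults give a ~4 Mb CDS union.

    Panel TMB is quantised at 1/footprint_mb mutations per Mb, so footprints
    around 1.5-3 Mb (see DEFAULT_PANEL_SPECS fractions) are needed before
    cut-points near 10/Mb can be resolved to fractions of a mutation/Mb.
    """

    n_genes: int = 2000
    n_chromosomes: int = 4
    mean_cds_length: float = 2000.0
    cds_length_sigma: float = 0.45
    min_cds_length: int = 300
    max_cds_length: int = 9000
    max_exons: int = 6
    max_transcripts: int = 3
    intergenic_gap: tuple[int, int] = (200, 2000)
    intron_gap: tuple[int, int] = (50, 400)
    driver_fraction: float = 0.3


@dataclass(frozen=True)
class PanelSpec:
    """A synthetic panel: target footprint as a fraction of the CDS union."""

    name: str
    footprint_fraction: float


# Footprint fractions span a 1.9x ratio, mirroring the relative spread of
# commercial panel footprints (0.78 vs 1.48 Mb); ordering follows the panels'
# relative concordance ranking, not any vendor's real design.
DEFAULT_PANEL_SPECS: tuple[PanelSpec, ...] = (
    PanelSpec("FoundationOne", 0.3750),
    PanelSpec("NeoGenomics", 0.4125),
    PanelSpec("MSK-IMPACT", 0.4500),
    PanelSpec("Cancerplex", 0.5000),
    PanelSpec("ThermoFisher", 0.5500),
    PanelSpec("TempusXT", 0.6250),
    PanelSpec("Caris", 0.7125),
)


@dataclass(frozen=True)
class TumourTypeTmb:
    """Log-normal TMB (mutations per CDS-Mb) with a hypermutator mixture."""

    mu: float
    sigma: float
    hypermutator_fraction: float
    hypermutator_multiplier: float


DEFAULT_TMB_DISTRIBUTIONS: dict[str, TumourTypeTmb] = {
    "colorectal": TumourTypeTmb(math.log(4.0), 0.9, 0.15, 8.0),
    "skin": TumourTypeTmb(math.log(12.0), 1.0, 0.05, 4.0),
    "lung": TumourTypeTmb(math.log(9.0), 0.9, 0.03, 4.0),
    "breast": TumourTypeTmb(math.log(3.0), 0.8, 0.03, 5.0),
}

DEFAULT_TYPE_MIX: dict[str, float] = {
    "colorectal": 0.3,
    "skin": 0.2,
    "lung": 0.3,
    "breast": 0.2,
}

DEFAULT_VARIANT_MIX: dict[str, float] = {SNV: 0.88, MNV: 0.04, INDEL: 0.08}
DEFAULT_NS_FRACTION: dict[str, float] = {SNV: 0.75, MNV: 0.90, INDEL: 0.90}


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_samples: int = 500
    tumour_type_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_MIX)
    )
    tmb_distribution: dict[str, TumourTypeTmb] = field(
        default_factory=lambda: dict(DEFAULT_TMB_DISTRIBUTIONS)
    )
    driver_enrichment: float = 2.0
    variant_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_VARIANT_MIX)
    )
    nonsynonymous_fraction: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NS_FRACTION)
    )
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    panels: tuple[PanelSpec, ...] = DEFAULT_PANEL_SPECS

    def validate(self) -> None:
        if not self.tumour_type_mix:
            raise SimulationError("tumour_type_mix must not be empty")
        for name, probs in (
            ("tumour_type_mix", self.tumour_type_mix),
            ("variant_mix", self.variant_mix),
        ):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise SimulationError(f"{name} proportions must sum to 1")
            if any(p <= 0 for p in probs.values()):
                raise SimulationError(f"{name} proportions must be positive")
        missing = set(self.tumour_type_mix) - set(self.tmb_distribution)
        if missing:
            raise SimulationError(
                f"no TMB distribution for tumour type(s): {', '.join(sorted(missing))}"
            )
        if self.driver_enrichment < 1.0:
            raise SimulationError("driver_enrichment must be >= 1")
        if self.n_samples < 1:
            raise SimulationError("n_samples must be >= 1")
        for c, p in self.nonsynonymous_fraction.items():
            if not 0.0 <= p <= 1.0:
                raise SimulationError(f"nonsynonymous_fraction[{c}] outside [0, 1]")


@dataclass(frozen=True)
class SyntheticGenome:
    genes: tuple[GeneModel, ...]
    gtf: str
    driver_genes: frozenset[str]
    chrom_lengths: dict[str, int]

    @property
    def cds_union_mb(self) -> float:
        return length_mb(
            iv for g in self.genes for t in g.transcripts for iv in t.cds
        )


def _sid_key(sample_id: str) -> int:
    return zlib.crc32(sample_id.encode())


def generate_annotation(spec: GenomeSpec, seed: int) -> SyntheticGenome:
    """Build a miniature GTF annotation of non-overlapping protein-coding genes.

    Each gene has 1-8 CDS exons; the primary transcript (``<gene>.t1``)
    carries all exons, and 0-2 secondary transcripts carry contiguous exon
    subsets, so the gene's CDS union always equals its longest ORF.
    Deterministic: the same (spec, seed) yields byte-identical GTF text.
    """
    if spec.n_genes < 10:
        raise SimulationError("n_genes must be >= 10")
    rng = np.random.default_rng([seed, 0])
    mu = math.log(spec.mean_cds_length) - spec.cds_length_sigma**2 / 2
    lengths = np.clip(
        rng.lognormal(mu, spec.cds_length_sigma, size=spec.n_genes),
        spec.min_cds_length,
        spec.max_cds_length,
    ).astype(int)

    chroms = [f"chr{i + 1}" for i in range(spec.n_chromosomes)]
    cursors = {c: 1000 for c in chroms}
    genes: list[GeneModel] = []
    gtf_lines: list[str] = []
    for i in range(spec.n_genes):
        gid, gname = f"g{i:04d}", f"GENE{i:04d}"
        chrom = chroms[i % spec.n_chromosomes]
        total = int(lengths[i])
        n_exons = int(rng.integers(1, spec.max_exons + 1))
        n_exons = min(n_exons, max(1, total // 100))
        # Exon lengths: minimum 60 bp each, remainder spread by Dirichlet draw.
        base = 60
        extra = rng.multinomial(total - base * n_exons, rng.dirichlet(np.ones(n_exons)))
        exon_lengths = (extra + base).tolist()
        start = cursors[chrom]
        exons: list[GenomicInterval] = []
        pos = start
        for j, elen in enumerate(exon_lengths):
            exons.append(GenomicInterval(chrom, pos, pos + int(elen)))
            pos += int(elen)
            if j < n_exons - 1:
                pos += int(rng.integers(*spec.intron_gap))
        cursors[chrom] = pos + int(rng.integers(*spec.intergenic_gap))

        transcripts = [Transcript(f"{gid}.t1", tuple(exons))]
        if n_exons > 1 and spec.max_transcripts > 1:
            sub_ranges = [
                (a, b)
                for a in range(n_exons)
                for b in range(a + 1, n_exons + 1)
                if (a, b) != (0, n_exons)
            ]
            n_extra = int(rng.integers(0, spec.max_transcripts))
            for k in range(n_extra):
                a, b = sub_ranges[int(rng.integers(len(sub_ranges)))]
                transcripts.append(Transcript(f"{gid}.t{k + 2}", tuple(exons[a:b])))
        genes.append(GeneModel(gid, gname, tuple(transcripts)))

        gene_start, gene_end = exons[0].start, exons[-1].end
        attrs = f'gene_id "{gid}"; gene_name "{gname}";'
        gtf_lines.append(
            f"{chrom}\tsim\tgene\t{gene_start + 1}\t{gene_end}\t.\t+\t.\t{attrs}"
        )
        for t in transcripts:
            tattrs = f'{attrs} transcript_id "{t.transcript_id}";'
            gtf_lines.append(
                f"{chrom}\tsim\ttranscript\t{t.cds[0].start + 1}\t{t.cds[-1].end}"
                f"\t.\t+\t.\t{tattrs}"
            )
            for iv in t.cds:
                gtf_lines.append(
                    f"{chrom}\tsim\tCDS\t{iv.start + 1}\t{iv.end}\t.\t+\t0\t{tattrs}"
                )

    n_drivers = int(round(spec.driver_fraction * spec.n_genes))
    driver_idx = rng.permutation(spec.n_genes)[:n_drivers]
    drivers = frozenset(genes[i].gene_name for i in driver_idx)
    chrom_lengths = {c: cursors[c] + 1000 for c in chroms}
    return SyntheticGenome(
        genes=tuple(genes),
        gtf="\n".join(gtf_lines) + "\n",
        driver_genes=drivers,
        chrom_lengths=chrom_lengths,
    )


def generate_panels(
    genome: SyntheticGenome,
    panel_specs: Sequence[PanelSpec] = DEFAULT_PANEL_SPECS,
    seed: int = 0,
) -> dict[str, tuple[str, ...]]:
    """Nested gene panels biased toward driver genes.

    Genes are ordered drivers-first (each block shuffled deterministically);
    every panel takes the prefix whose summed longest-ORF length reaches its
    target fraction of the CDS union, so smaller panels are subsets of larger
    ones and all panels are maximally driver-enriched.
    """
    rng = np.random.default_rng([seed, 1])
    names = [g.gene_name for g in genome.genes]
    orf_len = {
        g.gene_name: sum(iv.length for iv in max(
            g.transcripts, key=lambda t: (t.cds_length, t.transcript_id)
        ).cds)
        for g in genome.genes
    }
    drivers = sorted(genome.driver_genes)
    fillers = sorted(set(names) - genome.driver_genes)
    order = [drivers[i] for i in rng.permutation(len(drivers))]
    order += [fillers[i] for i in rng.permutation(len(fillers))]
    union_bp = sum(orf_len[n] for n in names)

    panels: dict[str, tuple[str, ...]] = {}
    for spec in panel_specs:
        target = spec.footprint_fraction * union_bp
        if spec.footprint_fraction > 1.0:
            raise SimulationError(
                f"panel {spec.name}: footprint fraction {spec.footprint_fraction} > 1"
            )
        acc, chosen = 0, []
        for gname in order:
            if acc >= target:
                break
            chosen.append(gname)
            acc += orf_len[gname]
        panels[spec.name] = tuple(chosen)
    return panels


@dataclass(frozen=True)
class TruthRow:
    sample_id: str
    tumour_type: str
    drawn_tmb: float
    n_exome: int
    n_nonsynonymous: int
    panel_counts: dict[str, int]


class _SampleMachinery:
    """Per-genome caches shared across samples (exon maps, gene weights)."""

    def __init__(self, config: SimulationConfig, genome: SyntheticGenome,
                 panels: Mapping[str, Sequence[str]]):
        self.config = config
        self.genome = genome
        self.panels = {name: frozenset(genes) for name, genes in panels.items()}
        self.gene_names = [g.gene_name for g in genome.genes]
        self.exons: list[tuple[str, np.ndarray, np.ndarray]] = []
        orf_lengths = []
        for g in genome.genes:
            primary = max(g.transcripts, key=lambda t: (t.cds_length, t.transcript_id))
            starts = np.array([iv.start for iv in primary.cds])
            cums = np.concatenate([[0], np.cumsum([iv.length for iv in primary.cds])])
            self.exons.append((primary.cds[0].chrom, starts, cums))
            orf_lengths.append(primary.cds_length)
        self.orf_lengths = np.array(orf_lengths, dtype=float)
        self.cds_union_mb = float(self.orf_lengths.sum()) / 1e6
        weights = self.orf_lengths.copy()
        is_driver = np.array(
            [n in genome.driver_genes for n in self.gene_names], dtype=bool
        )
        weights[is_driver] *= config.driver_enrichment
        self.gene_probs = weights / weights.sum()
        self.classes = np.array(sorted(config.variant_mix))
        self.class_probs = np.array([config.variant_mix[c] for c in self.classes])
        self.panel_masks = {
            name: np.array([n in genes for n in self.gene_names], dtype=bool)
            for name, genes in self.panels.items()
        }


def _draw_alleles(rng: np.random.Generator, vclass: str) -> tuple[str, str]:
    if vclass == SNV:
        ref = str(rng.choice(BASES))
        alt = str(rng.choice(BASES[BASES != ref]))
        return ref, alt
    if vclass == MNV:
        k = int(rng.integers(2, 4))
        ref = "".join(rng.choice(BASES, size=k))
        alt = "".join(str(rng.choice(BASES[BASES != b])) for b in ref)
        return ref, alt
    k = int(rng.integers(1, 11))
    anchor = str(rng.choice(BASES))
    tail = "".join(rng.choice(BASES, size=k))
    if rng.random() < 0.5:
        return anchor, anchor + tail  # insertion
    return anchor + tail, anchor  # deletion


def simulate_sample(
    config: SimulationConfig,
    genome: SyntheticGenome,
    panels: Mapping[str, Sequence[str]],
    sample_id: str,
    tumour_type: str,
    _machinery: _SampleMachinery | None = None,
) -> tuple[list[SomaticVariant], TruthRow]:
    """Draw one tumour's somatic calls and the matching truth record.

    The target TMB (mutations per CDS-Mb) comes from the tumour type's
    log-normal, optionally inflated by the hypermutator multiplier; the
    Poisson mutation count is placed over genes' longest-ORF bases with
    driver-enriched multinomial weights.
    """
    config.validate()
    m = _machinery or _SampleMachinery(config, genome, panels)
    try:
        dist = config.tmb_distribution[tumour_type]
    except KeyError:
        raise SimulationError(f"no TMB distribution for tumour type {tumour_type!r}")
    rng = np.random.default_rng([config.seed, 3, _sid_key(sample_id)])
    tmb = float(rng.lognormal(dist.mu, dist.sigma))
    if rng.random() < dist.hypermutator_fraction:
        tmb *= dist.hypermutator_multiplier
    n = int(rng.poisson(tmb * m.cds_union_mb))
    gene_counts = rng.multinomial(n, m.gene_probs)

    variants: list[tuple[int, int, SomaticVariant]] = []
    chrom_rank = {c: i for i, c in enumerate(sorted(genome.chrom_lengths))}
    n_ns = 0
    for gi in np.nonzero(gene_counts)[0]:
        chrom, starts, cums = m.exons[gi]
        for _ in range(int(gene_counts[gi])):
            offset = int(rng.integers(cums[-1]))
            ei = int(np.searchsorted(cums, offset, side="right")) - 1
            gpos = int(starts[ei]) + (offset - int(cums[ei]))  # 0-based
            vclass = str(rng.choice(m.classes, p=m.class_probs))
            ref, alt = _draw_alleles(rng, vclass)
            ns = bool(rng.random() < config.nonsynonymous_fraction[vclass])
            n_ns += ns
            v = make_variant(sample_id, chrom, gpos + 1, ref, alt, ns)
            variants.append((chrom_rank[chrom], gpos, v))
    variants.sort(key=lambda t: (t[0], t[1], t[2].ref, t[2].alt))
    ordered = [v for _, _, v in variants]

    panel_counts = {
        name: int(gene_counts[mask].sum()) for name, mask in m.panel_masks.items()
    }
    truth = TruthRow(
        sample_id=sample_id,
        tumour_type=tumour_type,
        drawn_tmb=tmb,
        n_exome=n,
        n_nonsynonymous=n_ns,
        panel_counts=panel_counts,
    )
    return ordered, truth


def variants_to_vcf(
    variants: Sequence[SomaticVariant], chrom_lengths: Mapping[str, int]
) -> str:
    """Render sorted somatic calls as VCF 4.2 text with NS and CLASS INFO keys."""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=NS,Number=1,Type=Integer,Description='
        '"1 if the variant is non-synonymous, else 0">',
        '##INFO=<ID=CLASS,Number=1,Type=String,Description='
        '"Variant class: SNV, MNV or INDEL">',
    ]
    for chrom in sorted(chrom_lengths):
        lines.append(f"##contig=<ID={chrom},length={chrom_lengths[chrom]}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for v in variants:
        ns = int(bool(v.non_synonymous))
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t"
            f"NS={ns};CLASS={v.vclass}"
        )
    return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class SyntheticCohort:
    config: SimulationConfig
    genome: SyntheticGenome
    panels: dict[str, tuple[str, ...]]
    variants_by_sample: dict[str, list[SomaticVariant]]
    truth: "pd.DataFrame"
    metadata: "pd.DataFrame"

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        (out / "panels").mkdir(parents=True, exist_ok=True)
        (out / "vcf").mkdir(exist_ok=True)
        (out / "annotation.gtf").write_text(self.genome.gtf)
        for name, genes in self.panels.items():
            body = f"# panel {name}\n" + "\n".join(genes) + "\n"
            (out / "panels" / f"{name}.txt").write_text(body)
        for sid, variants in self.variants_by_sample.items():
            (out / "vcf" / f"{sid}.vcf").write_text(
                variants_to_vcf(variants, self.genome.chrom_lengths)
            )
        self.metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        cfg = asdict(self.config)
        cfg["panels"] = [asdict(p) for p in self.config.panels]
        (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
        return out


def simulate_cohort(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> SyntheticCohort:
    """Generate a full cohort: annotation, panels, per-sample VCFs and truth."""
    import pandas as pd

    config.validate()
    genome = generate_annotation(config.genome, config.seed)
    panels = generate_panels(genome, config.panels, config.seed)
    machinery = _SampleMachinery(config, genome, panels)

    type_names = sorted(config.tumour_type_mix)
    type_probs = [config.tumour_type_mix[t] for t in type_names]
    rng = np.random.default_rng([config.seed, 2])
    assigned = rng.choice(type_names, size=config.n_samples, p=type_probs)

    variants_by_sample: dict[str, list[SomaticVariant]] = {}
    truth_rows = []
    for i in range(config.n_samples):
        sid = f"S{i:04d}"
        variants, truth = simulate_sample(
            config, genome, panels, sid, str(assigned[i]), _machinery=machinery
        )
        variants_by_sample[sid] = variants
        row = {
            "sample_id": truth.sample_id,
            "tumour_type": truth.tumour_type,
            "drawn_tmb": truth.drawn_tmb,
            "n_exome": truth.n_exome,
            "n_nonsynonymous": truth.n_nonsynonymous,
        }
        row.update({f"n_panel_{k}": v for k, v in truth.panel_counts.items()})
        truth_rows.append(row)

    truth_df = pd.DataFrame(truth_rows)
    metadata = truth_df[["sample_id", "tumour_type"]].copy()
    cohort = SyntheticCohort(
        config=config,
        genome=genome,
        panels=panels,
        variants_by_sample=variants_by_sample,
        truth=truth_df,
        metadata=metadata,
    )
    if out_dir is not None:
        cohort.write(out_dir)
    return cohort
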