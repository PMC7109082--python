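"""Gene annotation handling and panel footprint construction.

A targeted panel's interrogated region ("footprint") is approximated by the
longest open reading frame of each panel gene: for every gene the transcript
with the largest summed CDS length is taken, and the resulting intervals are
merged. Footprint size in Mb is the panel-TMB denominator; the exome-TMB
denominator is the conventional 30 Mb constant regardless of the true CDS
union size (a config override supports sensitivity analysis).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils

from .intervals import FootprintIndex, GenomicInterval, length_mb, merge_intervals

EXOME_MB = 30.0


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    cds: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.cds:
            raise AnnotationError(f"transcript {self.transcript_id} has no CDS")
        chroms = {iv.chrom for iv in self.cds}
        if len(chroms) > 1:
            raise AnnotationError(
                f"transcript {self.transcript_id} spans chromosomes {sorted(chroms)}"
            )
        ivs = sorted(self.cds, key=lambda iv: iv.start)
        for a, b in zip(ivs, ivs[1:]):
            if b.start < a.end:
                raise AnnotationError(
                    f"transcript {self.transcript_id} has overlapping CDS intervals"
                )

    @property
    def cds_length(self) -> int:
        return sum(iv.length for iv in self.cds)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    gene_name: str
    transcripts: tuple[Transcript, ...]


def longest_orf_intervals(gene: GeneModel) -> list[GenomicInterval]:
    """CDS intervals of the transcript with maximal summed CDS length.

    Ties are broken by the lexicographically smallest transcript_id so the
    choice is deterministic across runs and annotation orderings.
    """
    if not gene.transcripts:
        raise AnnotationError(f"gene {gene.gene_name} has no CDS-bearing transcript")
    best_len = max(t.cds_length for t in gene.transcripts)
    best = min(
        (t for t in gene.transcripts if t.cds_length == best_len),
        key=lambda t: t.transcript_id,
    )
    return sorted(best.cds, key=lambda iv: (iv.chrom, iv.start))


def read_gene_models(source: str | Path, *, from_string: bool = False) -> list[GeneModel]:
    """Read gene models from GTF/GFF3 (CDS features only).

    GTF/GFF 1-based inclusive coordinates are converted to 0-based half-open.
    Required attributes: gene_id, transcript_id; gene_name falls back to gene_id.
    """
    db = gffutils.create_db(
        str(source) if not from_string else source,
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        from_string=from_string,
    )
    per_gene: dict[str, dict] = {}
    for cds in db.features_of_type("CDS"):
        try:
            gid = cds.attributes["gene_id"][0]
            tid = cds.attributes["transcript_id"][0]
        except KeyError as exc:
            raise AnnotationError(
                f"CDS feature at {cds.seqid}:{cds.start} lacks attribute {exc}"
            ) from None
        gname = cds.attributes.get("gene_name", [gid])[0]
        rec = per_gene.setdefault(gid, {"name": gname, "transcripts": {}})
        rec["transcripts"].setdefault(tid, []).append(
            GenomicInterval(cds.seqid, cds.start - 1, cds.end)
        )
    genes = []
    for gid in sorted(per_gene):
        rec = per_gene[gid]
        transcripts = tuple(
            Transcript(tid, tuple(sorted(ivs, key=lambda iv: iv.start)))
            for tid, ivs in sorted(rec["transcripts"].items())
        )
        genes.append(GeneModel(gid, rec["name"], transcripts))
    return genes


def read_panel_gene_list(path: str | Path) -> list[str]:
    """Plain-text panel definition: one gene symbol per line, '#' comments."""
    names = []
    for line in Path(path).read_text().splitlines():
        sym = line.split("#", 1)[0].strip()
        if sym:
            names.append(sym)
    return names


@dataclass(frozen=True)
class PanelDesign:
    """A named gene panel with its derived longest-ORF genomic footprint."""

    name: str
    genes: frozenset[str]
    footprint: tuple[GenomicInterval, ...]
    footprint_mb: float
    matched_genes: tuple[str, ...]
    unmatched_genes: tuple[str, ...] = ()
    _index: FootprintIndex = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.footprint_mb <= 0:
            raise AnnotationError(f"panel {self.name} has empty footprint")
        object.__setattr__(self, "_index", FootprintIndex(self.footprint))

    @property
    def index(self) -> FootprintIndex:
        return self._index


def build_panel_footprint(
    name: str,
    panel_genes: Iterable[str],
    annotation: Sequence[GeneModel],
    synonyms: Mapping[str, str] | None = None,
) -> PanelDesign:
    """Resolve panel gene symbols against the annotation and merge their longest ORFs.

    Matching is by gene_name, case-sensitive exact match; an optional synonym
    map (alias -> annotation symbol) is applied first. Genes absent from the
    annotation, or present without any CDS, are reported via warnings and the
    panel's unmatched list. Zero matches is a hard error.
    """
    panel_genes = list(dict.fromkeys(panel_genes))
    if not panel_genes:
        raise AnnotationError(f"panel {name}: empty gene list")
    by_name: dict[str, GeneModel] = {}
    for g in annotation:
        by_name.setdefault(g.gene_name, g)
    matched, unmatched, intervals = [], [], []
    for sym in panel_genes:
        key = synonyms.get(sym, sym) if synonyms else sym
        gene = by_name.get(key)
        if gene is None:
            unmatched.append(sym)
            continue
        try:
            intervals.extend(longest_orf_intervals(gene))
        except AnnotationError:
            unmatched.append(sym)
            warnings.warn(
                f"panel {name}: gene {sym} has no annotated CDS; excluded from footprint"
            )
            continue
        matched.append(sym)
    if not matched:
        raise AnnotationError(f"panel {name}: no panel gene matched the annotation")
    if unmatched:
        warnings.warn(
            f"panel {name}: {len(unmatched)} gene(s) not matched in annotation: "
            + ", ".join(unmatched[:10])
        )
    footprint = merge_intervals(intervals)
    return PanelDesign(
        name=name,
        genes=frozenset(panel_genes),
        footprint=tuple(footprint),
        footprint_mb=length_mb(footprint),
        matched_genes=tuple(matched),
        unmatched_genes=tuple(unmatched),
    )


@dataclass(frozen=True)
class ExomeModel:
    """Union of all annotated CDS, with the fixed 30 Mb TMB denominator.

    ``denominator_mb`` stays 30.0 by convention even when the annotation's true
    CDS union differs; pass an override for sensitivity analyses or for
    miniature synthetic genomes where panel and exome TMB must share a scale.
    """

    regions: tuple[GenomicInterval, ...]
    denominator_mb: float = EXOME_MB
    _index: FootprintIndex = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.denominator_mb <= 0:
            raise AnnotationError("exome denominator must be positive")
        object.__setattr__(self, "_index", FootprintIndex(self.regions))

    @property
    def index(self) -> FootprintIndex:
        return self._index

    @property
    def regions_mb(self) -> float:
        return sum(iv.length for iv in self.regions) / 1e6


def build_exome_model(
    annotation: Sequence[GeneModel], denominator_mb: float | str = EXOME_MB
) -> ExomeModel:
    """Exome = merged union of every CDS of every transcript.

    ``denominator_mb="cds"`` sets the denominator to the true CDS-union size.
    """
    regions = merge_intervals(
        iv for g in annotation for t in g.transcripts for iv in t.cds
    )
    if denominator_mb == "cds":
        denom = length_mb(regions)
    else:
        denom = float(denominator_mb)
    return ExomeModel(regions=tuple(regions), denominator_mb=denom)


def write_footprint_bed(panel: PanelDesign, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in panel.footprint:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{panel.name}\n")


def write_footprint_summary(panels: Sequence[PanelDesign], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("panel\tn_genes_matched\tn_genes_unmatched\tfootprint_mb\n")
        for p in panels:
            fh.write(
                f"{p.name}\t{len(p.matched_genes)}\t{len(p.unmatched_genes)}\t"
                f"{p.footprint_mb:.6f}\n"
            )
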