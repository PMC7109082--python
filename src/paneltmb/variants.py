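"""Somatic variant reading, classification and footprint membership.

Variant classes follow the usual somatic-call taxonomy: SNV (single-base
substitution), MNV (equal-length multi-base substitution) and indel
(length-changing event). Footprint membership uses the reference-span
any-overlap rule: an event counts for a panel if any base of its reference
span lies inside the panel footprint, which is how a capture design would
observe it. Inputs are assumed normalized; no re-left-alignment is done.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from cyvcf2 import VCF

from .intervals import FootprintIndex, GenomicInterval

SNV = "SNV"
MNV = "MNV"
INDEL = "INDEL"
VARIANT_CLASSES = (SNV, MNV, INDEL)


class VariantError(ValueError):
    pass


def classify_variant(ref: str, alt: str) -> str:
    """Classify a normalized ref/alt pair as SNV, MNV or INDEL."""
    if not ref or not alt:
        raise VariantError(f"empty allele in {ref!r}>{alt!r}")
    if ref == alt:
        raise VariantError(f"ref equals alt ({ref!r}); not a variant")
    if len(ref) == len(alt):
        return SNV if len(ref) == 1 else MNV
    return INDEL


@dataclass(frozen=True)
class SomaticVariant:
    """One normalized somatic event (VCF 1-based position, anchor-base indels)."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    vclass: str
    non_synonymous: bool | None = None

    def __post_init__(self) -> None:
        expected = classify_variant(self.ref, self.alt)
        if self.vclass != expected:
            raise VariantError(
                f"{self.chrom}:{self.pos} {self.ref}>{self.alt}: class "
                f"{self.vclass} inconsistent with alleles (expected {expected})"
            )

    @property
    def ref_span(self) -> GenomicInterval:
        """0-based half-open span of the reference allele."""
        return GenomicInterval(self.chrom, self.pos - 1, self.pos - 1 + len(self.ref))


def make_variant(
    sample_id: str,
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    non_synonymous: bool | None = None,
) -> SomaticVariant:
    return SomaticVariant(
        sample_id, chrom, pos, ref, alt, classify_variant(ref, alt), non_synonymous
    )


def read_somatic_vcf(
    path: str | Path,
    sample_id: str | None = None,
    ns_key: str = "NS",
) -> list[SomaticVariant]:
    """Read passing somatic calls from a VCF, one variant per ALT allele.

    Records failing FILTER (anything other than PASS / '.') are excluded.
    Symbolic and breakend ALT alleles are skipped with a warning. The
    non-synonymous flag is taken from INFO[ns_key] (0/1) when present and left
    unset otherwise.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.name.removesuffix(".gz").removesuffix(".vcf")
    out: list[SomaticVariant] = []
    vcf = VCF(str(path))
    try:
        for rec in vcf:
            try:
                if rec.FILTER is not None:  # cyvcf2: None means PASS or '.'
                    continue
                ns_raw = rec.INFO.get(ns_key)
                ns = None if ns_raw is None else bool(int(ns_raw))
                for alt in rec.ALT:
                    if alt.startswith("<") or "[" in alt or "]" in alt or alt == "*":
                        warnings.warn(
                            f"{path.name}: skipping symbolic allele {alt} at "
                            f"{rec.CHROM}:{rec.POS}"
                        )
                        continue
                    out.append(make_variant(sample_id, rec.CHROM, rec.POS, rec.REF, alt, ns))
            except (VariantError, ValueError, TypeError) as exc:
                raise VariantError(
                    f"malformed record in {path} at {rec.CHROM}:{rec.POS}: {exc}"
                ) from exc
    finally:
        vcf.close()
    return out


def in_footprint(
    variant: SomaticVariant,
    footprint: FootprintIndex | Sequence[GenomicInterval],
) -> bool:
    """True iff any base of the variant's reference span overlaps the footprint."""
    index = footprint if isinstance(footprint, FootprintIndex) else FootprintIndex(footprint)
    span = variant.ref_span
    return index.overlaps(span.chrom, span.start, span.end)


def write_variant_tsv(variants: Iterable[SomaticVariant], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tchrom\tpos\tref\talt\tvclass\tnon_synonymous\n")
        for v in variants:
            ns = "" if v.non_synonymous is None else int(v.non_synonymous)
            fh.write(
                f"{v.sample_id}\t{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.vclass}\t{ns}\n"
            )
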