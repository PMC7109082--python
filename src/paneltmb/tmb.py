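"""Per-sample TMB and mutational-load computation.

TMB = somatic events (SNV + MNV + indel) per Mb of interrogated sequence:
panel TMB divides the in-footprint count by the panel footprint size, exome
TMB divides the in-exome count by the fixed 30 Mb exome convention (or its
override). Mutational load (ML) is the genome-wide count of non-synonymous
coding events, not restricted to any footprint.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .annotation import ExomeModel, PanelDesign
from .variants import SomaticVariant, in_footprint


class TmbError(ValueError):
    pass


def panel_tmb(variants: Sequence[SomaticVariant], panel: PanelDesign) -> float:
    """In-footprint event count divided by the panel footprint in Mb."""
    if panel.footprint_mb <= 0:
        raise TmbError(f"panel {panel.name}: footprint size must be positive")
    count = sum(1 for v in variants if in_footprint(v, panel.index))
    return count / panel.footprint_mb


def exome_tmb(variants: Sequence[SomaticVariant], exome: ExomeModel) -> float:
    """In-exome event count divided by the exome denominator (30 Mb convention)."""
    count = sum(1 for v in variants if in_footprint(v, exome.index))
    return count / exome.denominator_mb


def mutational_load(variants: Sequence[SomaticVariant]) -> int:
    """Count of non-synonymous events; requires every variant to carry the flag."""
    unset = sorted({v.sample_id for v in variants if v.non_synonymous is None})
    if unset:
        raise TmbError(
            "mutational load requested but non-synonymous annotation is missing "
            f"for sample(s): {', '.join(unset)}"
        )
    return sum(1 for v in variants if v.non_synonymous)


@dataclass(frozen=True)
class SampleProfile:
    sample_id: str
    tumour_type: str
    exome_tmb: float
    panel_tmb: dict[str, float]
    mutational_load: int | None = None

    def __post_init__(self) -> None:
        if self.exome_tmb < 0 or any(t < 0 for t in self.panel_tmb.values()):
            raise TmbError(f"sample {self.sample_id}: negative TMB")
        if self.mutational_load is not None and self.mutational_load < 0:
            raise TmbError(f"sample {self.sample_id}: negative mutational load")


def build_profiles(
    variants_by_sample: Mapping[str, Sequence[SomaticVariant]],
    tumour_types: Mapping[str, str],
    panels: Sequence[PanelDesign],
    exome: ExomeModel,
    with_ml: bool = True,
    nonsynonymous_only: bool = False,
) -> list[SampleProfile]:
    """Compute the full per-sample profile table.

    ``nonsynonymous_only`` restricts the TMB numerators to flagged
    non-synonymous events (requires annotation); ML always counts
    non-synonymous events genome-wide.
    """
    profiles = []
    for sid in sorted(variants_by_sample):
        variants = list(variants_by_sample[sid])
        if sid not in tumour_types:
            raise TmbError(f"sample {sid} missing from metadata")
        ml = mutational_load(variants) if with_ml else None
        counted = variants
        if nonsynonymous_only:
            unset = [v for v in variants if v.non_synonymous is None]
            if unset:
                raise TmbError(
                    f"sample {sid}: nonsynonymous-only counting requested but "
                    f"{len(unset)} variant(s) lack the annotation"
                )
            counted = [v for v in variants if v.non_synonymous]
        profiles.append(
            SampleProfile(
                sample_id=sid,
                tumour_type=tumour_types[sid],
                exome_tmb=exome_tmb(counted, exome),
                panel_tmb={p.name: panel_tmb(counted, p) for p in panels},
                mutational_load=ml,
            )
        )
    return profiles


def profiles_to_frame(profiles: Sequence[SampleProfile]) -> pd.DataFrame:
    panel_names = sorted(profiles[0].panel_tmb) if profiles else []
    rows = []
    for p in profiles:
        row = {
            "sample_id": p.sample_id,
            "tumour_type": p.tumour_type,
            "exome_tmb": p.exome_tmb,
        }
        row.update({name: p.panel_tmb[name] for name in panel_names})
        row["mutational_load"] = p.mutational_load
        rows.append(row)
    return pd.DataFrame(rows)


def write_profiles_tsv(profiles: Sequence[SampleProfile], path: str | Path) -> None:
    profiles_to_frame(profiles).to_csv(path, sep="\t", index=False)


def read_profiles_tsv(path: str | Path) -> list[SampleProfile]:
    """Inverse of :func:`write_profiles_tsv`; non-reserved columns are panels."""
    df = pd.read_csv(path, sep="\t")
    reserved = {"sample_id", "tumour_type", "exome_tmb", "mutational_load"}
    missing = {"sample_id", "tumour_type", "exome_tmb"} - set(df.columns)
    if missing:
        raise TmbError(f"profile table missing column(s): {', '.join(sorted(missing))}")
    panel_names = [c for c in df.columns if c not in reserved]
    profiles = []
    for _, row in df.iterrows():
        ml = row.get("mutational_load")
        profiles.append(
            SampleProfile(
                sample_id=str(row["sample_id"]),
                tumour_type=str(row["tumour_type"]),
                exome_tmb=float(row["exome_tmb"]),
                panel_tmb={name: float(row[name]) for name in panel_names},
                mutational_load=None if pd.isna(ml) else int(ml),
            )
        )
    return profiles
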