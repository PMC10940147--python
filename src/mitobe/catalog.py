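"""Classify pathogenic mtDNA point mutations by required editor chemistry.

Deaminase editors reach only the four transition changes. To *correct* a
mutation the editor must act on the mutant base (or its strand partner):

    G>A  -> mitoABE, edited strand top      (mutant A on top, A->G)
    C>T  -> mitoABE, edited strand bottom   (mutant T on top is A on bottom)
    T>C  -> mitoCBE, edited strand top      (mutant C on top, C->T)
    A>G  -> mitoCBE, edited strand bottom   (mutant G on top is C on bottom)

Transversions are unreachable by either chemistry. The same table run in
the forward direction gives the editor that would *create* the mutation
from wild type (disease modelling).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .designability import DesignabilityTrack
from .genome import CircularGenome

_CLASS_NAMES = {
    ("A", "G"): "A•T→G•C",
    ("C", "T"): "C•G→T•A",
    ("G", "A"): "G•C→A•T",
    ("T", "C"): "T•A→C•G",
}

# (ref, alt) -> (corrective editor, corrective edited strand)
_CORRECTIVE = {
    ("G", "A"): ("mitoABE", "top"),
    ("C", "T"): ("mitoABE", "bottom"),
    ("T", "C"): ("mitoCBE", "top"),
    ("A", "G"): ("mitoCBE", "bottom"),
}

# (ref, alt) -> editor that would create alt from ref
_MODELING = {
    ("A", "G"): ("mitoABE", "top"),
    ("T", "C"): ("mitoABE", "bottom"),
    ("C", "T"): ("mitoCBE", "top"),
    ("G", "A"): ("mitoCBE", "bottom"),
}


@dataclass(frozen=True)
class MutationRecord:
    position: int  # 1-based
    ref: str
    alt: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref equals alt")
        for b in (self.ref, self.alt):
            if b not in "ACGT":
                raise ValueError(f"invalid base {b!r}")
        if self.position < 1:
            raise ValueError("position must be >= 1")

    @property
    def name(self) -> str:
        return f"m.{self.position}{self.ref}>{self.alt}"


@dataclass(frozen=True)
class CorrectionPlan:
    mutation_class: str
    corrective_editor: str | None
    corrective_edited_strand: str | None
    modeling_editor: str | None
    modeling_edited_strand: str | None
    designable_by: tuple[str, ...] = ()


def classify_mutation(record: MutationRecord) -> CorrectionPlan:
    key = (record.ref, record.alt)
    mclass = _CLASS_NAMES.get(key, "transversion")
    corr = _CORRECTIVE.get(key)
    model = _MODELING.get(key)
    return CorrectionPlan(
        mutation_class=mclass,
        corrective_editor=corr[0] if corr else None,
        corrective_edited_strand=corr[1] if corr else None,
        modeling_editor=model[0] if model else None,
        modeling_edited_strand=model[1] if model else None,
    )


def read_catalog(path: str | Path) -> list[MutationRecord]:
    """Tab-separated catalog with header: position, ref, alt, label."""
    df = pd.read_csv(path, sep="\t", dtype={"position": int, "ref": str,
                                            "alt": str, "label": str})
    required = {"position", "ref", "alt"}
    if not required <= set(df.columns):
        raise ValueError(f"catalog must have columns {sorted(required)}")
    if "label" not in df.columns:
        df["label"] = ""
    return [MutationRecord(int(r.position), r.ref.upper(), r.alt.upper(),
                           str(r.label) if pd.notna(r.label) else "")
            for r in df.itertuples()]


def catalog_report(catalog: list[MutationRecord],
                   genome: CircularGenome | None = None,
                   tracks: dict[str, DesignabilityTrack] | None = None,
                   ) -> pd.DataFrame:
    """Per-record correction plans plus designability annotation.

    The returned frame carries aggregate percentages in ``df.attrs``:
    per-class shares and the share of records correctable by either
    deaminase chemistry (and, if tracks were given, also designable).
    """
    if not catalog:
        raise ValueError("empty catalog")
    rows = []
    for rec in catalog:
        if genome is not None:
            if rec.position > genome.length:
                raise ValueError(f"{rec.name}: position outside genome")
            gbase = genome.sequence[rec.position - 1]
            if gbase != rec.ref:
                raise ValueError(
                    f"{rec.name}: genome has {gbase} at {rec.position}, not {rec.ref}")
        plan = classify_mutation(rec)
        designable_by = tuple(
            name for name, t in (tracks or {}).items()
            if t.designable(rec.position))
        rows.append({
            "mutation": rec.name, "position": rec.position, "ref": rec.ref,
            "alt": rec.alt, "label": rec.label,
            "class": plan.mutation_class,
            "corrective_editor": plan.corrective_editor or "none",
            "corrective_edited_strand": plan.corrective_edited_strand or "",
            "modeling_editor": plan.modeling_editor or "none",
            "designable_by": ",".join(designable_by),
            "correctable": plan.corrective_editor is not None,
        })
    df = pd.DataFrame(rows)
    total = len(df)
    class_pct = (df["class"].value_counts() / total * 100).to_dict()
    correctable_pct = float(df["correctable"].sum()) / total * 100
    if tracks:
        ok = df["correctable"] & (df["designable_by"] != "")
        correctable_designable_pct = float(ok.sum()) / total * 100
    else:
        correctable_designable_pct = None
    df.attrs["class_percent"] = class_pct
    df.attrs["correctable_percent"] = correctable_pct
    df.attrs["correctable_designable_percent"] = correctable_designable_pct
    return df
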