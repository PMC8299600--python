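"""Cohort data model, TSV readers/writers, neoantigen calling and baselines.

A cohort bundles per-patient clinical records (overall survival in days plus
an event indicator), the patient's mutant/wild-type 9-mer pairs with predicted
IC50 values, and optionally MAF-style mutation records used for
missense-load counting. Neoantigen calling applies the strict affinity rule:
the mutant peptide must bind (IC50 < 500 nM) while its wild-type counterpart
must not (IC50 > 500 nM).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .peptide_features import PeptidePair

IC50_BINDER_NM = 500.0

MISSENSE = "Missense_Mutation"
MAF_CLASSES = {
    "Missense_Mutation", "Nonsense_Mutation", "Silent", "Splice_Site",
    "Frame_Shift_Del", "Frame_Shift_Ins", "In_Frame_Del", "In_Frame_Ins",
    "Nonstop_Mutation", "Translation_Start_Site", "3'UTR", "5'UTR",
    "3'Flank", "5'Flank", "Intron", "RNA", "IGR", "Targeted_Region",
}


@dataclass(frozen=True)
class ClinicalRecord:
    patient_id: str
    os_days: float
    os_event: int
    age: float | None = None
    subtype: str | None = None

    def __post_init__(self) -> None:
        if not (self.os_days >= 0 and self.os_days == self.os_days):
            raise ValueError(f"os_days must be finite and >= 0 for {self.patient_id}")
        if self.os_event not in (0, 1):
            raise ValueError(f"os_event must be 0 or 1 for {self.patient_id}")


@dataclass(frozen=True)
class MutationRecord:
    patient_id: str
    gene: str
    variant_classification: str
    protein_change: str | None = None

    def __post_init__(self) -> None:
        if self.variant_classification not in MAF_CLASSES:
            raise ValueError(
                f"unknown Variant_Classification {self.variant_classification!r}"
            )


@dataclass
class Cohort:
    """Clinical records + peptide pairs (+ optional mutation records)."""

    clinical: list[ClinicalRecord]
    pairs: list[PeptidePair]
    mutations: list[MutationRecord] = field(default_factory=list)
    name: str = "cohort"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = {c.patient_id for c in self.clinical}
        if len(ids) != len(self.clinical):
            raise ValueError("duplicate patient_id in clinical table")
        orphans = sorted({p.patient_id for p in self.pairs} - ids)
        if orphans:
            raise ValueError(
                f"peptide pairs reference patients without clinical records: {orphans[:5]}"
            )

    @property
    def patient_ids(self) -> list[str]:
        return [c.patient_id for c in self.clinical]

    def clinical_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "patient_id": [c.patient_id for c in self.clinical],
                "os_days": [c.os_days for c in self.clinical],
                "os_event": [c.os_event for c in self.clinical],
                "age": [c.age for c in self.clinical],
                "subtype": [c.subtype for c in self.clinical],
            }
        ).set_index("patient_id")
        return df

    def patients_with_pairs(self) -> list[str]:
        """Patients with at least one pair, in clinical order (samples
        without detected neoantigens drop out of featurization)."""
        have = {p.patient_id for p in self.pairs}
        return [pid for pid in self.patient_ids if pid in have]


# ---------------------------------------------------------------------------
# neoantigen calling and simple baselines
# ---------------------------------------------------------------------------

def call_neoantigens(pairs: Iterable[PeptidePair]) -> list[PeptidePair]:
    """Strict binder rule: keep pairs with IC50_MT < 500 and IC50_WT > 500 nM."""
    kept = []
    for p in pairs:
        if p.ic50_mt <= 0 or p.ic50_wt <= 0:
            raise ValueError(f"non-positive IC50 for patient {p.patient_id}")
        if p.ic50_mt < IC50_BINDER_NM and p.ic50_wt > IC50_BINDER_NM:
            kept.append(p)
    return kept


def compute_dai(pair: PeptidePair, scale: str = "nM") -> float:
    """Differential agretopicity index: wild-type minus mutant affinity.

    ``scale="nM"`` (default) is the raw difference in nM; ``scale="log10"``
    takes the difference of log10 affinities instead.
    """
    if scale == "nM":
        return pair.ic50_wt - pair.ic50_mt
    if scale == "log10":
        import math

        return math.log10(pair.ic50_wt) - math.log10(pair.ic50_mt)
    raise ValueError("scale must be 'nM' or 'log10'")


def patient_mean_dai(cohort: Cohort, scale: str = "nM",
                     called_only: bool = True) -> pd.Series:
    """Mean DAI per patient over that patient's (called) pairs.

    Patients without pairs are excluded (no DAI is defined for them).
    """
    pairs = call_neoantigens(cohort.pairs) if called_only else list(cohort.pairs)
    sums: dict[str, list[float]] = {}
    for p in pairs:
        sums.setdefault(p.patient_id, []).append(compute_dai(p, scale))
    order = [pid for pid in cohort.patient_ids if pid in sums]
    return pd.Series({pid: sum(sums[pid]) / len(sums[pid]) for pid in order},
                     name="mean_dai").reindex(order)


def missense_load(cohort: Cohort) -> pd.Series:
    """Missense mutation count per patient; patients with no records count 0."""
    counts: dict[str, int] = {pid: 0 for pid in cohort.patient_ids}
    for m in cohort.mutations:
        if m.variant_classification == MISSENSE and m.patient_id in counts:
            counts[m.patient_id] += 1
    return pd.Series(counts, name="missense_load").reindex(cohort.patient_ids)


def neoantigen_count(cohort: Cohort) -> pd.Series:
    """Called-neoantigen count per patient; absent patients count 0."""
    counts: dict[str, int] = {pid: 0 for pid in cohort.patient_ids}
    for p in call_neoantigens(cohort.pairs):
        counts[p.patient_id] += 1
    return pd.Series(counts, name="neoantigen_count").reindex(cohort.patient_ids)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

PEPTIDE_COLUMNS = ["patient_id", "mt_peptide", "wt_peptide", "mut_pos", "ic50_mt", "ic50_wt"]


def read_peptide_table(path) -> list[PeptidePair]:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str},
                     float_precision="round_trip")
    missing = [c for c in PEPTIDE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"peptide table {path} is missing columns {missing}")
    pairs = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            pairs.append(PeptidePair(
                patient_id=row.patient_id,
                mt_seq=row.mt_peptide,
                wt_seq=row.wt_peptide,
                mut_pos=int(row.mut_pos),
                ic50_mt=float(row.ic50_mt),
                ic50_wt=float(row.ic50_wt),
            ))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}, line {i}: {exc}") from exc
    return pairs


def write_peptide_table(pairs: Sequence[PeptidePair], path) -> None:
    pd.DataFrame(
        [(p.patient_id, p.mt_seq, p.wt_seq, p.mut_pos, p.ic50_mt, p.ic50_wt) for p in pairs],
        columns=PEPTIDE_COLUMNS,
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_clinical_table(path) -> list[ClinicalRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str},
                     float_precision="round_trip")
    for c in ("patient_id", "os_days", "os_event"):
        if c not in df.columns:
            raise ValueError(f"clinical table {path} is missing column {c!r}")
    recs = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            age = getattr(row, "age", None)
            subtype = getattr(row, "subtype", None)
            recs.append(ClinicalRecord(
                patient_id=row.patient_id,
                os_days=float(row.os_days),
                os_event=int(row.os_event),
                age=None if age is None or pd.isna(age) else float(age),
                subtype=None if subtype is None or pd.isna(subtype) else str(subtype),
            ))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}, line {i}: {exc}") from exc
    return recs


def write_clinical_table(records: Sequence[ClinicalRecord], path) -> None:
    pd.DataFrame(
        [(c.patient_id, c.os_days, c.os_event,
          "" if c.age is None else c.age,
          "" if c.subtype is None else c.subtype) for c in records],
        columns=["patient_id", "os_days", "os_event", "age", "subtype"],
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_mutation_table(path) -> list[MutationRecord]:
    """MAF-style TSV with Tumor_Sample_Barcode, Hugo_Symbol, Variant_Classification."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Classification"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"mutation table {path} is missing columns {missing}")
    recs = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            recs.append(MutationRecord(
                patient_id=row.Tumor_Sample_Barcode,
                gene=row.Hugo_Symbol,
                variant_classification=row.Variant_Classification,
                protein_change=getattr(row, "Protein_Change", None),
            ))
        except ValueError as exc:
            raise ValueError(f"{path}, line {i}: {exc}") from exc
    return recs


def write_mutation_table(records: Sequence[MutationRecord], path) -> None:
    pd.DataFrame(
        [(m.patient_id, m.gene, m.variant_classification, m.protein_change or "")
         for m in records],
        columns=["Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Classification",
                 "Protein_Change"],
    ).to_csv(path, sep="\t", index=False)


def read_cohort(peptide_path, clinical_path, mutation_path=None, name: str = "cohort") -> Cohort:
    return Cohort(
        clinical=read_clinical_table(clinical_path),
        pairs=read_peptide_table(peptide_path),
        mutations=read_mutation_table(mutation_path) if mutation_path else [],
        name=name,
    )
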