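"""Intrinsic-feature encoding of mutant/wild-type 9-mer pairs.

Each peptide of a pair (mutant role ``MT``, wild-type role ``WT``) is encoded
with descriptor components, composition-class flags, molecular weights,
physico-chemical properties, class fractions and Shannon entropy at several
sequence units: every absolute position, every adjacent dipeptide and
tripeptide, the whole sequence, and units anchored at the mutated position.
Mutation-anchored units that would extend past the peptide ends are carried as
masked (missing) entries so that every pair maps onto one fixed, ordered
feature vocabulary. Patient-level vectors are the element-wise mean over that
patient's neoantigens, ignoring masked entries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from ._residues import (
    BOMAN,
    CLASS_NAMES,
    EISENBERG,
    PEPTIDE_LENGTH,
    RESIDUE_MASS,
    STANDARD_AA,
    WATER_MASS,
    validate_sequence,
)
from .descriptors import load_class_table, load_descriptor_table

ROLES = ("MT", "WT")

PHYSCHEM_NAMES = (
    "aliphatic_index",
    "boman",
    "charge_pH7",
    "hydrophobic_moment",
    "gravy",
    "instability_index",
    "MW",
    "pI",
)

_AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}
_MASS_VEC = np.array([RESIDUE_MASS[a] for a in STANDARD_AA])
_EISENBERG_VEC = np.array([EISENBERG[a] for a in STANDARD_AA])
_BOMAN_VEC = np.array([BOMAN[a] for a in STANDARD_AA])


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeptidePair:
    """One neoantigen record: a mutant 9-mer, its wild-type twin and IC50s.

    ``mut_pos`` is 1-based; the two sequences must differ at exactly that
    position. IC50 values are predicted binding affinities in nM (> 0).
    """

    patient_id: str
    mt_seq: str
    wt_seq: str
    mut_pos: int
    ic50_mt: float
    ic50_wt: float

    def __post_init__(self) -> None:
        mt = validate_sequence(self.mt_seq, length=PEPTIDE_LENGTH)
        wt = validate_sequence(self.wt_seq, length=PEPTIDE_LENGTH)
        object.__setattr__(self, "mt_seq", mt)
        object.__setattr__(self, "wt_seq", wt)
        diffs = [i + 1 for i, (a, b) in enumerate(zip(mt, wt)) if a != b]
        if diffs != [self.mut_pos]:
            raise ValueError(
                f"mt/wt sequences must differ exactly at mut_pos={self.mut_pos}; "
                f"observed differences at {diffs}"
            )
        if not (1 <= self.mut_pos <= PEPTIDE_LENGTH):
            raise ValueError(f"mut_pos must be in 1..{PEPTIDE_LENGTH}")
        if self.ic50_mt <= 0 or self.ic50_wt <= 0:
            raise ValueError("IC50 values must be positive (nM)")

    @classmethod
    def unchecked(cls, patient_id, mt_seq, wt_seq, mut_pos, ic50_mt, ic50_wt):
        """Bypass the single-difference invariant (testing hook)."""
        obj = object.__new__(cls)
        for k, v in dict(
            patient_id=patient_id, mt_seq=mt_seq, wt_seq=wt_seq,
            mut_pos=mut_pos, ic50_mt=ic50_mt, ic50_wt=ic50_wt,
        ).items():
            object.__setattr__(obj, k, v)
        return obj


class FeatureVocabulary:
    """The ordered intrinsic-feature namespace.

    Names follow ``{role}.peptide.{start}[-{end}].{measure}`` for absolute
    units, ``{role}.peptide.full.{measure}`` for whole-sequence measures and
    ``{role}.mutsite.{unit}.{measure}`` for mutation-anchored units. The order
    is deterministic: for each role, positions 1..9, dipeptides 1-2..8-9,
    tripeptides 1-3..7-9, whole sequence, then the mutation-anchored blocks.
    """

    def __init__(self, roles: Sequence[str] = ROLES,
                 include_mutation_anchored: bool = True) -> None:
        for r in roles:
            if r not in ROLES:
                raise ValueError(f"unknown peptide role {r!r}")
        self.roles = tuple(roles)
        self.include_mutation_anchored = bool(include_mutation_anchored)
        comps = load_descriptor_table().components
        unit_measures = comps + ["MW"]
        pos_measures = comps + list(CLASS_NAMES)
        full_measures = (comps + list(PHYSCHEM_NAMES)
                         + [f"frac{c}" for c in CLASS_NAMES] + ["entropy"])
        names: list[str] = []
        for role in self.roles:
            for p in range(1, PEPTIDE_LENGTH + 1):
                names += [f"{role}.peptide.{p}.{m}" for m in pos_measures]
            for p in range(1, PEPTIDE_LENGTH):
                names += [f"{role}.peptide.{p}-{p + 1}.{m}" for m in unit_measures]
            for p in range(1, PEPTIDE_LENGTH - 1):
                names += [f"{role}.peptide.{p}-{p + 2}.{m}" for m in unit_measures]
            names += [f"{role}.peptide.full.{m}" for m in full_measures]
            if self.include_mutation_anchored:
                names += [f"{role}.mutsite.pos.{m}" for m in pos_measures]
                for unit in ("di.left", "di.right", "tri.left", "tri.center", "tri.right"):
                    names += [f"{role}.mutsite.{unit}.{m}" for m in unit_measures]
        if len(set(names)) != len(names):
            raise AssertionError("vocabulary names must be unique")
        self.names: tuple[str, ...] = tuple(names)
        self.index = {n: i for i, n in enumerate(names)}

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self.index

    def __eq__(self, other) -> bool:
        return isinstance(other, FeatureVocabulary) and self.names == other.names

    def __hash__(self) -> int:
        return hash(self.names)


@dataclass
class FeatureVector:
    """One realization of a :class:`FeatureVocabulary`.

    ``mask`` is True where the value is undefined (mutation-anchored unit out
    of range); values are finite wherever the mask is False.
    """

    vocabulary: FeatureVocabulary
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != (len(self.vocabulary),) or self.mask.shape != self.values.shape:
            raise ValueError("vector length must equal vocabulary size")
        if not np.isfinite(self.values[~self.mask]).all():
            raise ValueError("unmasked feature values must be finite")

    def __getitem__(self, name: str) -> float:
        i = self.vocabulary.index[name]
        return math.nan if self.mask[i] else float(self.values[i])


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def shannon_entropy(seq: str) -> float:
    """Shannon entropy (bits) of the residue composition of ``seq``."""
    s = validate_sequence(seq)
    if not s:
        raise ValueError("empty sequence")
    _, counts = np.unique(list(s), return_counts=True)
    f = counts / counts.sum()
    return float(-(f * np.log2(f)).sum() + 0.0)  # + 0.0 avoids -0.0


def unit_descriptor(residues: str, component: str) -> float:
    """Descriptor component of a 1-3 residue unit (mean over residues)."""
    s = validate_sequence(residues)
    if not 1 <= len(s) <= 3:
        raise ValueError("unit must span 1-3 residues")
    table = load_descriptor_table()
    return float(np.mean([table.lookup(a, component) for a in s]))


def unit_molecular_weight(residues: str) -> float:
    """Average molecular weight (Da) of a peptide unit: mass sum + one water."""
    s = validate_sequence(residues)
    if not s:
        raise ValueError("empty unit")
    return float(sum(RESIDUE_MASS[a] for a in s) + WATER_MASS)


def aa_class_flags(residue: str) -> dict[str, int]:
    """Binary membership of ``residue`` in the 9 composition classes."""
    r = validate_sequence(residue, length=1)
    row = load_class_table().loc[r]
    return {c: int(row[c]) for c in CLASS_NAMES}


def hydrophobic_moment(seq: str, angle_deg: float = 100.0) -> float:
    """Eisenberg helical hydrophobic moment per residue (window = sequence)."""
    s = validate_sequence(seq)
    h = _EISENBERG_VEC[[_AA_INDEX[a] for a in s]]
    theta = np.deg2rad(angle_deg) * np.arange(1, len(s) + 1)
    return float(np.hypot((h * np.sin(theta)).sum(), (h * np.cos(theta)).sum()) / len(s))


def physchem_properties(seq: str) -> dict[str, float]:
    """The pinned 8 whole-sequence physico-chemical properties."""
    s = validate_sequence(seq, length=PEPTIDE_LENGTH)
    idx = [_AA_INDEX[a] for a in s]
    pa = ProteinAnalysis(s)
    n = len(s)
    counts = np.bincount(idx, minlength=20)
    f = counts / n
    aliphatic = 100.0 * (f[_AA_INDEX["A"]] + 2.9 * f[_AA_INDEX["V"]]
                         + 3.9 * (f[_AA_INDEX["I"]] + f[_AA_INDEX["L"]]))
    return {
        "aliphatic_index": float(aliphatic),
        "boman": float(_BOMAN_VEC[idx].mean()),
        "charge_pH7": float(pa.charge_at_pH(7.0)),
        "hydrophobic_moment": hydrophobic_moment(s),
        "gravy": float(pa.gravy()),
        "instability_index": float(pa.instability_index()),
        "MW": unit_molecular_weight(s),
        "pI": float(pa.isoelectric_point()),
    }


def residue_frequency_matrix(pairs: Iterable[PeptidePair], role: str = "MT") -> pd.DataFrame:
    """Position-wise residue frequencies (9 positions x 20 residues).

    Rows are positions 1..9 and sum to 1; this is the matrix behind
    position-frequency sequence logos.
    """
    if role not in ROLES:
        raise ValueError(f"role must be one of {ROLES}")
    counts = np.zeros((PEPTIDE_LENGTH, 20))
    n = 0
    for pair in pairs:
        seq = pair.mt_seq if role == "MT" else pair.wt_seq
        for p, a in enumerate(seq):
            counts[p, _AA_INDEX[a]] += 1
        n += 1
    if n == 0:
        raise ValueError("at least one peptide pair is required")
    return pd.DataFrame(counts / n, index=range(1, PEPTIDE_LENGTH + 1),
                        columns=list(STANDARD_AA))


# ---------------------------------------------------------------------------
# full-vector featurization
# ---------------------------------------------------------------------------

_TABLE_CACHE: dict[str, np.ndarray] = {}


def _tables() -> tuple[np.ndarray, np.ndarray]:
    if not _TABLE_CACHE:
        _TABLE_CACHE["D"] = load_descriptor_table().matrix()
        _TABLE_CACHE["C"] = load_class_table().to_numpy(dtype=float)
    return _TABLE_CACHE["D"], _TABLE_CACHE["C"]


def _encode_role(seq: str, mut_pos: int, include_mut: bool) -> tuple[np.ndarray, np.ndarray]:
    """Feature block for one peptide role, in vocabulary block order."""
    idx = np.array([_AA_INDEX[a] for a in seq])
    D, C = _tables()  # (20, 66), (20, 9)
    pos_desc = D[idx]                             # (9, 66)
    pos_flag = C[idx]                             # (9, 9)
    masses = _MASS_VEC[idx]

    di_desc = (pos_desc[:-1] + pos_desc[1:]) / 2.0
    di_mw = masses[:-1] + masses[1:] + WATER_MASS
    tri_desc = (pos_desc[:-2] + pos_desc[1:-1] + pos_desc[2:]) / 3.0
    tri_mw = masses[:-2] + masses[1:-1] + masses[2:] + WATER_MASS

    blocks = [np.concatenate([pos_desc, pos_flag], axis=1).ravel(),
              np.concatenate([di_desc, di_mw[:, None]], axis=1).ravel(),
              np.concatenate([tri_desc, tri_mw[:, None]], axis=1).ravel()]

    pc = physchem_properties(seq)
    blocks.append(np.concatenate([
        pos_desc.mean(axis=0),
        np.array([pc[k] for k in PHYSCHEM_NAMES]),
        pos_flag.mean(axis=0),
        [shannon_entropy(seq)],
    ]))

    mask_parts = [np.zeros(b.size, dtype=bool) for b in blocks]

    if include_mut:
        p = mut_pos - 1  # 0-based

        def unit(lo: int, hi: int) -> tuple[np.ndarray, np.ndarray]:
            # inclusive 0-based [lo, hi]; out of range -> masked 67-vector
            if lo < 0 or hi >= PEPTIDE_LENGTH:
                return np.full(67, np.nan), np.ones(67, dtype=bool)
            d = pos_desc[lo:hi + 1].mean(axis=0)
            mw = masses[lo:hi + 1].sum() + WATER_MASS
            return np.concatenate([d, [mw]]), np.zeros(67, dtype=bool)

        blocks.append(np.concatenate([pos_desc[p], pos_flag[p]]))
        mask_parts.append(np.zeros(75, dtype=bool))
        for lo, hi in ((p - 1, p), (p, p + 1), (p - 2, p), (p - 1, p + 1), (p, p + 2)):
            v, m = unit(lo, hi)
            blocks.append(v)
            mask_parts.append(m)

    return np.concatenate(blocks), np.concatenate(mask_parts)


def build_feature_vector(pair: PeptidePair, vocab: FeatureVocabulary | None = None) -> FeatureVector:
    """Encode one MT/WT pair onto the vocabulary."""
    if vocab is None:
        vocab = FeatureVocabulary()
    values, masks = [], []
    for role in vocab.roles:
        seq = pair.mt_seq if role == "MT" else pair.wt_seq
        v, m = _encode_role(seq, pair.mut_pos, vocab.include_mutation_anchored)
        values.append(v)
        masks.append(m)
    return FeatureVector(vocab, np.concatenate(values), np.concatenate(masks))


def aggregate_patient(vectors: Sequence[FeatureVector]) -> FeatureVector:
    """Element-wise mean over a patient's vectors, ignoring masked entries.

    An entry is masked in the result only if it is masked in every input.
    """
    if not vectors:
        raise ValueError("at least one feature vector is required")
    vocab = vectors[0].vocabulary
    if any(v.vocabulary != vocab for v in vectors[1:]):
        raise ValueError("all vectors must share one vocabulary")
    vals = np.stack([v.values for v in vectors])
    mask = np.stack([v.mask for v in vectors])
    valid = (~mask).sum(axis=0)
    out_mask = valid == 0
    safe = np.where(mask, 0.0, vals)
    with np.errstate(invalid="ignore"):
        out = safe.sum(axis=0) / np.where(valid == 0, 1, valid)
    out[out_mask] = np.nan
    return FeatureVector(vocab, out, out_mask)


def patient_feature_matrix(pairs: Iterable[PeptidePair],
                           vocab: FeatureVocabulary | None = None) -> pd.DataFrame:
    """Patients x features matrix: per-pair vectors averaged per patient.

    Entries masked in every pair of a patient come out as NaN. Patients
    appear in first-seen order.
    """
    if vocab is None:
        vocab = FeatureVocabulary()
    by_patient: dict[str, list[FeatureVector]] = {}
    for pair in pairs:
        by_patient.setdefault(pair.patient_id, []).append(build_feature_vector(pair, vocab))
    if not by_patient:
        raise ValueError("no peptide pairs to featurize")
    rows = {pid: aggregate_patient(vs).values for pid, vs in by_patient.items()}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(vocab.names))
    df.index.name = "patient_id"
    return df


def write_feature_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=True)


def read_feature_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="patient_id")
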