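"""Synthetic cohorts with the structure the pipeline assumes.

Each patient carries a Poisson number of mutant/wild-type 9-mer pairs with a
single-residue difference, IC50 pairs straddling the 500 nM calling rule, and
right-censored exponential survival whose hazard depends on a planted group.
The two groups differ in residue usage at peptide positions 3-4: the
"long" group is enriched for arginine/serine there, the "short" group for
leucine/glycine, and the short group carries the higher hazard. This plants a
positional sequence signal that the featurization, screening, clustering and
stratifier stages can be tested against end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._residues import PEPTIDE_LENGTH, STANDARD_AA
from .cohort_io import (
    ClinicalRecord,
    Cohort,
    MutationRecord,
    write_clinical_table,
    write_mutation_table,
    write_peptide_table,
)
from .peptide_features import PeptidePair
from .survival_stats import SurvivalData

BIAS_POSITIONS = (3, 4)  # 1-based peptide sites carrying the group signal
LONG_RESIDUES = "RS"
SHORT_RESIDUES = "LG"


@dataclass(frozen=True)
class SimConfig:
    """Generator settings (defaults are the desk-scale study conditions).

    ``beta`` is the log hazard ratio of the short-term group versus the
    long-term group; ``h0`` the baseline (long-term) hazard per day;
    ``bias_strength`` the probability that a residue at a biased position is
    drawn from the group's enriched residue set instead of the background;
    ``neoantigen_fraction`` the fraction of generated pairs constructed to
    satisfy the 500 nM calling rule.
    """

    n_patients: int = 200
    lam: float = 8.0
    beta: float = 1.1
    h0: float = 1.0 / 400.0
    censor_window: float = 1500.0
    bias_strength: float = 0.6
    neoantigen_fraction: float = 0.7
    missense_mean: float = 30.0
    other_mut_mean: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2 or self.lam <= 0 or self.h0 <= 0:
            raise ValueError("n_patients >= 2, lam > 0 and h0 > 0 required")
        if not 0 <= self.bias_strength <= 1 or not 0 <= self.neoantigen_fraction <= 1:
            raise ValueError("bias_strength and neoantigen_fraction are probabilities")
        if self.censor_window <= 0:
            raise ValueError("censor_window must be positive")


def _draw_residue(rng: np.random.Generator, enriched: str | None, strength: float) -> str:
    if enriched and rng.random() < strength:
        return enriched[rng.integers(len(enriched))]
    return STANDARD_AA[rng.integers(20)]


def _draw_ic50(rng: np.random.Generator, passing: bool) -> tuple[float, float]:
    # log-normal affinities; resample into the wanted side of the 500 nM rule
    def trunc(median: float, below: bool) -> float:
        for _ in range(1000):
            v = float(np.exp(np.log(median) + rng.normal(0, 1.0)))
            if (v < 500.0) == below and v != 500.0:
                return v
        raise RuntimeError("IC50 rejection sampling failed")

    if passing:
        return trunc(150.0, True), trunc(1500.0, False)
    # violate the rule in one of the two possible ways
    if rng.random() < 0.5:
        return trunc(1500.0, False), trunc(1500.0, False)  # MT not a binder
    return trunc(150.0, True), trunc(150.0, True)          # WT also binds


def generate_peptide_pair(rng: np.random.Generator,
                          bias: dict[int, str] | None = None,
                          bias_strength: float = 0.0,
                          passing: bool = True,
                          patient_id: str = "P0") -> PeptidePair:
    """One MT/WT 9-mer pair differing at a uniform position.

    ``bias`` maps 1-based positions to enriched residue alphabets applied to
    both peptides of the pair (the mutated position, if biased, is re-drawn
    for the mutant from the same distribution).
    """
    bias = bias or {}
    wt = [_draw_residue(rng, bias.get(p + 1), bias_strength)
          for p in range(PEPTIDE_LENGTH)]
    pos = int(rng.integers(1, PEPTIDE_LENGTH + 1))
    mt = list(wt)
    while mt[pos - 1] == wt[pos - 1]:
        mt[pos - 1] = _draw_residue(rng, bias.get(pos), bias_strength)
    ic50_mt, ic50_wt = _draw_ic50(rng, passing)
    return PeptidePair(patient_id=patient_id, mt_seq="".join(mt), wt_seq="".join(wt),
                       mut_pos=pos, ic50_mt=ic50_mt, ic50_wt=ic50_wt)


def simulate_survival(x, beta: float, h0: float, censor_window: float,
                      rng: np.random.Generator) -> SurvivalData:
    """Proportional-hazards exponential survival with uniform censoring.

    Event time ~ Exp(rate h0 * exp(beta * x)); censoring ~ U(0, window);
    observed time is the minimum and the event flag marks a death.
    """
    x = np.asarray(x, dtype=float)
    rate = h0 * np.exp(beta * x)
    t_event = rng.exponential(1.0 / rate)
    t_cens = rng.uniform(0.0, censor_window, size=x.size)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return SurvivalData(time=time, event=event)


@dataclass
class SyntheticCohort:
    cohort: Cohort
    truth: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    """Per-patient planted truth: group label and scalar risk feature."""


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """A full synthetic cohort plus the planted per-patient truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    ids = [f"SYN{i:04d}" for i in range(n)]
    group = rng.integers(0, 2, size=n)  # 1 = short-term (higher hazard)

    pairs: list[PeptidePair] = []
    for pid, g in zip(ids, group):
        k = max(1, int(rng.poisson(config.lam)))
        enriched = SHORT_RESIDUES if g == 1 else LONG_RESIDUES
        bias = {p: enriched for p in BIAS_POSITIONS}
        for _ in range(k):
            passing = bool(rng.random() < config.neoantigen_fraction)
            pairs.append(generate_peptide_pair(
                rng, bias=bias, bias_strength=config.bias_strength,
                passing=passing, patient_id=pid))

    surv = simulate_survival(group.astype(float), config.beta, config.h0,
                             config.censor_window, rng)

    clinical = [
        ClinicalRecord(patient_id=pid, os_days=float(t), os_event=int(e),
                       age=float(np.round(rng.normal(60, 10), 1)))
        for pid, t, e in zip(ids, surv.time, surv.event)
    ]

    mutations: list[MutationRecord] = []
    for pid in ids:
        for _ in range(rng.poisson(config.missense_mean)):
            mutations.append(MutationRecord(
                patient_id=pid, gene=f"GENE{rng.integers(1, 2000)}",
                variant_classification="Missense_Mutation"))
        for _ in range(rng.poisson(config.other_mut_mean)):
            cls = ("Nonsense_Mutation", "Silent", "Splice_Site")[rng.integers(3)]
            mutations.append(MutationRecord(
                patient_id=pid, gene=f"GENE{rng.integers(1, 2000)}",
                variant_classification=cls))

    truth = pd.DataFrame({
        "patient_id": ids,
        "group": np.where(group == 1, "short", "long"),
        "risk": group.astype(float),
    }).set_index("patient_id")

    cohort = Cohort(clinical=clinical, pairs=pairs, mutations=mutations,
                    name=f"synthetic-seed{config.seed}")
    return SyntheticCohort(cohort=cohort, truth=truth)


def write_synthetic_cohort(sim: SyntheticCohort, out_dir) -> dict[str, Path]:
    """Emit the standard peptide/clinical/mutation/truth TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "peptides": out / "peptides.tsv",
        "clinical": out / "clinical.tsv",
        "mutations": out / "mutations.tsv",
        "truth": out / "truth.tsv",
    }
    write_peptide_table(sim.cohort.pairs, paths["peptides"])
    write_clinical_table(sim.cohort.clinical, paths["clinical"])
    write_mutation_table(sim.cohort.mutations, paths["mutations"])
    sim.truth.to_csv(paths["truth"], sep="\t")
    return paths
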