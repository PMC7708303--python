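"""Synthetic EMR cohort generation.

Emulates the statistical structure the analysis pipeline assumes, without
any patient data: per-individual EMR-usage windows (first-encounter age and
follow-up duration), encounter streams at a realistic contact rate,
age-dependent baseline emission of provider diagnosis codes, and planted
time-localized gene-phenotype effects expressed as an odds ratio on the
per-encounter emission probability.

The defaults mirror published childhood-epilepsy cohort characteristics:
median follow-up 6.9 years, ~19 documented encounters per patient-year
(higher in infancy), causative-gene frequencies led by SCN1A and STXBP1,
and diagnosis codes whose age profiles echo the natural history of the
phenotypes (febrile seizures in early childhood, infantile spasms in
infancy, ADHD at school age).  Emission distinguishes acute event codes
(independent per encounter) from chronic problem-list codes, which onset
once via an age-windowed hazard and are then re-documented at subsequent
visits -- the temporal persistence that real problem lists exhibit.

All randomness flows from the single ``seed`` through one numpy Generator.
Draw order (part of the reproducibility contract): genes, first ages,
durations, per-individual encounter counts / interior ages / infancy
extras, then per-code emissions in codebook order (one uniform array per
event code; hazard then re-documentation arrays per chronic code), then
list-type labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

ADMIN_CODE = ("Encounter for administrative examination", "Z02.89")


@dataclass(frozen=True)
class CodeDef:
    """One provider diagnosis code the generator can emit.

    ``baseline`` is a per-encounter probability while the patient's age
    lies in ``[age_lo, age_hi)``; outside it the code is never emitted.
    ``hpo_ids`` may be empty (unmappable code) or hold several terms.

    Two emission modes mirror how EMR problem lists behave:

    * event codes (``persistent=False``): emitted independently at each
      encounter with probability ``baseline`` -- acute diagnoses such as a
      status epilepticus episode or a febrile seizure;
    * chronic codes (``persistent=True``): ``baseline`` acts as a
      per-encounter onset hazard while the age lies in the onset window
      ``[age_lo, onset_hi)``; once first emitted, the code is re-documented
      at every subsequent encounter with probability ``redocument`` while
      the age stays in ``[age_lo, age_hi)`` -- problem-list entries such as
      "Seizure disorder" or "Intellectual disability".  A bounded onset
      window mirrors clinical practice: chronic diagnoses are established
      within a few years of symptom emergence, after which the problem
      list carries them forward.
    """

    source_code: str
    icd_code: str
    hpo_ids: tuple[str, ...]
    baseline: float
    age_lo: float = 0.0
    age_hi: float = 25.0
    persistent: bool = False
    redocument: float = 0.9
    onset_hi: float | None = None  # chronic codes: onset window end (default age_hi)

    def prob(self, ages: np.ndarray) -> np.ndarray:
        return np.where((ages >= self.age_lo) & (ages < self.age_hi), self.baseline, 0.0)

    def hazard(self, ages: np.ndarray) -> np.ndarray:
        """Onset-hazard profile for chronic codes (0 outside onset window)."""
        hi = min(self.onset_hi, self.age_hi) if self.onset_hi is not None else self.age_hi
        return np.where((ages >= self.age_lo) & (ages < hi), self.baseline, 0.0)


#: Default codebook: a realistic slice of a pediatric-neurology problem list.
#: Codes and ICD prefixes match the packaged fixture dictionary.  Chronic
#: problem-list entries are ``persistent`` (onset hazard + re-documentation);
#: acute diagnoses are per-encounter events.  A few codes deliberately carry
#: non-neurological ICD prefixes and are removed by the ICD filter, as in
#: real extractions.
DEFAULT_CODEBOOK: tuple[CodeDef, ...] = (
    # epilepsy problem-list entries (chronic)
    CodeDef("Seizure disorder", "G40.909", ("HP:0001250",), 0.12, persistent=True, redocument=0.35),
    CodeDef("Epilepsy, unspecified, not intractable", "G40.909", ("HP:0001250",), 0.012, persistent=True, onset_hi=6.0),
    CodeDef("Generalized epilepsy", "G40.309", ("HP:0002197",), 0.010, persistent=True, onset_hi=7.0),
    CodeDef("Focal seizure", "G40.209", ("HP:0007359",), 0.014, persistent=True, onset_hi=7.0),
    CodeDef("Localization-related epilepsy", "G40.109", ("HP:0007359",), 0.006, persistent=True, onset_hi=7.0),
    # seizure-type problem-list entries (chronic until remission age)
    CodeDef("Absence seizure", "G40.A09", ("HP:0002121",), 0.008, 3.0, 14.0, persistent=True, onset_hi=9.0),
    CodeDef("Myoclonic seizure", "G40.409", ("HP:0002123",), 0.006, persistent=True, onset_hi=9.0),
    CodeDef("Generalized tonic-clonic seizure", "G40.409", ("HP:0002069",), 0.008, 1.0, 25.0, persistent=True, onset_hi=10.0),
    CodeDef("Tonic seizure", "G40.409", ("HP:0010818",), 0.005, persistent=True, onset_hi=7.0),
    CodeDef("Atonic seizure", "G40.409", ("HP:0010819",), 0.005, 1.0, 12.0, persistent=True, onset_hi=6.0),
    CodeDef("Febrile convulsion", "R56.00", ("HP:0002373",), 0.018, 0.25, 6.0),
    CodeDef("Complex febrile seizure", "R56.01", ("HP:0002373",), 0.006, 0.25, 6.0),
    CodeDef("Status epilepticus", "G40.901", ("HP:0002133",), 0.018),
    CodeDef("Infantile spasms", "G40.821", ("HP:0012469",), 0.012, 0.0, 2.0),
    CodeDef("Epileptic spasms", "G40.821", ("HP:0011097",), 0.008, 0.0, 3.0),
    CodeDef("Neonatal seizure onset", "P90", ("HP:0003623",), 0.004, 0.0, 1.0),
    # development and cognition (chronic)
    CodeDef("Global developmental delay", "F88", ("HP:0001263",), 0.025, 0.0, 5.0, persistent=True, onset_hi=4.0),
    CodeDef("Developmental regression", "F84.3", ("HP:0002376",), 0.005, 0.5, 10.0, persistent=True, onset_hi=5.0),
    CodeDef("Intellectual disability", "F79", ("HP:0001249",), 0.015, 3.0, 25.0, persistent=True, onset_hi=8.0),
    CodeDef("Mild intellectual disability", "F70", ("HP:0001256",), 0.006, 3.0, 25.0, persistent=True, onset_hi=8.0),
    CodeDef("Moderate intellectual disability", "F71", ("HP:0002342",), 0.005, 3.0, 25.0, persistent=True, onset_hi=8.0),
    CodeDef("Severe intellectual disability", "F72", ("HP:0010864", "HP:0012828"), 0.005, 3.0, 25.0, persistent=True, onset_hi=8.0),
    CodeDef("Speech delay", "R47.9", ("HP:0000750",), 0.018, 1.0, 10.0, persistent=True, onset_hi=6.0),
    CodeDef("Speech and language disorder", "F80.9", ("HP:0002167",), 0.008, 1.0, 18.0, persistent=True, onset_hi=7.0),
    CodeDef("Dysarthria", "R47.1", ("HP:0001260",), 0.005, 3.0, 25.0, persistent=True, onset_hi=9.0),
    # behavior (chronic)
    CodeDef("Attention deficit hyperactivity disorder", "F90.0", ("HP:0007018",), 0.010, 5.0, 18.0, persistent=True, onset_hi=10.0),
    CodeDef("Autism spectrum disorder", "F84.0", ("HP:0000729",), 0.007, 2.0, 18.0, persistent=True, onset_hi=7.0),
    CodeDef("Aggressive behavior", "R45.6", ("HP:0000718",), 0.005, 4.0, 18.0, persistent=True, onset_hi=11.0),
    CodeDef("Anxiety disorder", "F41.9", ("HP:0000739",), 0.008, 6.0, 25.0, persistent=True, onset_hi=13.0),
    CodeDef("Insomnia", "G47.00", ("HP:0002360",), 0.007, 1.0, 25.0, persistent=True, onset_hi=9.0),
    # motor (chronic)
    CodeDef("Hypotonia", "R29.898", ("HP:0001252",), 0.018, 0.0, 10.0, persistent=True, onset_hi=4.0),
    CodeDef("Congenital hypotonia", "P94.2", ("HP:0001290",), 0.008, 0.0, 5.0, persistent=True, onset_hi=2.0),
    CodeDef("Spastic quadriplegia", "G80.0", ("HP:0001257",), 0.006, 0.5, 25.0, persistent=True, onset_hi=4.0),
    CodeDef("Ataxia", "R27.0", ("HP:0001251",), 0.008, 1.0, 25.0, persistent=True, onset_hi=6.0),
    CodeDef("Dystonia", "G24.9", ("HP:0001332",), 0.005, 1.0, 25.0, persistent=True, onset_hi=6.0),
    CodeDef("Tremor", "R25.1", ("HP:0001337",), 0.005, 2.0, 25.0, persistent=True, onset_hi=9.0),
    CodeDef("Chorea", "G25.5", ("HP:0002072",), 0.004, 2.0, 25.0, persistent=True, onset_hi=7.0),
    CodeDef("Gait abnormality", "R26.9", ("HP:0001288",), 0.010, 2.0, 25.0, persistent=True, onset_hi=8.0),
    # structural / other neurology
    CodeDef("Microcephaly", "Q02", ("HP:0000252",), 0.008, 0.0, 10.0, persistent=True, onset_hi=3.0),
    CodeDef("Macrocephaly", "Q75.3", ("HP:0000256",), 0.004, 0.0, 10.0, persistent=True, onset_hi=3.0),
    CodeDef("Cerebral atrophy", "G31.9", ("HP:0002059",), 0.004, persistent=True, onset_hi=5.0),
    CodeDef("Encephalopathy, unspecified", "G93.40", ("HP:0001298",), 0.008, persistent=True, onset_hi=4.0),
    CodeDef("Abnormal EEG", "R94.01", ("HP:0002353",), 0.03),
    CodeDef("Headache", "R51.9", ("HP:0002315",), 0.012, 5.0, 25.0),
    CodeDef("Migraine", "G43.909", ("HP:0002076",), 0.010, 6.0, 25.0, persistent=True, onset_hi=13.0),
    # ophthalmology (H-codes: removed by the neurology ICD filter)
    CodeDef("Strabismus", "H50.9", ("HP:0000486",), 0.006, 0.0, 10.0, persistent=True, onset_hi=4.0),
    CodeDef("Nystagmus", "H55.00", ("HP:0000639",), 0.005, 0.0, 10.0, persistent=True, onset_hi=3.0),
    # codes curated as unmappable, or non-neurological
    CodeDef("Neurology follow-up visit", "R62.50", (), 0.05),
    CodeDef("Altered mental status", "R41.82", (), 0.008),
    CodeDef("Well child examination", "Z00.129", (), 0.10, 0.0, 12.0),
    CodeDef("Asthma exacerbation", "J45.901", (), 0.03),
)

#: Causative-gene frequencies echoing a genetic-epilepsy referral cohort:
#: the five most common etiologies at their published cohort shares, a tail
#: of 31 rarer genes, and ~65% of individuals without a genetic diagnosis.
_TOP_GENES = {"SCN1A": 29, "STXBP1": 22, "SCN2A": 12, "KCNQ2": 8, "KCNT1": 6}
_TAIL_GENES = (
    "CDKL5", "PCDH19", "SLC2A1", "CHD2", "GRIN2A", "SYNGAP1", "DEPDC5", "TSC2",
    "MECP2", "FOXG1", "GABRA1", "GABRB3", "GABRG2", "KCNA2", "KCNB1", "HNF1B",
    "PURA", "SLC6A1", "STX1B", "TBC1D24", "UBE3A", "ZEB2", "ARX", "ATP1A3",
    "CACNA1A", "DNM1", "EEF1A2", "GNAO1", "IQSEC2", "KCNH5", "PRRT2",
)


def _default_gene_freqs() -> dict[str, float]:
    freqs = {g: c / 658 for g, c in _TOP_GENES.items()}
    freqs.update({g: 5 / 658 for g in _TAIL_GENES})
    freqs["none"] = 1.0 - sum(freqs.values())
    return freqs


DEFAULT_GENE_FREQS: dict[str, float] = _default_gene_freqs()


@dataclass(frozen=True)
class PlantedEffect:
    """Multiply a code's emission odds by ``odds_ratio`` for carriers of
    ``gene`` while their age lies in ``[age_lo, age_hi)``."""

    gene: str
    source_code: str
    age_lo: float
    age_hi: float
    odds_ratio: float


@dataclass
class CohortConfig:
    """Generator configuration; see module docstring for the model."""

    n_individuals: int = 300
    gene_freqs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GENE_FREQS))
    first_age_min: float = 0.0
    first_age_max: float = 5.0
    duration_median: float = 6.9
    duration_sigma: float = 0.6
    encounter_rate: float = 19.0     # encounters per patient-year
    infancy_rate: float = 36.0       # elevated contact rate below infancy_age_max
    infancy_age_max: float = 2.0     # well-baby visits, early workup
    max_age: float = 25.0
    codebook: tuple[CodeDef, ...] = DEFAULT_CODEBOOK
    planted_effects: tuple[PlantedEffect, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        freqs = np.array(list(self.gene_freqs.values()))
        if (freqs < 0).any() or (freqs > 1).any() or abs(freqs.sum() - 1) > 1e-9:
            raise ValueError("gene frequencies must lie in [0, 1] and sum to 1")
        if "none" not in self.gene_freqs:
            raise ValueError('gene frequency table must include "none"')
        for code in self.codebook:
            if not 0 <= code.baseline <= 1:
                raise ValueError(f"baseline probability out of [0, 1] for {code.source_code!r}")
        known_codes = {c.source_code for c in self.codebook}
        for eff in self.planted_effects:
            if eff.odds_ratio <= 0:
                raise ValueError(f"odds ratio must be positive (got {eff.odds_ratio})")
            if not 0 <= eff.age_lo < eff.age_hi <= self.max_age:
                raise ValueError(f"effect interval [{eff.age_lo}, {eff.age_hi}) outside [0, {self.max_age})")
            if eff.source_code not in known_codes:
                raise ValueError(f"planted effect references unknown code {eff.source_code!r}")
        if self.encounter_rate <= 0 or self.duration_median <= 0:
            raise ValueError("encounter_rate and duration_median must be positive")


@dataclass
class SyntheticCohort:
    """Generated tables plus the ground-truth record."""

    encounters: pd.DataFrame  # individual_id, age_years, source_code, icd_code, list_type
    genotypes: pd.DataFrame   # individual_id, gene
    dictionary: pd.DataFrame  # source_code, icd_code, hpo_id
    truth: dict

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.encounters.to_csv(out / "encounters.tsv", sep="\t", index=False)
        self.genotypes.to_csv(out / "genotypes.tsv", sep="\t", index=False)
        self.dictionary.to_csv(out / "dictionary.tsv", sep="\t", index=False)
        (out / "truth.json").write_text(json.dumps(self.truth, indent=1, sort_keys=True))


def _odds_multiply(p: np.ndarray, odds_ratio: float) -> np.ndarray:
    return odds_ratio * p / (1.0 - p + odds_ratio * p)


def dictionary_frame(codebook=DEFAULT_CODEBOOK) -> pd.DataFrame:
    rows = []
    for code in codebook:
        if code.hpo_ids:
            rows += [(code.source_code, code.icd_code, h) for h in code.hpo_ids]
        else:
            rows.append((code.source_code, code.icd_code, ""))
    return pd.DataFrame(rows, columns=["source_code", "icd_code", "hpo_id"])


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a reproducible synthetic cohort from *config*.

    Windows are ``[first_age, first_age + duration]`` with first age drawn
    uniformly, duration lognormal around the configured median (truncated
    so windows end by ``max_age``); the first and last encounter sit at the
    window edges so the realized usage window equals the drawn one.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    ids = [f"P{i:04d}" for i in range(n)]

    genes = list(config.gene_freqs)
    probs = np.array([config.gene_freqs[g] for g in genes])
    genotype = rng.choice(genes, size=n, p=probs)

    first = rng.uniform(config.first_age_min, config.first_age_max, size=n)
    duration = rng.lognormal(mean=np.log(config.duration_median),
                             sigma=config.duration_sigma, size=n)
    duration = np.minimum(duration, config.max_age - first)

    enc_ind: list[str] = []
    enc_age: list[float] = []
    for i in range(n):
        last = first[i] + duration[i]
        n_enc = max(1, int(rng.poisson(config.encounter_rate * duration[i])))
        if n_enc == 1:
            ages = np.array([first[i]])
        else:
            interior = rng.uniform(first[i], last, size=n_enc - 2)
            ages = np.concatenate(([first[i]], np.sort(interior), [last]))
        # pediatric contact rates are higher in infancy: add extra encounters
        # over the window's overlap with [0, infancy_age_max)
        overlap = max(0.0, min(config.infancy_age_max, last) - first[i])
        if overlap > 0 and config.infancy_rate > config.encounter_rate:
            n_extra = int(rng.poisson((config.infancy_rate - config.encounter_rate) * overlap))
            if n_extra:
                extra = rng.uniform(first[i], first[i] + overlap, size=n_extra)
                ages = np.sort(np.concatenate((ages, extra)))
        enc_ind += [ids[i]] * len(ages)
        enc_age.append(ages)
    enc_age = np.concatenate(enc_age)
    enc_ind = np.array(enc_ind)
    enc_gene = pd.Series(genotype, index=ids).loc[enc_ind].to_numpy()

    # encounter index ranges per individual (encounters are contiguous and
    # age-sorted within each individual)
    seg_bounds = np.concatenate(([0], np.cumsum(
        np.bincount(pd.factorize(enc_ind)[0], minlength=n))))

    rows_ind: list[np.ndarray] = []
    rows_age: list[np.ndarray] = []
    rows_code: list[str] = []
    rows_icd: list[str] = []
    emitted_any = np.zeros(len(enc_age), dtype=bool)
    for code in config.codebook:
        p = code.hazard(enc_age) if code.persistent else code.prob(enc_age)
        for eff in config.planted_effects:
            if eff.source_code != code.source_code:
                continue
            in_eff = (enc_gene == eff.gene) & (enc_age >= eff.age_lo) & (enc_age < eff.age_hi)
            p = np.where(in_eff, _odds_multiply(p, eff.odds_ratio), p)
        u = rng.random(len(enc_age))
        if not code.persistent:
            hit = u < p
        else:
            # onset hazard, then re-documentation at later encounters while
            # the code's age range remains active
            u2 = rng.random(len(enc_age))
            onset_draw = u < p  # p is 0 outside the onset window
            in_range = (enc_age >= code.age_lo) & (enc_age < code.age_hi)
            hit = np.zeros(len(enc_age), dtype=bool)
            for i in range(n):
                lo, hi = seg_bounds[i], seg_bounds[i + 1]
                seg = onset_draw[lo:hi]
                if not seg.any():
                    continue
                onset = int(np.argmax(seg))
                hit[lo + onset] = True
                later = slice(lo + onset + 1, hi)
                hit[later] = in_range[later] & (u2[later] < code.redocument)
        emitted_any |= hit
        rows_ind.append(enc_ind[hit])
        rows_age.append(enc_age[hit])
        rows_code += [code.source_code] * int(hit.sum())
        rows_icd += [code.icd_code] * int(hit.sum())
    # keep encounters with no emitted diagnosis documented (phone calls,
    # labs, administrative visits) so usage windows stay faithful
    silent = ~emitted_any
    rows_ind.append(enc_ind[silent])
    rows_age.append(enc_age[silent])
    rows_code += [ADMIN_CODE[0]] * int(silent.sum())
    rows_icd += [ADMIN_CODE[1]] * int(silent.sum())

    encounters = pd.DataFrame({
        "individual_id": np.concatenate(rows_ind),
        "age_years": np.round(np.concatenate(rows_age), 6),
        "source_code": rows_code,
        "icd_code": rows_icd,
    })
    encounters["list_type"] = np.where(
        rng.random(len(encounters)) < 0.5, "encounter_dx", "problem_list"
    )
    encounters = encounters.sort_values(
        ["individual_id", "age_years", "source_code"], kind="mergesort", ignore_index=True
    )

    genotypes = pd.DataFrame({"individual_id": ids, "gene": genotype})
    truth = {
        "config": {
            **{k: v for k, v in asdict(config).items() if k not in ("codebook", "planted_effects")},
            "planted_effects": [asdict(e) for e in config.planted_effects],
        },
        "windows": {ids[i]: [float(first[i]), float(first[i] + duration[i])] for i in range(n)},
        "genotype": dict(zip(ids, map(str, genotype))),
    }
    return SyntheticCohort(encounters, genotypes, dictionary_frame(config.codebook), truth)


def null_cohort(n: int, seed: int) -> SyntheticCohort:
    """Default-parameter cohort with no planted effects."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return generate_cohort(CohortConfig(n_individuals=n, seed=seed))


def _recovery_gene_freqs() -> dict[str, float]:
    """Gene table for planted-effect recovery experiments: the default
    cohort with the planted gene enriched to 25% of individuals.  Since
    first encounters are uniform over ages 0-5, only ~a quarter of carriers
    are informative in infancy bins; the enrichment gives the planted
    association enough informative carriers there to be detectable."""
    freqs = _default_gene_freqs()
    freqs["none"] -= 0.25 - freqs["SCN1A"]
    freqs["SCN1A"] = 0.25
    return freqs


RECOVERY_GENE_FREQS: dict[str, float] = _recovery_gene_freqs()


def recovery_config(seed: int, n: int = 300, odds_ratio: float = 20.0,
                    age_lo: float = 0.5, age_hi: float = 1.25) -> CohortConfig:
    """Standard parameter-recovery scenario: one planted effect enriching
    "Status epilepticus" in SCN1A carriers during infancy (bins 2-4 of the
    default grid)."""
    return CohortConfig(
        n_individuals=n,
        gene_freqs=dict(RECOVERY_GENE_FREQS),
        planted_effects=(
            PlantedEffect("SCN1A", "Status epilepticus", age_lo, age_hi, odds_ratio),
        ),
        seed=seed,
    )
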