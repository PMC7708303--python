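"""Diagnosis-code to ontology-term mapping and the neurology ICD filter.

EMR problem lists and encounter diagnoses arrive as provider-facing source
codes (IMO-style term strings) carrying an associated ICD9/10 billing code.
A curated dictionary maps each source code to zero or more ontology terms;
codes explicitly reviewed and found unmappable carry an empty term column.

Rows are restricted to neurological diagnoses by ICD10 prefix before
mapping.  The inclusion list is the closed letter ranges F00-F99, G00-G99,
Q00-Q07, R25-R29, R40-R49, plus the single codes P90, R56, R62, R90 (with
any dotted extension) and R94.01 (exact).  Matching uses the letter plus
first two digits only, so no external ICD table is needed; an optional
user-supplied extra-code list covers ICD9 or site-specific codes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from .ontology import OntologyGraph

logger = logging.getLogger(__name__)

# closed ranges on letter + two-digit prefix
_PREFIX_RANGES = [("F", 0, 99), ("G", 0, 99), ("Q", 0, 7), ("R", 25, 29), ("R", 40, 49)]
# codes matching themselves or any dotted extension
_STEM_CODES = {"P90", "R56", "R62", "R90"}
# exact matches only
_EXACT_CODES = {"R94.01"}

_ICD_RE = re.compile(r"^([A-Z])(\d{2})")


def neurology_filter(icd: str, extra_codes: frozenset[str] | None = None) -> bool:
    """True iff *icd* falls in the neurology-related ICD10 inclusion list.

    Unparseable codes return False (logged).  ``extra_codes`` members match
    themselves or any dotted extension, for ICD9 or site-specific additions.
    """
    code = icd.strip().upper()
    if code in _EXACT_CODES:
        return True
    if extra_codes:
        for stem in extra_codes:
            if code == stem or code.startswith(stem + "."):
                return True
    for stem in _STEM_CODES:
        if code == stem or code.startswith(stem + "."):
            return True
    m = _ICD_RE.match(code)
    if m is None:
        logger.debug("unparseable ICD code %r treated as non-neurological", icd)
        return False
    letter, num = m.group(1), int(m.group(2))
    return any(letter == lt and lo <= num <= hi for lt, lo, hi in _PREFIX_RANGES)


@dataclass
class DiagnosisDictionary:
    """Many-to-many map from source diagnosis code to ontology term ids.

    ``entries`` maps each mappable source code to its set of term ids;
    ``unmapped`` holds codes explicitly curated as unmappable.
    """

    entries: dict[str, frozenset[str]]
    unmapped: set[str] = field(default_factory=set)

    def terms_for(self, source_code: str) -> frozenset[str]:
        return self.entries.get(source_code, frozenset())

    @property
    def all_terms(self) -> set[str]:
        out: set[str] = set()
        for terms in self.entries.values():
            out |= terms
        return out


def load_dictionary(path, graph: OntologyGraph) -> DiagnosisDictionary:
    """Load a TSV dictionary (source_code, icd_code, hpo_id) and validate it.

    An empty term column marks the code as explicitly unmappable.  Term ids
    absent from *graph* are a hard error listing all offenders; duplicate
    (code, term) rows collapse to one entry with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"source_code", "hpo_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"dictionary must have columns {sorted(required)}; got {list(df.columns)}")
    unknown = sorted(
        {t for t in df["hpo_id"] if t and t not in graph and t not in graph.alt_ids}
    )
    if unknown:
        raise ValueError(f"dictionary references term ids absent from the ontology: {unknown}")
    n_dupes = df.duplicated(subset=["source_code", "hpo_id"]).sum()
    if n_dupes:
        logger.warning("dictionary contains %d duplicate (code, term) rows; deduplicated", n_dupes)
    entries: dict[str, set[str]] = {}
    unmapped: set[str] = set()
    for code, term in zip(df["source_code"], df["hpo_id"]):
        if term:
            entries.setdefault(code, set()).add(graph.resolve(term))
        else:
            unmapped.add(code)
    return DiagnosisDictionary(
        entries={c: frozenset(t) for c, t in entries.items()},
        unmapped={c for c in unmapped if c not in entries},
    )


def map_encounters(
    raw: pd.DataFrame,
    dictionary: DiagnosisDictionary,
    extra_codes: frozenset[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Map raw encounter rows to (individual, age, term) rows.

    Input columns: ``individual_id``, ``age_years``, ``source_code``,
    ``icd_code`` (a ``list_type`` column, distinguishing problem-list from
    encounter-diagnosis provenance, is accepted and ignored: both are
    merged).  Rows failing the neurology ICD filter are dropped; rows whose
    source code maps to no term are dropped and counted.  Output has one row
    per distinct (individual_id, age_years, hpo_id).

    Returns the mapped frame and a dict of drop counters.
    """
    raw = raw.copy()
    raw["age_years"] = raw["age_years"].astype(float)
    if (raw["age_years"] < 0).any():
        bad = raw.loc[raw["age_years"] < 0].iloc[0]
        raise ValueError(
            f"negative encounter age {bad['age_years']} for individual {bad['individual_id']!r}"
        )
    keep = raw["icd_code"].astype(str).map(lambda c: neurology_filter(c, extra_codes))
    n_filtered = int((~keep).sum())
    neuro = raw.loc[keep]
    mappable = neuro["source_code"].map(lambda c: len(dictionary.terms_for(c)) > 0)
    n_unmapped = int((~mappable).sum())
    rows = [
        (ind, age, term)
        for ind, age, code in zip(
            neuro.loc[mappable, "individual_id"],
            neuro.loc[mappable, "age_years"],
            neuro.loc[mappable, "source_code"],
        )
        for term in dictionary.terms_for(code)
    ]
    mapped = pd.DataFrame(rows, columns=["individual_id", "age_years", "hpo_id"])
    mapped = mapped.drop_duplicates(ignore_index=True)
    counters = {
        "input_rows": int(len(raw)),
        "dropped_non_neurological": n_filtered,
        "dropped_unmappable": n_unmapped,
        "mapped_rows": int(len(mapped)),
    }
    logger.info(
        "mapped %(input_rows)d rows -> %(mapped_rows)d term rows "
        "(%(dropped_non_neurological)d non-neurological, %(dropped_unmappable)d unmappable dropped)",
        counters,
    )
    return mapped, counters
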