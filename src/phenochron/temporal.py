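"""Age binning, EMR-usage windows, and the presence/absence tensor.

Encounter ages are placed on a grid of half-open bins ``[k*w, (k+1)*w)``
covering ages 0 to ``max_age``; the default 3-month bins over 0-25 years
give 100 bins.  Each individual's EMR-usage window is the closed interval
between their first and last documented encounter, assumed uninterrupted.
Within the window a phenotype term is interpretable as present or absent;
outside it the state is not-applicable, because absence of a diagnosis in
a period without EMR contact carries no information.

Per (individual, bin), the propagated term sets of all encounters falling
in the bin are merged and deduplicated, so the tensor is closed under
ancestor propagation: whenever a term is present, every retained ancestor
is present too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ontology import OntologyGraph

OUT_OF_RANGE = -1

# uint8 states of the presence tensor
ABSENT, PRESENT, NOT_APPLICABLE = 0, 1, 2
STATE_NAMES = {ABSENT: "absent", PRESENT: "present", NOT_APPLICABLE: "not_applicable"}


@dataclass(frozen=True)
class BinGrid:
    """Uniform half-open age bins from 0 to ``max_age`` years."""

    bin_width: float = 0.25
    max_age: float = 25.0

    def __post_init__(self):
        if self.bin_width <= 0 or self.max_age <= 0:
            raise ValueError("bin_width and max_age must be positive")
        ratio = self.max_age / self.bin_width
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                f"max_age {self.max_age} is not an integral multiple of bin_width {self.bin_width}"
            )

    @property
    def n_bins(self) -> int:
        return int(round(self.max_age / self.bin_width))

    def bin_index(self, age: float) -> int:
        """Bin index for an age, or :data:`OUT_OF_RANGE` for ages >= max_age."""
        if age < 0:
            raise ValueError(f"negative age: {age}")
        if age >= self.max_age:
            return OUT_OF_RANGE
        return int(age / self.bin_width)

    def bin_start(self, index: int) -> float:
        return index * self.bin_width


@dataclass(frozen=True)
class UsageWindow:
    """Closed interval [min_age, max_age] of documented EMR usage."""

    individual_id: str
    min_age: float
    max_age: float

    def __post_init__(self):
        if not 0 <= self.min_age <= self.max_age:
            raise ValueError(
                f"invalid usage window [{self.min_age}, {self.max_age}] "
                f"for {self.individual_id!r}"
            )

    @property
    def duration(self) -> float:
        return self.max_age - self.min_age


def usage_window(individual_id: str, ages) -> UsageWindow:
    """Window spanning the min and max of an individual's encounter ages."""
    ages = np.asarray(list(ages), dtype=float)
    if ages.size == 0:
        raise ValueError(f"no encounters for individual {individual_id!r}")
    return UsageWindow(individual_id, float(ages.min()), float(ages.max()))


def usage_windows(encounters: pd.DataFrame) -> dict[str, UsageWindow]:
    """Per-individual usage windows from a raw encounter table.

    Windows are computed from all documented encounters, before any
    diagnosis filtering, since any contact demonstrates EMR usage.
    """
    agg = encounters.groupby("individual_id")["age_years"].agg(["min", "max"])
    return {
        str(ind): UsageWindow(str(ind), float(row["min"]), float(row["max"]))
        for ind, row in agg.iterrows()
    }


def window_bin_mask(window: UsageWindow, grid: BinGrid) -> np.ndarray:
    """Boolean informative mask over bins: does the closed window intersect
    the half-open bin?  A window touching a bin only at the bin's left edge
    counts as intersecting, so a single-encounter individual is informative
    in exactly one bin.  Window ages beyond the grid are clipped."""
    starts = np.arange(grid.n_bins) * grid.bin_width
    lo = min(window.min_age, grid.max_age - 1e-12)  # keep max-age windows in the last bin
    hi = min(window.max_age, grid.max_age)
    return (lo < starts + grid.bin_width) & (hi >= starts)


class PresenceTensor:
    """individual x bin x term states in {present, absent, not_applicable}.

    Built by :func:`build_presence`; stores a dense uint8 array plus index
    maps.  Not-applicable is a property of (individual, bin) alone: it marks
    bins outside the individual's usage window, identically for all terms.
    """

    def __init__(self, individuals, terms, grid: BinGrid,
                 informative: np.ndarray, present: np.ndarray):
        self.individuals = list(individuals)
        self.terms = list(terms)
        self.grid = grid
        self.informative = informative  # (n_ind, n_bins) bool
        self.present = present          # (n_ind, n_bins, n_terms) bool
        self._ind_index = {ind: i for i, ind in enumerate(self.individuals)}
        self._term_index = {t: i for i, t in enumerate(self.terms)}

    @property
    def n_bins(self) -> int:
        return self.grid.n_bins

    def term_idx(self, term: str) -> int:
        if term not in self._term_index:
            raise KeyError(f"term {term!r} not in tensor")
        return self._term_index[term]

    def state(self, individual: str, bin_index: int, term: str) -> int:
        i = self._ind_index[individual]
        if not self.informative[i, bin_index]:
            return NOT_APPLICABLE
        return PRESENT if self.present[i, bin_index, self.term_idx(term)] else ABSENT

    def term_trajectory(self, term: str) -> pd.DataFrame:
        """Per-bin counts: individuals with the term present, individuals
        informative, and their ratio (NaN where no one is informative)."""
        t = self.term_idx(term)
        n_present = self.present[:, :, t].sum(axis=0)
        n_informative = self.informative.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(n_informative > 0, n_present / n_informative, np.nan)
        return pd.DataFrame({
            "bin": np.arange(self.n_bins),
            "age_years": np.arange(self.n_bins) * self.grid.bin_width,
            "n_present": n_present.astype(int),
            "n_informative": n_informative.astype(int),
            "frequency": freq,
        })

    def to_long(self) -> pd.DataFrame:
        """Long-format export of present cells (individual_id, bin, term,
        state).  Absent and not-applicable cells are implied by the usage
        windows and omitted to keep exports compact."""
        ind_idx, bin_idx, term_idx = np.nonzero(self.present)
        return pd.DataFrame({
            "individual_id": [self.individuals[i] for i in ind_idx],
            "bin": bin_idx,
            "hpo_id": [self.terms[t] for t in term_idx],
            "state": "present",
        })

    def term_count_matrix(self) -> pd.DataFrame:
        """terms x bins matrix of present counts (heatmap-style export)."""
        counts = self.present.sum(axis=0).T  # (n_terms, n_bins)
        return pd.DataFrame(counts, index=pd.Index(self.terms, name="hpo_id"),
                            columns=np.arange(self.n_bins))


def build_presence(
    mapped: pd.DataFrame,
    graph: OntologyGraph,
    grid: BinGrid,
    windows: dict[str, UsageWindow],
) -> PresenceTensor:
    """Bin mapped term rows and propagate ancestors into a presence tensor.

    *mapped* has columns individual_id, age_years, hpo_id (one row per
    individual-encounter-term).  Every individual appearing in *mapped*
    must have a usage window; individuals with a window but no mapped rows
    are retained as all-absent within their window.  Ages at or beyond the
    grid maximum are excluded from binning (windows are clipped).
    """
    missing = set(mapped["individual_id"].astype(str)) - set(windows)
    if missing:
        raise ValueError(f"mapped rows for individuals without usage windows: {sorted(missing)[:5]}")

    individuals = sorted(windows)
    ind_index = {ind: i for i, ind in enumerate(individuals)}
    informative = np.zeros((len(individuals), grid.n_bins), dtype=bool)
    for ind, w in windows.items():
        informative[ind_index[ind]] = window_bin_mask(w, grid)

    # per-(individual, bin) union of assigned terms, then one propagation each
    assigned: dict[tuple[int, int], set[str]] = {}
    for ind, age, term in zip(
        mapped["individual_id"].astype(str), mapped["age_years"], mapped["hpo_id"]
    ):
        b = grid.bin_index(float(age))
        if b == OUT_OF_RANGE:
            continue
        assigned.setdefault((ind_index[ind], b), set()).add(term)

    closures = {t: graph.propagate([t]) for t in set(mapped["hpo_id"])}
    all_terms = sorted(set().union(*closures.values())) if closures else []
    term_index = {t: i for i, t in enumerate(all_terms)}

    present = np.zeros((len(individuals), grid.n_bins, len(all_terms)), dtype=bool)
    for (i, b), terms in assigned.items():
        cell: set[str] = set()
        for t in terms:
            cell |= closures[t]
        present[i, b, [term_index[t] for t in cell]] = True

    # presence only interpretable inside the usage window
    present &= informative[:, :, None]
    return PresenceTensor(individuals, all_terms, grid, informative, present)


def summarize_windows(windows: dict[str, UsageWindow]) -> dict[str, float]:
    """Cohort usage summary: total and median window duration in years."""
    if not windows:
        raise ValueError("no usage windows to summarize")
    durations = np.array([w.duration for w in windows.values()])
    return {
        "n_individuals": len(windows),
        "total_patient_years": float(durations.sum()),
        "median_duration_years": float(np.median(durations)),
    }
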