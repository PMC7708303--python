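"""Time-resolved gene-phenotype association testing.

At every age bin, carriers of a candidate gene are compared with the rest
of the informative cohort on the presence of each phenotype term, in a 2x2
table tested with a two-sided Fisher exact test (minimum-likelihood
convention, as implemented by scipy).  Each bin is analyzed independently;
no information flows between time points.  For every (gene, term) pair the
most significant bin is selected -- its p-value is ``p_gxp_max`` -- and the
Benjamini-Hochberg step-up procedure is applied across the family of all
tested pairs' ``p_gxp_max`` values at FDR 0.05.

Tests are restricted to genes with at least ``min_carriers`` carriers
(default 2) and to terms outside the modifier branches (age of onset,
severity, quality), which describe phenotypes rather than being phenotypes.
Bins with no informative carrier contribute no p-value rather than p = 1,
so undefined tests do not dilute the max-selection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ontology import DEFAULT_MODIFIER_ROOTS, OntologyGraph
from .temporal import PresenceTensor

logger = logging.getLogger(__name__)

NO_GENE = "none"


@dataclass(frozen=True)
class ContingencyTable:
    """Counts at one bin: carriers/non-carriers x term present/absent."""

    a: int  # carriers, term present
    b: int  # carriers, term absent
    c: int  # non-carriers, term present
    d: int  # non-carriers, term absent

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@lru_cache(maxsize=200_000)
def _fisher_cached(a: int, b: int, c: int, d: int) -> float:
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def fisher_two_sided(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    Sums hypergeometric point probabilities (margins fixed) of all tables
    at most as probable as the observed one (relative tolerance 1 + 1e-7).
    Any zero margin admits a single table and returns 1.
    """
    return min(_fisher_cached(table.a, table.b, table.c, table.d), 1.0)


def neg_log10(p: float) -> float:
    """-log10 of a p-value, the scale used in association reports."""
    return -math.log10(p)


@dataclass
class AssociationResult:
    """Max-over-time association of one gene with one term."""

    gene: str
    term: str
    p_by_bin: np.ndarray        # NaN where untestable (no informative carrier)
    p_gxp_max: float            # min over defined bins (1.0 if none defined)
    argmax_bin: int             # earliest bin attaining the min; -1 if none
    table_at_max: ContingencyTable | None
    bh_significant: bool = False

    @property
    def nominal_significant(self) -> bool:
        return self.p_gxp_max < 0.05


def _carrier_mask(tensor: PresenceTensor, genotypes: pd.DataFrame, gene: str) -> np.ndarray:
    gt = genotypes.set_index(genotypes["individual_id"].astype(str))["gene"]
    return np.array([gt.get(ind, NO_GENE) == gene for ind in tensor.individuals])


def contingency_at_bin(
    tensor: PresenceTensor,
    genotypes: pd.DataFrame,
    gene: str,
    term: str,
    bin_index: int,
) -> ContingencyTable:
    """2x2 table at one bin, restricted to informative individuals.

    Carriers are individuals whose causative gene equals *gene*; the
    comparison group is every other informative individual, including
    those with no genetic diagnosis.
    """
    car = _carrier_mask(tensor, genotypes, gene)
    inf = tensor.informative[:, bin_index]
    pres = tensor.present[:, bin_index, tensor.term_idx(term)]
    a = int((car & inf & pres).sum())
    b = int((car & inf & ~pres).sum())
    c = int((~car & inf & pres).sum())
    d = int((~car & inf & ~pres).sum())
    return ContingencyTable(a, b, c, d)


def scan_pair(
    tensor: PresenceTensor,
    genotypes: pd.DataFrame,
    gene: str,
    term: str,
) -> AssociationResult:
    """Per-bin Fisher tests for one (gene, term) pair with max-selection.

    Bins with no informative carrier are untestable (NaN).  ``p_gxp_max``
    is the minimum defined p-value; ties break to the earliest bin.
    """
    car = _carrier_mask(tensor, genotypes, gene)
    if not car.any():
        raise ValueError(f"gene {gene!r} has no carriers in the genotype table")
    t = tensor.term_idx(term)
    p = np.full(tensor.n_bins, np.nan)
    tables: dict[int, ContingencyTable] = {}
    for b in range(tensor.n_bins):
        inf = tensor.informative[:, b]
        if not (car & inf).any():
            continue
        pres = tensor.present[:, b, t]
        tab = ContingencyTable(
            int((car & inf & pres).sum()), int((car & inf & ~pres).sum()),
            int((~car & inf & pres).sum()), int((~car & inf & ~pres).sum()),
        )
        tables[b] = tab
        p[b] = fisher_two_sided(tab)
    if np.isnan(p).all():
        return AssociationResult(gene, term, p, 1.0, -1, None)
    argmax = int(np.nanargmin(p))  # earliest bin on ties
    return AssociationResult(gene, term, p, float(p[argmax]), argmax, tables[argmax])


def bh_stepup(pvalues, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at FDR *q*."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    return multipletests(p, alpha=q, method="fdr_bh")[0]


def run_study(
    tensor: PresenceTensor,
    genotypes: pd.DataFrame,
    graph: OntologyGraph,
    min_carriers: int = 2,
    fdr_q: float = 0.05,
    modifier_roots=DEFAULT_MODIFIER_ROOTS,
) -> pd.DataFrame:
    """Test all qualifying (gene, term) pairs and apply BH FDR control.

    Genes need >= *min_carriers* carriers in the genotype table; terms in
    the tensor falling under any modifier branch root are excluded.  The
    BH family is the set of all tested pairs' ``p_gxp_max`` values.

    Returns a frame ranked by ``p_gxp_max`` with the contingency counts at
    the most significant bin and nominal / BH significance flags.
    """
    counts = genotypes.loc[genotypes["gene"] != NO_GENE, "gene"].value_counts()
    genes = sorted(counts[counts >= min_carriers].index)
    roots = [graph.resolve(r) for r in modifier_roots if r in graph or r in graph.alt_ids]
    terms = [t for t in tensor.terms if not graph.in_branch(t, roots)]
    if not genes or not terms:
        logger.warning("empty test family (%d genes, %d terms)", len(genes), len(terms))
        return _as_frame([], graph, tensor)

    gt = genotypes.set_index(genotypes["individual_id"].astype(str))["gene"]
    gene_of = np.array([gt.get(ind, NO_GENE) for ind in tensor.individuals])
    n_inf = tensor.informative.sum(axis=0)  # informative individuals per bin
    pres_all = tensor.present.sum(axis=0)   # (n_bins, n_terms)

    results: list[AssociationResult] = []
    for gene in genes:
        car = gene_of == gene
        inf_car = tensor.informative[car].sum(axis=0)          # (n_bins,)
        pres_car = tensor.present[car].sum(axis=0)             # (n_bins, n_terms)
        testable = inf_car >= 1
        for term in terms:
            t = tensor.term_idx(term)
            p = np.full(tensor.n_bins, np.nan)
            best_p, best_bin, best_tab = np.inf, -1, None
            for b in np.nonzero(testable)[0]:
                a = int(pres_car[b, t])
                bb = int(inf_car[b]) - a
                c = int(pres_all[b, t]) - a
                d = int(n_inf[b] - inf_car[b]) - c
                pv = _fisher_cached(a, bb, c, d)
                p[b] = pv
                if pv < best_p:
                    best_p, best_bin, best_tab = pv, int(b), ContingencyTable(a, bb, c, d)
            if best_bin < 0:
                results.append(AssociationResult(gene, term, p, 1.0, -1, None))
            else:
                results.append(AssociationResult(gene, term, p, min(best_p, 1.0), best_bin, best_tab))

    reject = bh_stepup([r.p_gxp_max for r in results], q=fdr_q)
    for r, rej in zip(results, reject):
        r.bh_significant = bool(rej)
    return _as_frame(results, graph, tensor)


def _as_frame(results, graph: OntologyGraph, tensor: PresenceTensor) -> pd.DataFrame:
    rows = []
    for r in results:
        tab = r.table_at_max
        rows.append({
            "gene": r.gene,
            "hpo_id": r.term,
            "hpo_name": graph.name(r.term),
            "argmax_bin": r.argmax_bin,
            "argmax_age_years": (
                tensor.grid.bin_start(r.argmax_bin) if r.argmax_bin >= 0 else np.nan
            ),
            "p_gxp_max": r.p_gxp_max,
            "neg_log10_p": neg_log10(r.p_gxp_max),
            "a_carriers_present": tab.a if tab else 0,
            "b_carriers_absent": tab.b if tab else 0,
            "c_others_present": tab.c if tab else 0,
            "d_others_absent": tab.d if tab else 0,
            "nominal_significant": r.nominal_significant,
            "bh_significant": r.bh_significant,
        })
    cols = ["gene", "hpo_id", "hpo_name", "argmax_bin", "argmax_age_years",
            "p_gxp_max", "neg_log10_p", "a_carriers_present", "b_carriers_absent",
            "c_others_present", "d_others_absent", "nominal_significant", "bh_significant"]
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values(["p_gxp_max", "gene", "hpo_id"], ignore_index=True)


def pair_trajectory(result_row: pd.Series, tensor: PresenceTensor,
                    genotypes: pd.DataFrame) -> pd.DataFrame:
    """Recompute the full per-bin p-value trajectory for one ranked row."""
    r = scan_pair(tensor, genotypes, result_row["gene"], result_row["hpo_id"])
    return pd.DataFrame({
        "bin": np.arange(tensor.n_bins),
        "age_years": np.arange(tensor.n_bins) * tensor.grid.bin_width,
        "p": r.p_by_bin,
    })
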