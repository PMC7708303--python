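"""Fisher exact testing, max-over-time selection, and BH FDR control."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import phenochron as pc
from phenochron.association import (
    ContingencyTable,
    bh_stepup,
    fisher_two_sided,
    neg_log10,
)


def fisher_oracle(a, b, c, d):
    """Exhaustive hypergeometric enumeration with the minimum-likelihood
    two-sided convention (tables at most as probable as the observed one,
    relative tolerance 1 + 1e-7)."""
    n1, n2, m1 = a + b, c + d, a + c
    N = n1 + n2
    if min(n1, n2, m1, b + d) == 0:
        return 1.0
    support = np.arange(max(0, m1 - n2), min(n1, m1) + 1)
    pmf = stats.hypergeom.pmf(support, N, n1, m1)
    p_obs = stats.hypergeom.pmf(a, N, n1, m1)
    return min(float(pmf[pmf <= p_obs * (1 + 1e-7)].sum()), 1.0)


def bh_oracle(pvals, q):
    """Independent step-up: reject the k smallest where k is the largest
    index with p_(k) <= k q / m."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    k = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            k = rank
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject


class TestFisher:
    def test_all_or_nothing_table(self):
        # margins 3/5 and 3/5: only the observed table is as extreme
        assert fisher_two_sided(ContingencyTable(3, 0, 0, 5)) == pytest.approx(1 / 56)

    def test_zero_margin_gives_one(self):
        assert fisher_two_sided(ContingencyTable(0, 10, 0, 10)) == 1.0
        assert fisher_two_sided(ContingencyTable(0, 0, 5, 5)) == 1.0

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            a, b, c, d = rng.integers(0, 16, size=4)
            p = fisher_two_sided(ContingencyTable(int(a), int(b), int(c), int(d)))
            assert p == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-12)
            assert 0 < p <= 1

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 0, 0, 0)

    def test_enrichment_monotone_in_odds_ratio(self):
        # stronger planted effect -> smaller two-sided p (others fixed)
        ps = [fisher_two_sided(ContingencyTable(a, 10 - a, 5, 45)) for a in (5, 7, 9)]
        assert ps[0] > ps[1] > ps[2]

    def test_neg_log10_of_reported_extreme(self):
        assert round(neg_log10(1.84e-7), 2) == 6.74


class TestBH:
    def test_textbook_stepup(self):
        reject = bh_stepup([0.001, 0.01, 0.03, 0.04], q=0.05)
        assert reject.all()  # largest k with p_(k) <= k*0.05/4 is k=4

    def test_empty_family(self):
        assert bh_stepup([], q=0.05).size == 0

    def test_matches_stepup_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            m = rng.integers(1, 40)
            p = rng.random(m) ** rng.integers(1, 4)
            assert (bh_stepup(p, 0.05) == bh_oracle(p, 0.05)).all()


@pytest.fixture(scope="module")
def planted():
    """A small planted cohort analysed once, shared across tests."""
    graph = pc.load_fixture_ontology()
    dictionary = pc.load_dictionary(pc.fixture_path("mini_dictionary.tsv"), graph)
    cohort = pc.generate_cohort(pc.recovery_config(seed=5))
    mapped, _ = pc.map_encounters(cohort.encounters, dictionary)
    windows = pc.usage_windows(cohort.encounters)
    tensor = pc.build_presence(mapped, graph, pc.BinGrid(), windows)
    return graph, cohort, tensor


class TestContingency:
    def test_counts_partition_informative(self, planted):
        graph, cohort, tensor = planted
        for b in (4, 20, 60):
            tab = pc.contingency_at_bin(tensor, cohort.genotypes, "SCN1A", "HP:0001250", b)
            assert tab.n == tensor.informative[:, b].sum()

    def test_no_informative_carriers_gives_empty_carrier_row(self, planted):
        graph, cohort, tensor = planted
        tab = pc.contingency_at_bin(tensor, cohort.genotypes, "__absent__", "HP:0001250", 0)
        assert tab.a == tab.b == 0
        assert tab.n == tensor.informative[:, 0].sum()

    def test_planted_effect_enriches_carriers(self, planted):
        graph, cohort, tensor = planted
        tab = pc.contingency_at_bin(tensor, cohort.genotypes, "SCN1A", "HP:0002133", 3)
        carrier_freq = tab.a / (tab.a + tab.b)
        other_freq = tab.c / (tab.c + tab.d)
        assert carrier_freq > 4 * other_freq


class TestScanPair:
    def test_zero_carrier_gene_errors(self, planted):
        graph, cohort, tensor = planted
        with pytest.raises(ValueError, match="no carriers"):
            pc.scan_pair(tensor, cohort.genotypes, "NOT_A_GENE", "HP:0001250")

    def test_term_never_present_yields_p_one(self, planted):
        graph, cohort, tensor = planted
        # neonatal onset modifier is rarely coded; find any all-absent term
        counts = tensor.present.sum(axis=(0, 1))
        if (counts == 0).any():
            term = tensor.terms[int(np.argmin(counts))]
            r = pc.scan_pair(tensor, cohort.genotypes, "SCN1A", term)
            assert r.p_gxp_max == 1.0

    def test_max_selection_and_tie_break(self, planted):
        graph, cohort, tensor = planted
        r = pc.scan_pair(tensor, cohort.genotypes, "SCN1A", "HP:0002133")
        defined = ~np.isnan(r.p_by_bin)
        assert r.p_gxp_max == np.nanmin(r.p_by_bin)
        # earliest bin attaining the minimum
        assert r.argmax_bin == int(np.flatnonzero(r.p_by_bin == r.p_gxp_max)[0])
        assert defined[r.argmax_bin]

    def test_untestable_bins_are_nan_not_one(self, planted):
        graph, cohort, tensor = planted
        gt = cohort.genotypes.set_index("individual_id")["gene"]
        # a rare gene: some bins will have no informative carrier
        gene = gt[gt != "none"].value_counts().index[-1]
        car_idx = [i for i, ind in enumerate(tensor.individuals) if gt[ind] == gene]
        r = pc.scan_pair(tensor, cohort.genotypes, gene, "HP:0001250")
        inf_car = tensor.informative[car_idx].sum(axis=0)
        assert np.isnan(r.p_by_bin[inf_car == 0]).all()
        assert not np.isnan(r.p_by_bin[inf_car > 0]).any()


class TestRunStudy:
    def test_ranked_output_and_flags(self, planted):
        graph, cohort, tensor = planted
        res = pc.run_study(tensor, cohort.genotypes, graph)
        assert (res["p_gxp_max"].diff().dropna() >= 0).all()
        assert ((res["p_gxp_max"] < 0.05) == res["nominal_significant"]).all()
        counts = cohort.genotypes["gene"].value_counts()
        tested = set(res["gene"])
        assert all(counts[g] >= 2 for g in tested)
        assert "none" not in tested

    def test_modifier_terms_excluded(self, planted):
        graph, cohort, tensor = planted
        res = pc.run_study(tensor, cohort.genotypes, graph)
        modifier_terms = {
            t for t in tensor.terms if graph.in_branch(t, pc.DEFAULT_MODIFIER_ROOTS)
        }
        assert modifier_terms  # fixture dictionary does map a modifier
        assert not (set(res["hpo_id"]) & modifier_terms)

    def test_scan_pair_agrees_with_study_row(self, planted):
        graph, cohort, tensor = planted
        res = pc.run_study(tensor, cohort.genotypes, graph)
        row = res.iloc[0]
        r = pc.scan_pair(tensor, cohort.genotypes, row["gene"], row["hpo_id"])
        assert r.p_gxp_max == pytest.approx(row["p_gxp_max"], rel=1e-12)
        assert r.argmax_bin == row["argmax_bin"]

    def test_empty_family_warns_and_returns_empty(self, planted):
        graph, cohort, tensor = planted
        lonely = pd.DataFrame({"individual_id": tensor.individuals,
                               "gene": ["none"] * len(tensor.individuals)})
        res = pc.run_study(tensor, lonely, graph)
        assert res.empty
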