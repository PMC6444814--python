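"""Scoring, distances, clustering and the implausibility FDR estimator."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonecall.evaluation import (
    MUTATED,
    UNMUTATED,
    ClonalConfusion,
    classify_clonal_calls,
    cluster,
    dendrogram_newick,
    genotype_confusion,
    genotype_matrix,
    implausibility_fdr,
    metrics,
    pairwise_distance,
)
from clonecall.formats import GenotypeState, GsnvRecord, SiteCall, SiteTable
from clonecall.simulator import TrueLocus, TruthTable

GS = GenotypeState


def _locus(i, s_pos, snv=1, eal=0, mutated_clone=0):
    return TrueLocus(
        locus_id=i, contig="t", g_pos=s_pos - 30, s_pos=s_pos, g_ref="A", g_alt="G",
        s_ref="C", s_alt="T", snv=snv, eal=eal,
        mutated_clone=mutated_clone if snv else -1,
        snv_on_galt=1 if snv else -1, eal_on_galt=1 if eal else -1,
    )


def _truth(loci, n_cells=4):
    cells = [f"c{i}" for i in range(n_cells)]
    clone_of = {c: (0 if i < n_cells // 2 else 1) for i, c in enumerate(cells)}
    return TruthTable(loci=list(loci), cells=cells, clone_of=clone_of)


def _calls(sites, samples):
    return SiteTable(sites, samples)


def _site(pos, genotypes):
    s = SiteCall("t", pos, "C", "T")
    s.genotypes = dict(genotypes)
    return s


class TestMetrics:
    def test_exact_ratios(self):
        c = ClonalConfusion(tp=90, fn=10, tn=50, fp=50)
        m = metrics(c)
        assert m["sensitivity"] == 0.9
        assert m["specificity"] == 0.5
        assert m["fdr"] == 50 / 140

    def test_zero_denominators_are_missing_not_zero(self):
        m = metrics(ClonalConfusion())
        assert m == {"sensitivity": None, "specificity": None, "fdr": None}

    def test_no_false_positives_gives_zero_fdr(self):
        assert metrics(ClonalConfusion(tp=100))["fdr"] == 0.0


class TestClonalClassification:
    def test_two_or_more_cells_rule(self):
        truth = _truth([_locus(0, 1000), _locus(1, 4000), _locus(2, 7000, snv=0, eal=1)])
        samples = truth.cells
        sites = [
            _site(1000, {"c0": GS.HET_C1, "c1": GS.HET_C2, "c2": GS.HOM_C1}),  # TP
            _site(4000, {"c0": GS.HET_C1, "c1": GS.HOM_C1}),  # only 1 mutated -> FN
            _site(7000, {"c0": GS.HET_C1, "c1": GS.HET_C3, "c2": GS.HET_C1}),  # EAL -> FP
        ]
        c = classify_clonal_calls(_calls(sites, samples), truth)
        assert (c.tp, c.fn, c.fp, c.tn) == (1, 1, 1, 0)

    def test_call_outside_locus_set_counts_unmatched(self):
        truth = _truth([_locus(0, 1000)])
        sites = [_site(2222, {"c0": GS.HET_C1, "c1": GS.HET_C1})]
        c = classify_clonal_calls(_calls(sites, truth.cells), truth)
        assert c.unmatched_calls == 1 and c.fn == 1


class TestGenotypeConfusion:
    def test_six_way_binning(self):
        truth = _truth([_locus(0, 1000, mutated_clone=0)])  # c0,c1 het; c2,c3 hom
        sites = [
            _site(1000, {"c0": GS.HET_C1,      # true het
                         "c1": GS.HOM_C2,      # false hom
                         "c2": GS.HET_C3,      # false het
                         "c3": GS.CONFLICT})   # no prediction (hom truth)
        ]
        c = genotype_confusion(_calls(sites, truth.cells), truth)
        assert (c.true_het, c.false_hom, c.false_het, c.no_prediction_hom) == (1, 1, 1, 1)
        assert c.true_hom == 0 and c.no_prediction_het == 0

    def test_uncalled_site_is_no_prediction_everywhere(self):
        truth = _truth([_locus(0, 1000, mutated_clone=0)])
        c = genotype_confusion(_calls([], truth.cells), truth)
        assert (c.no_prediction_het, c.no_prediction_hom) == (2, 2)


class TestPairwiseDistance:
    def _matrix(self):
        return pd.DataFrame(
            {
                "s1": [MUTATED, MUTATED, UNMUTATED],
                "s2": [MUTATED, MUTATED, UNMUTATED],
                "s3": [MUTATED, MUTATED, np.nan],
                "s4": [UNMUTATED, MUTATED, np.nan],
            },
            index=["a", "b", "c"],
        )

    def test_concordant_minus_discordant(self):
        d = pairwise_distance(self._matrix())
        assert d.loc["a", "b"] == -3 + 1  # 3 concordant, 1 discordant
        assert d.loc["a", "c"] == 2  # 2 shared sites, both discordant

    def test_identical_cells_over_k_sites(self):
        m = pd.DataFrame({f"s{i}": [MUTATED, MUTATED] for i in range(5)}, index=["a", "b"])
        assert pairwise_distance(m).loc["a", "b"] == -5

    def test_no_shared_sites_is_missing(self):
        m = pd.DataFrame(
            {"s1": [MUTATED, np.nan], "s2": [np.nan, MUTATED]}, index=["a", "b"]
        )
        assert np.isnan(pairwise_distance(m).loc["a", "b"])

    def test_symmetric_and_permutation_equivariant(self):
        m = self._matrix()
        d = pairwise_distance(m)
        assert d.equals(d.T)
        perm = m.loc[["c", "a", "b"]]
        dp = pairwise_distance(perm)
        for x in "abc":
            for y in "abc":
                if x != y:
                    assert dp.loc[x, y] == d.loc[x, y]


class TestCluster:
    def test_separated_groups_recovered(self):
        cols = {}
        for i in range(6):
            cols[f"s{i}"] = [MUTATED] * 3 + [UNMUTATED] * 3
        m = pd.DataFrame(cols, index=[f"c{i}" for i in range(6)])
        _, labels = cluster(pairwise_distance(m), k=2)
        assert len({labels[c] for c in ["c0", "c1", "c2"]}) == 1
        assert labels["c0"] != labels["c3"]

    def test_degenerate_all_zero_matrix_is_deterministic(self):
        d = pd.DataFrame(np.zeros((4, 4)), index=list("abcd"), columns=list("abcd"))
        _, l1 = cluster(d, k=2)
        _, l2 = cluster(d, k=2)
        assert l1 == l2

    def test_single_cell_rejected(self):
        d = pd.DataFrame([[0.0]], index=["a"], columns=["a"])
        with pytest.raises(ValueError):
            cluster(d)

    def test_newick_serialization_contains_all_leaves(self):
        cols = {f"s{i}": [MUTATED, MUTATED, UNMUTATED, UNMUTATED] for i in range(3)}
        m = pd.DataFrame(cols, index=list("abcd"))
        z, _ = cluster(pairwise_distance(m), k=2)
        nwk = dendrogram_newick(z, list(m.index))
        assert nwk.endswith(";") and all(leaf in nwk for leaf in "abcd")


class TestImplausibilityFdr:
    CLONES = {"a": 0, "b": 0, "c": 1, "d": 1}

    def _m(self, cols):
        return pd.DataFrame(cols, index=list("abcd"))

    def test_single_clone_site_is_plausible(self):
        m = self._m({"s1": [MUTATED, MUTATED, UNMUTATED, UNMUTATED]})
        fdr, pl, im = implausibility_fdr(m, self.CLONES)
        assert (fdr, pl, im) == (0.0, 1, 0)

    def test_cross_clone_with_reference_cell_is_implausible(self):
        m = self._m({"s1": [MUTATED, UNMUTATED, MUTATED, np.nan]})
        fdr, pl, im = implausibility_fdr(m, self.CLONES)
        assert (fdr, pl, im) == (1.0, 0, 1)

    def test_cross_clone_without_reference_cell_is_excluded(self):
        m = self._m({"s1": [MUTATED, MUTATED, MUTATED, np.nan]})
        fdr, pl, im = implausibility_fdr(m, self.CLONES)
        assert (fdr, pl, im) == (None, 0, 0)

    def test_mixture_gives_ratio(self):
        m = self._m(
            {
                "s1": [MUTATED, MUTATED, UNMUTATED, UNMUTATED],
                "s2": [MUTATED, np.nan, UNMUTATED, np.nan],
                "s3": [MUTATED, UNMUTATED, MUTATED, UNMUTATED],
            }
        )
        fdr, pl, im = implausibility_fdr(m, self.CLONES)
        assert (pl, im) == (2, 1)
        assert fdr == pytest.approx(1 / 3)

    def test_single_clone_labelling_rejected(self):
        m = self._m({"s1": [MUTATED] * 4})
        with pytest.raises(ValueError):
            implausibility_fdr(m, {c: 0 for c in "abcd"})


class TestGenotypeMatrix:
    def test_states_map_to_three_values(self):
        site = _site(1000, {"c0": GS.HET_C1, "c1": GS.HOM_C3, "c2": GS.CONFLICT,
                            "c3": GS.NONE})
        m = genotype_matrix(_calls([site], [f"c{i}" for i in range(4)]))
        col = m["t:1000"]
        assert col["c0"] == MUTATED and col["c1"] == UNMUTATED
        assert pd.isna(col["c2"]) and pd.isna(col["c3"])
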