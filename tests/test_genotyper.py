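"""Tuple-pair voting, genotype classification and site-level filters."""

from __future__ import annotations

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonecall.formats import FragmentObservation, GenotypeState, GsnvRecord, SiteCall, SiteTable
from clonecall.genotyper import (
    TP_RA_AR,
    TP_RR_AA,
    GenotypeParams,
    TupleCounts,
    aggregate_genotype,
    apply_site_filters,
    classify_genotype,
    infer_low_depth_genotype,
    resolve_tp_star,
    sample_tp_vote,
    tuple_counts,
)

P = GenotypeParams()
GS = GenotypeState
GSNV = GsnvRecord("t", 541, "A", "G")


def tc(rr=0, ra=0, ar=0, aa=0) -> TupleCounts:
    return TupleCounts(rr=rr, ra=ra, ar=ar, aa=aa)


class TestTupleCounts:
    def test_observation_to_counter_mapping(self):
        obs = [
            FragmentObservation("c", "C", "G", "f1"),  # site ref, gSNV alt -> RA
            FragmentObservation("c", "T", "A", "f2"),  # site alt, gSNV ref -> AR
            FragmentObservation("c", "C", "A", "f3"),  # RR
            FragmentObservation("c", "T", "G", "f4"),  # AA
            FragmentObservation("c", "G", "A", "f5"),  # third base at site
        ]
        c = tuple_counts(obs, site_ref="C", site_alt="T", gsnv=GSNV)
        assert (c.rr, c.ra, c.ar, c.aa, c.other) == (1, 1, 1, 1, 1)
        assert c.n_tot == 4


class TestSampleTpVote:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            (tc(rr=20, aa=18), TP_RR_AA),         # clean het pair, internal 18/38 > 0.1
            (tc(rr=20, aa=18, ra=5), None),        # minor pair 5/38 >= rho
            (tc(rr=1, aa=1), None),                # depth gate: 2 <= phi
            (tc(aa=30), TP_RR_AA),                 # variant tuple is the single max
            (tc(ra=30), None),                     # non-variant tuple dominates, internal 0
            (tc(rr=15, ra=15), None),              # tuple-pair depth tie abstains
            (tc(ra=20, ar=18), TP_RA_AR),
            (tc(ar=30), TP_RA_AR),                 # AR is the variant tuple of {RA,AR}
            (tc(rr=30), None),                     # only RR: internal 0 and AA not max
        ],
    )
    def test_vote(self, counts, expected):
        assert sample_tp_vote(counts, P) == expected


class TestResolveTpStar:
    def test_unanimous_quorum_fixes_informative_allele(self):
        r = resolve_tp_star([TP_RR_AA] * 5, P)
        assert (r.tp_star, r.informative_gsnv_base) == (TP_RR_AA, "alt")
        assert r.voter_count == 5 and r.majority_fraction == 1.0

    def test_majority_below_omega_stays_unknown(self):
        r = resolve_tp_star([TP_RR_AA] * 9 + [TP_RA_AR] * 2, P)
        assert r.tp_star is None  # 9/11 = 0.818 < 0.9

    def test_single_voter_below_kappa(self):
        assert resolve_tp_star([TP_RR_AA], P).tp_star is None

    def test_ra_ar_pair_marks_reference_allele_informative(self):
        r = resolve_tp_star([TP_RA_AR] * 3, P)
        assert r.informative_gsnv_base == "ref"


class TestClassifyGenotype:
    @pytest.mark.parametrize(
        "counts,tp,expected",
        [
            (tc(rr=10, aa=10), TP_RR_AA, GS.HET_C1),
            (tc(ra=12), TP_RR_AA, GS.HOM_C2),     # informative allele, unmutated
            (tc(ra=12), TP_RA_AR, GS.NONE),       # only non-informative reads
            (tc(rr=16, aa=2, ra=2), TP_RR_AA, GS.CONFLICT),  # het_C1 and hom_C1 both hold
            (tc(aa=12), TP_RR_AA, GS.HET_C2),     # informative-only, mutated
            (tc(rr=12), TP_RR_AA, GS.NONE),       # non-informative only
            (tc(rr=12, ra=12), TP_RR_AA, GS.HOM_C1),
            (tc(ra=10, ar=10), TP_RA_AR, GS.HET_C1),
            (tc(ar=12), TP_RA_AR, GS.HET_C2),
            (tc(rr=12), TP_RA_AR, GS.HOM_C2),
            (tc(rr=30, ra=5, aa=5), TP_RR_AA, GS.CONFLICT),  # both informative states seen
            (tc(rr=1, aa=1), TP_RR_AA, GS.NONE),  # below depth gate
            (tc(rr=10, aa=10), None, GS.NONE),    # tp* unresolved
        ],
    )
    def test_case_analysis(self, counts, tp, expected):
        assert classify_genotype(counts, tp, P) == expected

    def test_tp_vote_contradiction_is_conflict(self):
        assert classify_genotype(tc(rr=10, aa=10), TP_RA_AR, P, sample_tp=TP_RR_AA) is GS.CONFLICT

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        counts=st.tuples(*[st.integers(0, 12)] * 4),
        tp=st.sampled_from([TP_RR_AA, TP_RA_AR]),
        k=st.integers(2, 5),
    )
    def test_scaling_depths_preserves_c1_c2_states(self, counts, tp, k):
        c1 = tc(*counts)
        ck = tc(*(k * x for x in counts))
        if c1.n_tot <= P.phi:
            return
        a, b = classify_genotype(c1, tp, P), classify_genotype(ck, tp, P)
        # the chi/xi dual-support floors are absolute depths, so scaling can
        # only move a state *into* conflict, never between het/hom classes
        assert a == b or b is GS.CONFLICT

    def test_informative_allele_guarantee_exhaustive(self):
        """Every C1/C2 call implies >=1 read from the informative allele; no
        hom call is ever made from non-informative reads alone."""
        for counts in itertools.product(range(0, 9), repeat=4):
            c = tc(*counts)
            for tp in (TP_RR_AA, TP_RA_AR):
                state = classify_genotype(c, tp, P)
                informative = c.ra + c.aa if tp == TP_RR_AA else c.rr + c.ar
                if state in (GS.HET_C1, GS.HOM_C1, GS.HET_C2, GS.HOM_C2):
                    assert informative >= 1, (counts, tp, state)
                if state in (GS.HOM_C1, GS.HOM_C2):
                    assert (c.ra if tp == TP_RR_AA else c.rr) >= 1


class TestInferLowDepth:
    @pytest.mark.parametrize(
        "counts,tp,expected",
        [
            (tc(ra=2), TP_RR_AA, GS.HOM_C3),   # 2 > chi
            (tc(aa=2), TP_RR_AA, GS.HET_C3),   # 2 > xi
            (tc(ra=2, aa=2), TP_RR_AA, GS.CONFLICT),
            (tc(ra=1), TP_RR_AA, GS.NONE),     # chi is strict
            (tc(rr=2), TP_RA_AR, GS.HOM_C3),
            (tc(ar=2), TP_RA_AR, GS.HET_C3),
            (tc(rr=2), TP_RR_AA, GS.NONE),     # non-informative reads only
            (tc(aa=2), None, GS.NONE),
        ],
    )
    def test_sparse_inference(self, counts, tp, expected):
        assert infer_low_depth_genotype(counts, tp, P) == expected


def _agg(states, counts, tps=None):
    keys = [("t", i) for i in range(len(counts))]
    per_gsnv = {k: s for k, s in zip(keys, states)}
    counts_by = {k: c for k, c in zip(keys, counts)}
    if tps is None:
        from clonecall.genotyper import TuplePairResolution

        tps = {k: TuplePairResolution(TP_RR_AA, "alt", 5, 1.0) for k in keys}
    return aggregate_genotype(per_gsnv, counts_by, tps, P)


class TestAggregateGenotype:
    def test_unanimous_gsnvs(self):
        c = tc(rr=10, aa=10)
        assert _agg([GS.HET_C1] * 3, [c] * 3) is GS.HET_C1

    def test_split_vote_is_conflict(self):
        assert (
            _agg([GS.HET_C1, GS.HET_C1, GS.HOM_C1], [tc(rr=10, aa=10)] * 3) is GS.CONFLICT
        )

    def test_low_depth_delegates_to_c3(self):
        assert _agg([], [tc(ra=2)]) is GS.HOM_C3
        assert _agg([], [tc(aa=2)]) is GS.HET_C3

    def test_sufficient_depth_without_votes_stays_none(self):
        # 12 non-informative reads: the classifier abstained, not the depth
        assert _agg([GS.NONE], [tc(rr=12)]) is GS.NONE


def _site(pos, genotypes, bulk_depth=40):
    s = SiteCall("t", pos, "A", "T", tp_star=TP_RR_AA, bulk_depth=bulk_depth)
    s.genotypes = dict(genotypes)
    return s


def _states(n_het=0, n_hom=0, n_conflict=0, n_none=0):
    out = {}
    i = 0
    for state, n in [(GS.HET_C1, n_het), (GS.HOM_C1, n_hom),
                     (GS.CONFLICT, n_conflict), (GS.NONE, n_none)]:
        for _ in range(n):
            out[f"c{i}"] = state
            i += 1
    return out


class TestSiteFilters:
    SAMPLES = [f"c{i}" for i in range(6)]

    def test_conflicting_sample_drops_site(self):
        t = SiteTable([_site(1000, _states(n_het=3, n_hom=2, n_conflict=1))], self.SAMPLES)
        assert len(apply_site_filters(t, P)) == 0

    def test_two_passing_sites_within_a_kilobase_both_drop(self):
        t = SiteTable(
            [_site(1000, _states(n_het=3, n_hom=3)), _site(1400, _states(n_het=3, n_hom=3))],
            self.SAMPLES,
        )
        assert len(apply_site_filters(t, P)) == 0

    def test_distant_passing_sites_survive(self):
        t = SiteTable(
            [_site(1000, _states(n_het=3, n_hom=3)), _site(2500, _states(n_het=3, n_hom=3))],
            self.SAMPLES,
        )
        assert len(apply_site_filters(t, P)) == 2

    def test_single_mutated_sample_below_kappa_drops(self):
        t = SiteTable([_site(1000, _states(n_het=1, n_hom=5))], self.SAMPLES)
        assert len(apply_site_filters(t, P)) == 0

    def test_bulk_depth_cap_drops_site(self):
        t = SiteTable([_site(1000, _states(n_het=3, n_hom=3), bulk_depth=80)], self.SAMPLES)
        assert len(apply_site_filters(t, P, bulk_depth_cap=55)) == 0
        assert len(apply_site_filters(t, P, bulk_depth_cap=90)) == 1
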