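"""Hypergeometric enrichment and BH adjustment against independent oracles."""

import itertools
import random
from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metorigin.enrichment import (
    bh_adjust,
    hypergeom_sf,
    pathway_enrichment,
    pathway_universe,
)
from metorigin.errors import ConfigError, DomainError
from metorigin.kegg_db import KeggCompound, KeggPathway, build_database


def sf_by_enumeration(k, K, n, N):
    """P[X >= k] by exhaustively drawing every n-subset of an N-universe."""
    marked = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return Fraction(hits, total)


def bh_by_hand(p_values):
    """The BH step-up formula applied literally, returned in input order."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        q = p_values[i] * m / rank_from_top
        running_min = min(running_min, q)
        adjusted[i] = min(running_min, 1.0)
    return adjusted


class TestHypergeomSf:
    def test_k_zero_is_certain(self):
        assert hypergeom_sf(0, 3, 4, 10) == 1.0
        assert hypergeom_sf(0, 0, 0, 1) == 1.0

    def test_all_marked_all_drawn(self):
        # drawing 5 of 10 and hitting all 5 marked: 1 draw of C(10,5)=252
        assert hypergeom_sf(5, 5, 5, 10) == pytest.approx(1 / 252, abs=1e-15)
        assert sf_by_enumeration(5, 5, 5, 10) == Fraction(1, 252)

    @pytest.mark.parametrize("trial_seed", range(3))
    def test_matches_enumeration_on_random_small_instances(self, trial_seed):
        rng = random.Random(trial_seed)
        for _ in range(15):
            N = rng.randint(1, 12)
            K = rng.randint(0, N)
            n = rng.randint(0, N)
            k = rng.randint(0, min(K, n))
            exact = float(sf_by_enumeration(k, K, n, N))
            assert hypergeom_sf(k, K, n, N) == pytest.approx(exact, abs=1e-12)

    def test_monotone_decreasing_in_k(self):
        values = [hypergeom_sf(k, 10, 8, 30) for k in range(9)]
        assert values == sorted(values, reverse=True)

    @pytest.mark.parametrize(
        "args, message",
        [((1, 11, 5, 10), "K <= N"), ((1, 5, 11, 10), "n <= N"),
         ((6, 5, 8, 10), "min"), ((-1, 5, 5, 10), "non-negative")],
    )
    def test_constraint_violations_name_the_inequality(self, args, message):
        with pytest.raises(DomainError, match=message):
            hypergeom_sf(*args)


class TestBhAdjust:
    def test_hand_worked_example(self):
        assert bh_adjust([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.03, 0.04])

    def test_single_value_unchanged(self):
        assert bh_adjust([0.2]) == [pytest.approx(0.2)]

    def test_ties_stay_tied(self):
        assert bh_adjust([0.5, 0.5, 0.5]) == pytest.approx([0.5, 0.5, 0.5])

    def test_empty_input(self):
        assert bh_adjust([]) == []

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            bh_adjust([0.1, 1.5])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False), max_size=50)
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_step_up_formula(self, p_values):
        assert bh_adjust(p_values) == pytest.approx(bh_by_hand(p_values), abs=1e-12)

    def test_constant_vectors_are_fixed_points(self):
        # q_i = c satisfies c <= c*m/j for every rank j, so BH leaves it alone
        for c in (0.0, 0.05, 0.5, 1.0):
            vec = [c] * 7
            assert bh_adjust(vec) == pytest.approx(vec, abs=1e-12)

    def test_order_invariance_up_to_permutation(self):
        rng = random.Random(5)
        p = [rng.random() for _ in range(20)]
        perm = list(range(20))
        rng.shuffle(perm)
        shuffled = [p[i] for i in perm]
        direct = bh_adjust(p)
        via_perm = bh_adjust(shuffled)
        assert [via_perm[perm.index(i)] for i in range(20)] == pytest.approx(direct)


def tiny_pathway_db(pathways):
    """Database with the given pathway->compound map and matching compounds."""
    compound_ids = sorted({c for members in pathways.values() for c in members})
    return build_database(
        compound_records=[
            KeggCompound(
                compound_id=cid,
                pathway_ids={p for p, mem in pathways.items() if cid in mem},
            )
            for cid in compound_ids
        ],
        pathway_records=[
            KeggPathway(pathway_id=p, name=p, compound_ids=set(mem))
            for p, mem in pathways.items()
        ],
    )


CIDS = [f"C{i:05d}" for i in range(1, 11)]


class TestPathwayEnrichment:
    def test_fully_enriched_pathway(self):
        db = tiny_pathway_db({"map00001": CIDS[:5], "map00002": CIDS[5:]})
        universe = set(CIDS)
        frame = pathway_enrichment(set(CIDS[:5]), db, universe)
        row = frame[frame.pathway_id == "map00001"].iloc[0]
        assert (row.k, row.K, row.n, row.N) == (5, 5, 5, 10)
        assert row.p_raw == pytest.approx(1 / 252, abs=1e-15)

    def test_only_pathways_with_query_members_tested(self):
        db = tiny_pathway_db({"map00001": CIDS[:5], "map00002": CIDS[5:]})
        frame = pathway_enrichment(set(CIDS[:3]), db, set(CIDS))
        assert list(frame.pathway_id) == ["map00001"]
        assert (frame.k >= 1).all()

    def test_unannotated_query_gives_empty_table(self):
        db = tiny_pathway_db({"map00001": CIDS[:5]})
        frame = pathway_enrichment({"C99999"}, db, set(CIDS[:5]) | {"C99999"})
        assert frame.empty

    def test_empty_universe_rejected(self):
        db = tiny_pathway_db({"map00001": CIDS[:5]})
        with pytest.raises(ConfigError):
            pathway_enrichment(set(CIDS[:2]), db, set())

    def test_querying_the_whole_universe_is_never_enriched(self):
        db = tiny_pathway_db({"map00001": CIDS[:4], "map00002": CIDS[2:]})
        frame = pathway_enrichment(set(CIDS), db, set(CIDS))
        assert (frame.p_raw == 1.0).all()

    def test_k_sums_to_pathway_membership_multiset_count(self):
        pathways = {"map00001": CIDS[:6], "map00002": CIDS[4:], "map00003": CIDS[::2]}
        db = tiny_pathway_db(pathways)
        query = set(CIDS[2:7])
        frame = pathway_enrichment(query, db, set(CIDS))
        expected = sum(len(query & set(mem)) for mem in pathways.values())
        assert frame.k.sum() == expected

    def test_planted_pathway_ranks_first(self, synth_bundle):
        _, truth, db = synth_bundle
        universe = pathway_universe(db)
        frame = pathway_enrichment(set(truth.planted["query_compounds"]), db, universe)
        assert frame.iloc[0].pathway_id == truth.planted["pathway_id"]
        assert (frame.k >= 1).all()

    def test_rows_sorted_by_p_then_id(self):
        db = tiny_pathway_db({"map00001": CIDS[:5], "map00002": CIDS[3:8]})
        frame = pathway_enrichment(set(CIDS[:6]), db, set(CIDS))
        ordered = frame.sort_values(["p_raw", "pathway_id"], kind="mergesort")
        assert list(frame.pathway_id) == list(ordered.pathway_id)


class TestPathwayUniverse:
    def test_default_is_pathway_annotated_compounds(self):
        db = tiny_pathway_db({"map00001": CIDS[:5]})
        db.compounds["C99999"] = KeggCompound(compound_id="C99999")
        assert pathway_universe(db) == set(CIDS[:5])
        assert pathway_universe(db, mode="all") == set(CIDS[:5]) | {"C99999"}

    def test_detected_mode_requires_detected(self):
        db = tiny_pathway_db({"map00001": CIDS[:2]})
        with pytest.raises(ConfigError):
            pathway_universe(db, mode="detected")
        assert pathway_universe(db, mode="detected", detected={"C00001"}) == {"C00001"}
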