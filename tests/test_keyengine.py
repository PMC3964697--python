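"""Filter semantics, histograms, normalization, entropy ranking.

The filter oracle is a straight per-taxon predicate scan written
independently of the engine's implementation.
"""

import math

import pytest

from zoomkey.collection import CollectionItem
from zoomkey.fixtures import FixtureSpec, gen_collection, gen_matrix
from zoomkey.keyengine import (
    UNSCORED_BUCKET,
    FilterQuery,
    QueryError,
    apply_filter,
    histogram,
    normalize_view,
    query_from_json,
    rank_characters,
    shannon_entropy,
)
from zoomkey.matrix import CATEGORICAL, UNKNOWN, parse_matrix

FIVE_TAXA = """Taxon,Achene cross-section shape,Blade width:min,Blade width:max
Carex a,trigonous,2,8
Carex b,two-sided,8,12
Carex c,trigonous|two-sided,1,3
Carex d,,4,6
Carex e,two-sided,,
"""


def oracle_remaining(matrix, selections):
    """Brute-force predicate scan: disjunction within, conjunction across,
    UNKNOWN retained."""
    kept = []
    for t in matrix.taxa:
        keep = True
        for cname, sel in selections.items():
            score = t.get(cname)
            if score is UNKNOWN:
                continue
            char = matrix.character(cname)
            if char.kind == CATEGORICAL:
                if not any(s in score for s in sel):
                    keep = False
            else:
                lo, hi = score
                a, b = sel
                if hi < a or lo > b:
                    keep = False
        if keep:
            kept.append(t.taxon)
    return kept


class TestApplyFilter:
    def test_empty_query_keeps_everything(self):
        m = parse_matrix(FIVE_TAXA)
        part = apply_filter(m, FilterQuery())
        assert part.remaining == [t.taxon for t in m.taxa]
        assert part.eliminated == []
        assert part.characters_chosen == []
        assert part.characters_available == m.character_names

    def test_trigonous_selection_keeps_scored_and_unknown(self):
        m = parse_matrix(FIVE_TAXA)
        q = FilterQuery({"Achene cross-section shape": frozenset({"trigonous"})})
        part = apply_filter(m, q)
        # a and c scored trigonous (c multi-valued); d UNKNOWN so retained
        assert part.remaining == ["Carex a", "Carex c", "Carex d"]
        assert part.eliminated == ["Carex b", "Carex e"]

    def test_wide_blade_interval_overlap(self):
        m = parse_matrix(FIVE_TAXA)
        q = FilterQuery({"Blade width": (10.0, math.inf)})
        part = apply_filter(m, q)
        # [8,12] overlaps [10,inf); [2,8] does not; e is UNKNOWN -> retained
        assert part.remaining == ["Carex b", "Carex e"]

    def test_conjunction_across_characters(self):
        m = parse_matrix(FIVE_TAXA)
        q = FilterQuery(
            {
                "Achene cross-section shape": frozenset({"two-sided"}),
                "Blade width": (10.0, math.inf),
            }
        )
        assert apply_filter(m, q).remaining == ["Carex b", "Carex e"]

    def test_unknown_character_in_query_rejected(self):
        m = parse_matrix(FIVE_TAXA)
        with pytest.raises(QueryError):
            apply_filter(m, FilterQuery({"Culm height": (1.0, 2.0)}))
        with pytest.raises(QueryError):
            apply_filter(
                m, FilterQuery({"Achene cross-section shape": frozenset({"winged"})})
            )

    @pytest.mark.parametrize("seed", range(20))
    def test_equivalence_with_predicate_scan(self, seed):
        m = gen_matrix(FixtureSpec(n_taxa=30, unknown_rate=0.2, seed=seed))
        q = _random_query(m, seed)
        part = apply_filter(m, FilterQuery(q))
        assert part.remaining == oracle_remaining(m, q)
        assert part.remaining + part.eliminated  # disjoint cover
        assert set(part.remaining) | set(part.eliminated) == {
            t.taxon for t in m.taxa
        }
        assert not set(part.remaining) & set(part.eliminated)

    @pytest.mark.parametrize("seed", range(10))
    def test_monotonicity_and_idempotence(self, seed):
        m = gen_matrix(FixtureSpec(n_taxa=25, unknown_rate=0.2, seed=100 + seed))
        q = _random_query(m, seed)
        items = list(q.items())
        prev = {t.taxon for t in m.taxa}
        for k in range(1, len(items) + 1):
            part = apply_filter(m, FilterQuery(dict(items[:k])))
            current = set(part.remaining)
            assert current <= prev  # adding selections never enlarges
            prev = current
        # idempotence: re-applying the full query to the remaining set
        full = apply_filter(m, FilterQuery(q))
        sub = parse_matrix_subset(m, full.remaining)
        again = apply_filter(sub, FilterQuery(q))
        assert again.remaining == full.remaining


def parse_matrix_subset(matrix, taxa_names):
    from zoomkey.matrix import Matrix

    keep = set(taxa_names)
    return Matrix(matrix.characters, [t for t in matrix.taxa if t.taxon in keep])


def _random_query(matrix, seed):
    import numpy as np

    rng = np.random.default_rng(10_000 + seed)
    selections = {}
    for char in matrix.characters:
        if rng.random() > 0.3:
            continue
        if char.kind == CATEGORICAL:
            k = 1 + int(rng.integers(0, len(char.states)))
            picks = rng.choice(len(char.states), size=min(k, len(char.states)),
                               replace=False)
            selections[char.name] = frozenset(char.states[i] for i in picks)
        else:
            a = float(rng.uniform(0, 40))
            selections[char.name] = (a, a + float(rng.uniform(0, 30)))
    return selections


class TestHistogram:
    def test_trigonous_by_province_matches_hand_tally(self):
        csv = (
            "Taxon,Achene cross-section shape,Canadian province or territory\n"
            "Carex 01,trigonous,ON|QC\n"
            "Carex 02,trigonous,ON\n"
            "Carex 03,two-sided,BC\n"
            "Carex 04,trigonous,\n"
            "Carex 05,trigonous|two-sided,QC\n"
            "Carex 06,two-sided,ON\n"
            "Carex 07,trigonous,BC|AB\n"
            "Carex 08,,MB\n"
            "Carex 09,trigonous,QC\n"
            "Carex 10,two-sided,\n"
        )
        m = parse_matrix(csv)
        q = FilterQuery({"Achene cross-section shape": frozenset({"trigonous"})})
        result = histogram(m, q, "Canadian province or territory")
        # remaining: 01,02,04,05,07,08,09 (08 unknown achene -> retained)
        # hand tally: ON: 01,02; QC: 01,05,09; BC: 07; AB: 07; MB: 08; unscored: 04
        assert result.buckets == {
            "ON": 2, "QC": 3, "BC": 1, "MB": 1, "AB": 1, UNSCORED_BUCKET: 1,
        }

    def test_empty_remaining_gives_all_zero_buckets(self):
        m = parse_matrix(FIVE_TAXA)
        q = FilterQuery({"Blade width": (100.0, 200.0)})
        result = histogram(m, q, "Achene cross-section shape")
        # only e (UNKNOWN width) survives; it is scored two-sided
        assert result.buckets["trigonous"] == 0
        # a fully scored matrix can empty out entirely
        m2 = parse_matrix(
            "Taxon,Achene cross-section shape,Blade width:min,Blade width:max\n"
            "Carex x,trigonous,2,8\nCarex y,two-sided,1,4\n"
        )
        q2 = FilterQuery({"Blade width": (100.0, 200.0)})
        result2 = histogram(m2, q2, "Achene cross-section shape")
        assert all(v == 0 for v in result2.buckets.values())

    def test_single_valued_buckets_conserve_remaining_count(self):
        for seed in range(10):
            m = gen_matrix(FixtureSpec(n_taxa=20, unknown_rate=0.25, seed=200 + seed))
            q = _random_query(m, seed)
            part = apply_filter(m, FilterQuery(q))
            result = histogram(m, FilterQuery(q), "Inflorescence type")  # single-valued
            assert sum(result.buckets.values()) == len(part.remaining)

    def test_numeric_group_by_directs_to_binning(self):
        m = parse_matrix(FIVE_TAXA)
        with pytest.raises(QueryError, match="binning"):
            histogram(m, FilterQuery(), "Blade width")


def _items_with_drawings(n_taxa, extra_matches=()):
    items = []
    for i in range(n_taxa):
        taxon = f"Carex ficta {i:02d}"
        items.append(
            CollectionItem(
                id=len(items), name=f"{taxon} - drawing", img_ref=f"#{len(items)}",
                facets={"Species": (taxon,),
                        "Image author": ("Mackenzie, K. K.",),
                        "Image type": ("line drawing",)},
            )
        )
        items.append(
            CollectionItem(
                id=len(items), name=f"{taxon} - photo", img_ref=f"#{len(items)}",
                facets={"Species": (taxon,), "Image author": ("Jones, S.",),
                        "Image type": ("field photo",)},
            )
        )
    for taxon in extra_matches:
        items.append(
            CollectionItem(
                id=len(items), name=f"{taxon} - a_second_plate",
                img_ref=f"#{len(items)}",
                facets={"Species": (taxon,),
                        "Image author": ("Mackenzie, K. K.",),
                        "Image type": ("line drawing",)},
            )
        )
    # re-densify ids after construction order
    for pos, item in enumerate(items):
        item.id = pos
    return items


class TestNormalizeView:
    REP = ("Image author", "Mackenzie, K. K.")

    def test_exactly_one_item_per_taxon(self):
        items = _items_with_drawings(6)
        view = normalize_view(items, self.REP)
        assert len(view.items) == 6
        taxa = [i.facets["Species"][0] for i in view.items]
        assert len(set(taxa)) == 6
        assert all(i.facets["Image type"] == ("line drawing",) for i in view.items)
        assert view.missing_taxa == []

    def test_matchless_value_empties_the_view(self):
        items = _items_with_drawings(4)
        view = normalize_view(items, ("Image author", "Nobody"))
        assert view.items == []
        assert len(view.missing_taxa) == 4

    def test_duplicate_match_tie_break_is_lexicographic_with_warning(self):
        items = _items_with_drawings(3, extra_matches=("Carex ficta 01",))
        view = normalize_view(items, self.REP)
        assert len(view.items) == 3
        winner = [i for i in view.items if i.facets["Species"][0] == "Carex ficta 01"]
        assert winner[0].name == "Carex ficta 01 - a_second_plate"  # sorts first
        assert len(view.warnings) == 1 and "Carex ficta 01" in view.warnings[0]

    def test_cardinality_never_exceeds_distinct_taxa(self):
        items = _items_with_drawings(5, extra_matches=("Carex ficta 00",) * 3)
        view = normalize_view(items, self.REP)
        assert len(view.items) <= 5


class TestRankCharacters:
    def test_even_split_outranks_uninformative(self):
        csv = (
            "Taxon,Achene cross-section shape,Style: whether deciduous or persistent\n"
            "Carex a,trigonous,deciduous\n"
            "Carex b,trigonous,deciduous\n"
            "Carex c,two-sided,deciduous\n"
            "Carex d,two-sided,deciduous\n"
        )
        m = parse_matrix(csv)
        part = apply_filter(m, FilterQuery())
        ranking = rank_characters(m, part)
        assert ranking[0][0] == "Achene cross-section shape"
        assert ranking[0][1] == pytest.approx(1.0)
        assert ranking[1][1] == pytest.approx(0.0)

    def test_three_one_distribution_entropy(self):
        assert shannon_entropy([3, 1]) == pytest.approx(0.8113, abs=5e-5)

    def test_all_unknown_scores_zero_in_matrix_order(self):
        csv = (
            "Taxon,Inflorescence type,Proximal spike sexuality\n"
            "Carex a,,\nCarex b,,\n"
        )
        m = parse_matrix(csv, config=None)
        # header-inferred states impossible from empty data -> placeholder ok
        part = apply_filter(m, FilterQuery())
        ranking = rank_characters(m, part)
        assert [r[0] for r in ranking] == m.character_names
        assert all(score == 0.0 for _, score in ranking)

    def test_fewer_than_two_remaining_gives_empty_ranking(self):
        m = parse_matrix(FIVE_TAXA)
        from zoomkey.keyengine import Partition

        part = Partition(["Carex a"], [t.taxon for t in m.taxa][1:],
                         [], m.character_names)
        assert rank_characters(m, part) == []


class TestQueryJson:
    def test_round_trip_through_json(self):
        m = parse_matrix(FIVE_TAXA)
        q = query_from_json('{"selections": {"Blade width": {"min": 10}}}', m)
        assert q.selections["Blade width"] == (10.0, math.inf)
        part = apply_filter(m, q)
        assert part.remaining == ["Carex b", "Carex e"]
        q2 = query_from_json(
            '{"selections": {"Achene cross-section shape": ["trigonous"]}}', m
        )
        assert q2.selections["Achene cross-section shape"] == frozenset({"trigonous"})

    def test_unknown_character_rejected(self):
        m = parse_matrix(FIVE_TAXA)
        with pytest.raises(QueryError):
            query_from_json('{"selections": {"Nope": ["x"]}}', m)
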