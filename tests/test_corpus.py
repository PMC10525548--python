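"""Corpus curation: frequency index, keyword selection, triple assignment,
subclass bounds and the 60/20/20 split."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from medcap.corpus import (CaptionTriple, CategoryMap, CorpusManifest,
                           ManifestRecord, assign_triple,
                           compute_keyword_frequencies, curate,
                           enumerate_triples, select_keywords_of_interest,
                           select_subclasses, split_corpus)
from medcap.errors import ConfigurationError, ValidationError

TEMPLATE = CategoryMap(("ct", "scan", "mri"), ("chest", "bone"), ("tumor", "cyst"))


class TestKeywordFrequencies:
    def test_counts_records_not_occurrences(self):
        idx = compute_keyword_frequencies([{"a", "b"}, {"a"}, {"a", "c"}])
        assert idx.entries == (("a", 3), ("b", 1), ("c", 1))

    def test_empty_input_gives_empty_index(self):
        assert len(compute_keyword_frequencies([])) == 0

    def test_ties_break_lexicographically(self):
        idx = compute_keyword_frequencies([{"zeta", "alpha"}])
        assert idx.keywords() == ["alpha", "zeta"]

    def test_case_normalization_merges_variants(self):
        idx = compute_keyword_frequencies([{"CT"}, {"ct"}])
        assert idx.entries == (("ct", 2),)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.sets(st.sampled_from("abcdefg")), max_size=20))
    def test_matches_brute_force_dictionary_count(self, records):
        idx = compute_keyword_frequencies(records)
        brute = Counter()
        for r in records:
            brute.update(r)
        assert dict(idx.entries) == dict(brute)
        counts = [c for _, c in idx.entries]
        assert counts == sorted(counts, reverse=True)


class TestKeywordSelection:
    def test_threshold_is_strict(self):
        idx = compute_keyword_frequencies([{"ct"}] * 501 + [{"scan"}] * 500)
        got = select_keywords_of_interest(idx, 500, TEMPLATE)
        assert got.exam_type == ("ct",)

    def test_untemplated_keywords_are_discarded(self):
        idx = compute_keyword_frequencies([{"ct", "mystery"}] * 10)
        got = select_keywords_of_interest(idx, 1, TEMPLATE)
        assert got.exam_type == ("ct",) and got.body_part == ()

    def test_empty_index_gives_empty_categories(self):
        got = select_keywords_of_interest(compute_keyword_frequencies([]), 500, TEMPLATE)
        assert got.exam_type == got.body_part == got.problem == ()


class TestTripleEnumeration:
    @pytest.mark.parametrize("ne,nb,np_", [(1, 1, 1), (2, 3, 4), (0, 3, 3), (3, 0, 1)])
    def test_length_is_product_of_category_sizes(self, ne, nb, np_):
        cm = CategoryMap(
            tuple(f"e{i}" for i in range(ne)),
            tuple(f"b{i}" for i in range(nb)),
            tuple(f"p{i}" for i in range(np_)),
        )
        assert len(enumerate_triples(cm)) == ne * nb * np_

    def test_order_is_category_major(self):
        cm = CategoryMap(("x", "y"), ("b",), ("p", "q"))
        assert enumerate_triples(cm) == [
            CaptionTriple("x", "b", "p"), CaptionTriple("x", "b", "q"),
            CaptionTriple("y", "b", "p"), CaptionTriple("y", "b", "q"),
        ]


class TestTripleAssignment:
    def test_unique_member_per_category(self):
        assert assign_triple({"ct", "chest", "tumor", "other"}, TEMPLATE) == \
            CaptionTriple("ct", "chest", "tumor")

    def test_missing_category_excludes_record(self):
        assert assign_triple({"ct", "chest"}, TEMPLATE) is None

    def test_two_exam_keywords_excludes_record(self):
        # strict uniqueness: a record matching both 'ct' and 'scan' is ambiguous
        assert assign_triple({"ct", "scan", "chest", "tumor"}, TEMPLATE) is None


class TestSubclassSelection:
    def test_bounds_are_inclusive(self):
        groups = {"t1": set(range(9)), "t2": set(range(10)),
                  "t3": set(range(80)), "t4": set(range(81))}
        kept = select_subclasses(groups, 10, 80)
        assert set(kept) == {"t2", "t3"}

    def test_empty_map_stays_empty(self):
        assert select_subclasses({}, 10, 80) == {}

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ConfigurationError):
            select_subclasses({}, 80, 10)


def _manifest(n):
    return CorpusManifest([
        ManifestRecord(f"im{i}", f"im{i}.png", ("ct",), frozenset({"ct"}))
        for i in range(n)
    ])


class TestSplit:
    @pytest.mark.parametrize("n,expected", [(1419, (851, 284, 284)), (10, (6, 2, 2)),
                                            (30, (18, 6, 6)), (5, (3, 1, 1))])
    def test_sizes_follow_round_half_up_rule(self, n, expected):
        got = split_corpus(_manifest(n), seed=0)
        sizes = tuple(len(got.subset(s)) for s in ("train", "val", "test"))
        assert sizes == expected

    def test_same_seed_gives_identical_assignment(self):
        a = split_corpus(_manifest(50), seed=3)
        b = split_corpus(_manifest(50), seed=3)
        assert [r.split for r in a.records] == [r.split for r in b.records]

    def test_partition_properties_across_seeds(self):
        m = _manifest(37)
        for seed in range(100):
            got = split_corpus(m, seed=seed)
            splits = [r.split for r in got.records]
            assert all(s in ("train", "val", "test") for s in splits)
            assert Counter(splits) == Counter(train=23, val=7, test=7)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ConfigurationError):
            split_corpus(_manifest(10), fractions=(0.5, 0.2, 0.2))
        with pytest.raises(ValidationError):
            split_corpus(CorpusManifest([]))


class TestRocoReader:
    def test_tab_separated_pair_files(self, tmp_path):
        from medcap.corpus import read_roco_pair

        (tmp_path / "captions.txt").write_text(
            "IMG1\tCT scan of the chest.\nIMG2\tNormal radiograph\nIMG3\tOrphan\n"
        )
        (tmp_path / "keywords.txt").write_text(
            "IMG1\tct chest tumor\nIMG2\tRadiograph bone Fracture\n"
        )
        m = read_roco_pair(tmp_path / "captions.txt", tmp_path / "keywords.txt")
        assert [r.image_id for r in m.records] == ["IMG1", "IMG2"]  # only shared ids
        assert m.records[0].caption == ("ct", "scan", "of", "the", "chest.")
        assert m.records[1].keywords == frozenset({"radiograph", "bone", "fracture"})
        assert m.records[0].image_path.endswith("IMG1.jpg")


class TestCuratePipeline:
    def test_end_to_end_on_toy_corpus(self):
        # 12 clean records of one triple, 3 of another (below min_size), one ambiguous
        records = [
            ManifestRecord(f"a{i}", "", ("c",), frozenset({"ct", "chest", "tumor"}))
            for i in range(12)
        ] + [
            ManifestRecord(f"b{i}", "", ("c",), frozenset({"mri", "bone", "cyst"}))
            for i in range(3)
        ] + [
            ManifestRecord("amb", "", ("c",), frozenset({"ct", "scan", "chest", "tumor"}))
        ]
        out = curate(CorpusManifest(records), TEMPLATE, threshold=0, min_size=10,
                     max_size=80, seed=0)
        assert len(out) == 12
        assert {r.triple for r in out.records} == {CaptionTriple("ct", "chest", "tumor")}
        assert all(r.split in ("train", "val", "test") for r in out.records)
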