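import math
import random

import pytest

from mafstream.filters import (
    column_entropy,
    concatenate,
    extract_features,
    feature_filter,
    merge,
    min_block_length,
    min_block_size,
    remove_full_gap_columns,
    select_chromosome,
    sliding_window_clean,
    subset,
    window_split,
    _window_fails,
)
from mafstream.model import (
    Feature,
    FeatureSet,
    MafBlock,
    MafSequence,
    block_length,
    to_plus_strand_interval,
)
from mafstream.simulate import simulate_k80_block, SimSpec

from conftest import CountingSource, make_block, random_block, simple_block


class TestSubset:
    def setup_method(self):
        self.block = simple_block(["AAAA", "CCCC", "GGGG"], species=["hg", "pt", "mm"])

    def test_keeps_listed_rows(self):
        (out,) = subset([self.block], ["hg", "pt"])
        assert out.species == ["hg", "pt"]

    def test_strict_drops_incomplete(self):
        assert list(subset([self.block], ["hg", "pt", "rn"], strict=True)) == []

    def test_duplicates_drop_block(self):
        dup = simple_block(["AAAA", "TTTT", "CCCC"], species=["hg", "hg", "pt"])
        assert list(subset([dup], ["hg", "pt"], remove_duplicates=True)) == []

    def test_keep_first_duplicate(self):
        dup = simple_block(["AAAA", "TTTT", "CCCC"], species=["hg", "hg", "pt"])
        (out,) = subset(
            [dup], ["hg", "pt"], remove_duplicates=True, keep_first_duplicate=True
        )
        assert out.species == ["hg", "pt"]
        assert out.sequences[0].text == "AAAA"

    def test_keep_others(self):
        (out,) = subset([self.block], ["hg"], keep_others=True)
        assert out.species == ["hg", "pt", "mm"]


class TestMerge:
    def _pair(self, start2, strand2="+", chrom2="chr1"):
        a = make_block([("hg", "chr1", 0, "+", 1000, "ACGTACGTAC")])
        b = make_block([("hg", chrom2, start2, strand2, 1000, "GGGCC")])
        return [a, b]

    def test_contiguous_merge(self):
        (out,) = merge(self._pair(10), ["hg"], max_dist=0)
        (row,) = out.sequences
        assert (row.start, row.size) == (0, 15)
        assert row.text == "ACGTACGTACGGGCC"

    def test_gap_filled_with_n(self):
        (out,) = merge(self._pair(13), ["hg"], max_dist=5)
        (row,) = out.sequences
        assert row.text == "ACGTACGTAC" + "NNN" + "GGGCC"
        assert row.size == 10 + 3 + 5

    def test_gap_exceeds_max_dist(self):
        out = list(merge(self._pair(13), ["hg"], max_dist=2))
        assert len(out) == 2

    def test_strand_mismatch_no_merge(self):
        assert len(list(merge(self._pair(10, strand2="-"), ["hg"]))) == 2

    def test_chromosome_mismatch_no_merge(self):
        assert len(list(merge(self._pair(10, chrom2="chr2"), ["hg"]))) == 2

    def test_greedy_run_collapses(self):
        blocks = [
            make_block([("hg", "chr1", i * 10, "+", 1000, "ACGTACGTAC")])
            for i in range(5)
        ]
        (out,) = merge(blocks, ["hg"], max_dist=0)
        assert out.sequences[0].size == 50

    def test_species_absent_boundary_does_not_merge(self):
        a = make_block([("hg", "chr1", 0, "+", 1000, "ACGT")])
        b = make_block([("pt", "chr1", 4, "+", 1000, "ACGT")])
        assert len(list(merge([a, b], ["hg"]))) == 2

    def test_row_absent_from_one_side_padded(self):
        a = make_block(
            [("hg", "chr1", 0, "+", 1000, "ACGT"), ("pt", "chr2", 0, "+", 500, "ACGT")]
        )
        b = make_block([("hg", "chr1", 4, "+", 1000, "TTTT")])
        (out,) = merge([a, b], ["hg"], max_dist=0)
        by_species = {s.species: s for s in out.sequences}
        assert by_species["hg"].text == "ACGTTTTT"
        assert by_species["pt"].text == "ACGT----"
        assert by_species["pt"].size == 4  # coordinates untouched


class TestConcatenate:
    def test_three_blocks_reach_min_length(self):
        blocks = [simple_block(["A" * 400, "C" * 400]) for _ in range(3)]
        out = list(concatenate(blocks, 1000))
        assert len(out) == 1
        assert block_length(out[0]) == 1200

    def test_long_block_passes_unchanged(self):
        block = simple_block(["A" * 1200])
        (out,) = concatenate([block], 1000)
        assert block_length(out) == 1200

    def test_species_change_flushes(self):
        a = simple_block(["AAAA"], species=["x"])
        b = simple_block(["CCCC"], species=["y"])
        out = list(concatenate([a, b], 1000))
        assert len(out) == 2

    def test_flagged_coordinate_less(self):
        blocks = [simple_block(["AAAA"]), simple_block(["CCCC"])]
        (out,) = concatenate(blocks, 8)
        assert out.annotations.get("coordinates_valid") is False


class TestXFullGap:
    def test_removes_ingroup_all_gap_column(self):
        block = simple_block(["A-C", "A-C", "AAC"], species=["i1", "i2", "out"])
        (out,) = remove_full_gap_columns([block], ["i1", "i2"])
        assert block_length(out) == 2
        assert [s.text for s in out.sequences] == ["AC", "AC", "AC"]

    def test_identity_when_no_full_gap_column(self):
        block = simple_block(["A-C", "AAC"], species=["i1", "i2"])
        (out,) = remove_full_gap_columns([block], ["i1", "i2"])
        assert [s.text for s in out.sequences] == ["A-C", "AAC"]

    def test_postcondition_no_all_gap_ingroup_column(self, rng):
        # exhaustive column-scan oracle
        for _ in range(20):
            block = random_block(rng, n_rows=4, n_cols=30, gap_rate=0.4)
            ingroup = ["sp0", "sp1"]
            out = list(remove_full_gap_columns([block], ingroup))
            for b in out:
                focal = [s for s in b.sequences if s.species in ingroup]
                for column in zip(*(s.text for s in focal)):
                    assert set(column) != {"-"}

    def test_ingroup_coordinates_stay_exact(self, rng):
        block = simple_block(["AA--CC", "A---CC", "AATTCC"], species=["i1", "i2", "o"])
        (out,) = remove_full_gap_columns([block], ["i1", "i2"])
        for s in out.sequences[:2]:
            s.validate()
            assert s.start == 0


def interval_subtraction_oracle(block_interval, features):
    """Independent oracle: subtract feature intervals from the reference
    interval, returning the surviving sub-intervals."""
    lo, hi = block_interval
    cuts = sorted(
        (max(f.start, lo), min(f.end, hi)) for f in features if f.start < hi and f.end > lo
    )
    merged = []
    for s, e in cuts:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    out = []
    pos = lo
    for s, e in merged:
        if s > pos:
            out.append((pos, s))
        pos = max(pos, e)
    if pos < hi:
        out.append((pos, hi))
    return out


class TestFeatureFilter:
    def _block(self):
        return make_block(
            [
                ("hg", "chr1", 0, "+", 1000, "A" * 100),
                ("pt", "chr1", 0, "+", 1000, "C" * 100),
            ]
        )

    def test_split_around_feature(self):
        features = FeatureSet([Feature("hg", "chr1", 20, 40, "+", "exon", "e")])
        out = list(feature_filter([self._block()], features, "hg"))
        intervals = [to_plus_strand_interval(b.sequences[0])[1:] for b in out]
        assert intervals == [(0, 20), (40, 100)]
        assert intervals == interval_subtraction_oracle(
            (0, 100), list(features)
        )

    def test_feature_covering_block_removes_it(self):
        features = FeatureSet([Feature("hg", "chr1", 0, 200, "+", "exon", "e")])
        assert list(feature_filter([self._block()], features, "hg")) == []

    def test_non_overlapping_identity(self):
        features = FeatureSet([Feature("hg", "chr1", 500, 600, "+", "exon", "e")])
        (out,) = feature_filter([self._block()], features, "hg")
        assert block_length(out) == 100

    def test_reference_absent_passes_with_warning(self, caplog):
        features = FeatureSet([Feature("hg", "chr1", 0, 10, "+", "exon", "e")])
        (out,) = feature_filter([self._block()], features, "mm")
        assert block_length(out) == 100

    def test_random_against_oracle(self, rng):
        for _ in range(20):
            n_feat = rng.randint(1, 4)
            feats = []
            for i in range(n_feat):
                s = rng.randrange(0, 95)
                e = s + rng.randint(1, 30)
                feats.append(Feature("hg", "chr1", s, e, "+", "exon", f"f{i}"))
            out = list(feature_filter([self._block()], FeatureSet(feats), "hg"))
            got = [to_plus_strand_interval(b.sequences[0])[1:] for b in out]
            assert got == interval_subtraction_oracle((0, 100), feats)


class TestExtractFeatures:
    def _block(self):
        text = "ACGTACGTACGTACGTACGT"  # 20 cols
        return make_block(
            [
                ("hg", "chr1", 100, "+", 1000, text),
                ("pt", "chr1", 0, "+", 1000, text.lower()),
            ]
        )

    def test_count_law(self):
        feats = [
            Feature("hg", "chr1", 100 + 2 * i, 102 + 2 * i, "+", "exon", f"f{i}")
            for i in range(5)
        ] + [Feature("hg", "chr1", 500, 510, "+", "exon", "far")]
        out = list(extract_features([self._block()], FeatureSet(feats), "hg"))
        assert len(out) == 5
        assert [b.annotations["feature_id"] for b in out] == [f"f{i}" for i in range(5)]

    def test_minus_strand_feature_reverse_complements(self):
        feats = FeatureSet([Feature("hg", "chr1", 100, 104, "-", "exon", "rc")])
        (out,) = extract_features([self._block()], feats, "hg")
        # block columns 0..3 are "ACGT"; reverse complement also "ACGT"
        hg = out.sequences[0]
        assert hg.strand == "-"
        assert hg.text == "ACGT"
        # first emitted column maps to the feature's 3' reference end
        assert to_plus_strand_interval(hg)[1:] == (100, 104)

    def test_complete_only_skips_spanning_feature(self):
        feats = FeatureSet([Feature("hg", "chr1", 110, 150, "+", "exon", "sp")])
        assert (
            list(extract_features([self._block()], feats, "hg", complete_only=True))
            == []
        )

    def test_complement_of_extraction_is_empty(self):
        # feature_filter then extract_features with the same set -> empty
        feats = FeatureSet([Feature("hg", "chr1", 104, 112, "+", "exon", "mid")])
        survivors = list(feature_filter([self._block()], feats, "hg"))
        assert all(
            not list(extract_features([b], feats, "hg", complete_only=True))
            for b in survivors
        )


class TestSimpleFilters:
    def test_select_chromosome(self):
        a = make_block([("hg", "chr1", 0, "+", 100, "ACGT")])
        b = make_block([("hg", "chr2", 0, "+", 100, "ACGT")])
        c = make_block([("pt", "chr1", 0, "+", 100, "ACGT")])
        out = list(select_chromosome([a, b, c], "hg", "chr1"))
        assert out == [a]

    @pytest.mark.parametrize(
        "length,min_len,kept", [(299, 300, False), (300, 300, True), (301, 300, True)]
    )
    def test_min_block_length_inclusive(self, length, min_len, kept):
        block = simple_block(["A" * length])
        assert bool(list(min_block_length([block], min_len))) is kept

    @pytest.mark.parametrize("rows,min_rows,kept", [(2, 3, False), (3, 3, True)])
    def test_min_block_size(self, rows, min_rows, kept):
        block = simple_block(["ACGT"] * rows)
        assert bool(list(min_block_size([block], min_rows))) is kept


class TestWindowSplit:
    def test_left_drops_right_remainder(self):
        block = simple_block(["A" * 3500])
        out = list(window_split([block], 1000, "left"))
        assert [block_length(b) for b in out] == [1000] * 3
        starts = [b.sequences[0].start for b in out]
        assert starts == [0, 1000, 2000]

    def test_exact_partition(self):
        block = simple_block(["AC" * 1000])
        out = list(window_split([block], 1000, "left"))
        assert "".join(b.sequences[0].text for b in out) == block.sequences[0].text

    def test_short_block_yields_nothing(self):
        block = simple_block(["A" * 999])
        assert list(window_split([block], 1000, "left")) == []

    def test_center_offsets_remainder(self):
        block = simple_block(["A" * 250])
        out = list(window_split([block], 100, "center"))
        assert [b.sequences[0].start for b in out] == [25, 125]

    def test_right_drops_left_remainder(self):
        block = simple_block(["A" * 250])
        out = list(window_split([block], 100, "right"))
        assert [b.sequences[0].start for b in out] == [50, 150]

    def test_adjust_balances(self):
        block = simple_block(["A" * 250])
        out = list(window_split([block], 100, "adjust"))
        assert [block_length(b) for b in out] == [84, 83, 83]
        assert sum(block_length(b) for b in out) == 250

    def test_adjust_short_block_passes(self):
        block = simple_block(["A" * 50])
        (out,) = window_split([block], 100, "adjust")
        assert block_length(out) == 50


class TestEntropy:
    def test_uniform_column_zero(self):
        assert column_entropy("AAAA") == 0.0

    def test_all_states_two_bits(self):
        assert column_entropy("ACGT") == pytest.approx(2.0)

    def test_gaps_and_n_excluded(self):
        assert column_entropy(["A", "-", "N", "A"]) == 0.0

    def test_closed_form(self):
        # (A,A,G): H = -(2/3 log2 2/3 + 1/3 log2 1/3)
        expected = -(2 / 3) * math.log2(2 / 3) - (1 / 3) * math.log2(1 / 3)
        assert column_entropy("AAG") == pytest.approx(expected)


def brute_force_failing_windows(block, focal_species, window, step, predicate, params):
    """Independent all-windows scan used to cross-check the filter."""
    focal = [
        s
        for s in block.sequences
        if focal_species is None or s.species in set(focal_species)
    ]
    length = block_length(block)
    fails = []
    lo = 0
    while lo + window <= length:
        if _window_fails(block, focal, lo, lo + window, predicate, params):
            fails.append((lo, lo + window))
        lo += step
    return fails


class TestSlidingWindowClean:
    def test_gap_free_identity(self):
        block = simple_block(["ACGT" * 5, "TGCA" * 5])
        (out,) = sliding_window_clean(
            [block], 4, 1, "gap_count", max_gap=0
        )
        assert [s.text for s in out.sequences] == [s.text for s in block.sequences]

    def test_spec_example_window_excised(self):
        # 10-column window with 3 focal gaps, max_gap=2 -> excised
        block = simple_block(["AC-G-TAC-T" + "ACGTACGTAC", "ACGTACGTAC" * 2])
        out = list(
            sliding_window_clean(
                [block], 10, 10, "gap_count", focal_species=["sp0"], max_gap=2
            )
        )
        for frag in out:
            for lo, hi in brute_force_failing_windows(
                frag, ["sp0"], 10, 10, "gap_count", {"max_gap": 2}
            ):
                pytest.fail(f"window [{lo},{hi}) still fails")
        assert sum(block_length(b) for b in out) == 10

    @pytest.mark.parametrize(
        "predicate,params",
        [
            ("gap_count", {"max_gap": 3}),
            ("gap_events", {"max_events": 2}),
            ("entropy", {"entropy_threshold": 1.0, "max_columns": 3}),
            ("mask_count", {"max_masked": 2}),
        ],
    )
    def test_remove_rescan_soundness(self, rng, predicate, params):
        for rep in range(15):
            block = random_block(rng, n_rows=4, n_cols=60, gap_rate=0.15)
            if predicate == "mask_count":
                # inject lowercase
                for s in block.sequences:
                    s.text = "".join(
                        c.lower() if rng.random() < 0.2 else c for c in s.text
                    )
            for step in (1, 3, 5):
                out = list(
                    sliding_window_clean(
                        [block.copy()], 10, step, predicate, action="remove", **params
                    )
                )
                for frag in out:
                    assert not brute_force_failing_windows(
                        frag, None, 10, step, predicate, params
                    )

    def test_mask_action_overwrites_with_n(self):
        block = simple_block(["A---AAAAAA", "AAAAAAAAAA"])
        (out,) = sliding_window_clean(
            [block], 5, 5, "gap_count", action="mask", max_gap=1
        )
        assert out.sequences[1].text == "NNNNNAAAAA"
        assert out.sequences[0].text == "N---NAAAAA"
        assert out.sequences[0].size == block.sequences[0].size

    def test_quality_predicate_without_scores_passes(self, caplog):
        block = simple_block(["ACGT" * 3, "ACGT" * 3])
        (out,) = sliding_window_clean(
            [block], 4, 2, "quality_mean", min_quality=5
        )
        assert out is block

    def test_quality_predicate_removes_low_quality(self):
        seq1 = MafSequence("a", "c", 0, 12, "+", 100, "ACGTACGTACGT",
                           scores=[9] * 6 + [1] * 6)
        seq2 = MafSequence("b", "c", 0, 12, "+", 100, "ACGTACGTACGT",
                           scores=[9] * 6 + [1] * 6)
        out = list(
            sliding_window_clean(
                [MafBlock([seq1, seq2])], 6, 6, "quality_mean", min_quality=5
            )
        )
        assert len(out) == 1
        assert out[0].sequences[0].text == "ACGTAC"
        assert out[0].sequences[0].scores == [9] * 6

    def test_gap_events_counts_openings(self):
        # one long gap run = 1 event; three runs = 3 events
        one_run = simple_block(["AA----AAAA"])
        three_runs = simple_block(["A-A-A-AAAA"])
        assert list(
            sliding_window_clean([one_run], 10, 10, "gap_events", max_events=2)
        )
        assert not list(
            sliding_window_clean([three_runs], 10, 10, "gap_events", max_events=2)
        )


class TestLaziness:
    def test_filters_consume_bounded_input(self):
        blocks = [simple_block(["ACGT" * 10, "TTTT" * 10]) for _ in range(1000)]
        source = CountingSource(blocks)
        chain = subset(source, ["sp0", "sp1"])
        chain = min_block_length(chain, 10)
        chain = window_split(chain, 10, "left")
        it = iter(chain)
        for _ in range(4):  # 4 windows come from the first block
            next(it)
        assert source.consumed <= 2

    def test_coordinate_invariants_hold_after_filters(self, rng):
        for _ in range(10):
            block = random_block(rng, n_rows=4, n_cols=40, gap_rate=0.2)
            for out in subset([block.copy()], ["sp0", "sp1", "sp2"]):
                out.validate()
            for out in window_split([block.copy()], 10, "center"):
                out.validate()
            for out in sliding_window_clean(
                [block.copy()], 10, 5, "gap_count", max_gap=4
            ):
                out.validate()
            for out in merge([block.copy()], ["sp0"]):
                out.validate()

    def test_column_removing_filters_never_lengthen(self, rng):
        for _ in range(10):
            block = random_block(rng, n_rows=3, n_cols=30, gap_rate=0.3)
            n = block_length(block)
            for out in remove_full_gap_columns([block.copy()], ["sp0", "sp1"]):
                assert block_length(out) <= n
            for out in sliding_window_clean(
                [block.copy()], 5, 5, "gap_count", max_gap=2
            ):
                assert block_length(out) <= n
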