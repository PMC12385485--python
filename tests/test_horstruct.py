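import random

import pytest

from alphahor.horstruct import (
    analyze_array,
    ArrayCandidate,
    cascading_scheme,
    classify_structure,
    derive_canonical,
    explain_period,
    find_hors,
    partition_copies,
    segment_arrays,
)
from alphahor.repeatmap import compute_md

from conftest import CANONICAL_11MER, VARIANT_9MER


class TestSegmentArrays:
    def test_pure_canonical_single_array(self, canonical_plan):
        seq = canonical_plan * 20
        cands = segment_arrays(seq, compute_md(seq))
        assert len(cands) == 1
        assert cands[0].period == 11
        assert (cands[0].start_index, cands[0].end_index) == (0, 220)

    def test_two_copy_52mer(self):
        seq = list(range(1, 53)) * 2
        cands = segment_arrays(seq, compute_md(seq))
        assert [(c.period, c.monomer_count) for c in cands] == [(52, 104)]

    def test_no_repeats_no_arrays(self):
        rng = random.Random(3)
        seq = rng.sample(range(1, 400), 300)  # all types distinct
        assert segment_arrays(seq, compute_md(seq)) == []

    def test_subfragment_periods_not_reported_as_arrays(self, canonical_plan):
        seq = canonical_plan * 20
        cands = segment_arrays(seq, compute_md(seq))
        assert {c.period for c in cands} == {11}  # 4s and 7s are subfragments


class TestDeriveCanonical:
    def test_rotation_recovered_from_mid_copy_start(self, canonical_plan):
        # array sliced mid-copy: recovered canonical is a rotation of the plan
        rotated = (canonical_plan * 21)[3 : 3 + 220]
        cand = ArrayCandidate(period=11, start_index=0, end_index=220)
        canonical, offset, has = derive_canonical(cand, rotated)
        assert has
        doubled = canonical_plan * 2
        assert list(canonical) in [doubled[i : i + 11] for i in range(11)]
        # anchor lands on a copy boundary of the recovered rotation
        assert list(rotated[offset : offset + 11]) == list(canonical)

    def test_majority_canonical_with_variants(self, canonical_plan):
        plan = canonical_plan * 3 + VARIANT_9MER + canonical_plan * 3 + VARIANT_9MER
        seq = [t for t in plan]
        cand = ArrayCandidate(11, 0, len(seq))
        canonical, offset, has = derive_canonical(cand, seq)
        assert has and offset == 0
        assert list(canonical) == canonical_plan

    def test_two_identical_copies_unanimous(self):
        seq = list(range(1, 53)) * 2
        canonical, offset, has = derive_canonical(ArrayCandidate(52, 0, 104), seq)
        assert has and offset == 0
        assert list(canonical) == list(range(1, 53))

    def test_no_repeated_copy_flagged(self):
        seq = [1, 2, 3, 4, 1, 2, 5, 6, 1, 3, 5, 7]
        canonical, _, has = derive_canonical(ArrayCandidate(4, 0, 12), seq)
        assert not has


class TestPartitionCopies:
    def test_c3_v_c3_v_pattern(self, canonical_plan):
        plan = (canonical_plan * 3 + VARIANT_9MER) * 2
        cand = ArrayCandidate(11, 0, len(plan))
        copies, excluded = partition_copies(cand, plan, tuple(canonical_plan), 0)
        assert excluded == []
        assert [c.status for c in copies] == ["canonical"] * 3 + ["variant"] + [
            "canonical"
        ] * 3 + ["variant"]
        labels = {c.variant_label for c in copies if c.status == "variant"}
        assert labels == {"V1"}  # same variant sequence shares one label

    def test_all_canonical(self, canonical_plan):
        plan = canonical_plan * 6
        copies, _ = partition_copies(
            ArrayCandidate(11, 0, 66), plan, tuple(canonical_plan), 0
        )
        assert all(c.status == "canonical" for c in copies)
        assert len(copies) == 6

    def test_copies_tile_array(self, canonical_plan):
        plan = canonical_plan * 2 + VARIANT_9MER + canonical_plan * 2
        copies, _ = partition_copies(
            ArrayCandidate(11, 0, len(plan)), plan, tuple(canonical_plan), 0
        )
        assert copies[0].start_index == 0
        assert copies[-1].end_index == len(plan)
        for a, b in zip(copies, copies[1:]):
            assert a.end_index == b.start_index

    def test_long_mixed_cv_pattern_reproduced(self, canonical_plan):
        pattern = "CCCVCCCVCCVCCCVCCCVCCCVCCCVCVCCVCVCV"
        plan = [
            t
            for ch in pattern
            for t in (canonical_plan if ch == "C" else VARIANT_9MER)
        ]
        arr = analyze_array(ArrayCandidate(11, 0, len(plan)), plan)
        assert arr.cv_pattern == pattern
        assert arr.n_canonical == pattern.count("C")


class TestClassifyStructure:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            (CANONICAL_11MER, "cascading"),  # n=11, tau=10
            (list(range(1, 24)), "willards"),  # 23 distinct types
            ([1], "willards"),
        ],
    )
    def test_classification(self, seq, expected):
        assert classify_structure(seq) == expected

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            classify_structure([])


class TestCascadingScheme:
    def test_11mer_rows(self, canonical_plan):
        scheme = cascading_scheme(canonical_plan)
        assert scheme.rows == (
            tuple((i, i) for i in range(1, 9)),
            ((5, 5), (6, 9), (7, 10)),
        )

    def test_25mer_row2_starts_at_column_11(self):
        seq = list(range(1, 13)) + [11, 12] + list(range(13, 24))
        scheme = cascading_scheme(seq)
        assert len(scheme.rows) == 2
        assert scheme.rows[1][0] == (11, 11)
        assert scheme.rows[1][1] == (12, 12)
        assert scheme.rows[1][-1] == (23, 23)

    def test_willards_single_row(self):
        scheme = cascading_scheme(list(range(1, 24)))
        assert len(scheme.rows) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_flatten_round_trip(self, seed):
        rng = random.Random(seed)
        seq = [rng.randrange(1, 8) for _ in range(50)]
        assert cascading_scheme(seq).flatten() == seq

    def test_render_aligns_columns(self, canonical_plan):
        text = cascading_scheme(canonical_plan).render()
        lines = text.split("\n")
        assert lines[0].startswith("t1")
        assert lines[1].lstrip().startswith("t5")


class TestExplainPeriod:
    def test_period_7_witness(self, canonical_plan):
        ex = explain_period([canonical_plan] * 2, 7)
        assert [e.witness_path for e in ex] == [(5, 9, 10, 1, 2, 3, 4, 5)]

    def test_period_4_witness(self, canonical_plan):
        ex = explain_period([canonical_plan] * 2, 4)
        assert (5, 6, 7, 8, 5) in [e.witness_path for e in ex]

    def test_triplet_period_9_and_20(self, triplet_plan):
        paths9 = [e.witness_path for e in explain_period(triplet_plan, 9)]
        assert (6, 11, 9, 10, 1, 2, 3, 4, 5, 6) in paths9
        paths20 = [e.witness_path for e in explain_period(triplet_plan, 20)]
        assert (
            7, 8, 5, 9, 10, 1, 2, 3, 4, 5, 6, 11, 9, 10, 1, 2, 3, 4, 5, 6, 7,
        ) in paths20

    def test_unexplained_period_empty(self, canonical_plan):
        assert explain_period([canonical_plan] * 3, 6) == []


class TestFindHors:
    def test_structure_fields_consistent(self, canonical_plan):
        plan = canonical_plan * 10 + VARIANT_9MER + canonical_plan * 10
        arrays = find_hors(plan, compute_md(plan))
        assert len(arrays) == 1
        arr = arrays[0]
        assert arr.period == 11
        assert arr.structure_class == "cascading"
        assert arr.distinct_type_count == 10
        assert arr.cv_pattern == "C" * 10 + "V" + "C" * 10
        assert sum(c.n_copy for c in arr.copies) == arr.end_index - arr.start_index
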