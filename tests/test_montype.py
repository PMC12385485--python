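import random

import pytest
from hypothesis import given, settings, strategies as st

from alphahor.monfind import Monomer
from alphahor.montype import assign_types, edit_divergence, type_consensus
from alphahor.seqio import Interval
from alphahor.synth import GeneratorSpec, generate, make_type_library

from conftest import levenshtein_dp, random_dna


def _mon(i, seq):
    return Monomer(i, Interval("r", 200 * i, 200 * i + len(seq)), seq, 0.0)


class TestEditDivergence:
    def test_identity_and_single_substitution(self):
        assert edit_divergence("ACGT", "ACGT") == 0.0
        assert edit_divergence("ACGT", "ACGA") == 25.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            edit_divergence("", "ACGT")

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_dp_oracle_on_random_171mers(self, seed):
        rng = random.Random(seed)
        a, b = random_dna(171, rng), random_dna(171, rng)
        expected = 100.0 * levenshtein_dp(a, b) / 171
        assert edit_divergence(a, b) == pytest.approx(expected)
        assert edit_divergence(b, a) == edit_divergence(a, b)


class TestTypeConsensus:
    def test_single_member(self):
        assert type_consensus(["ACGT"]) == "ACGT"

    def test_majority_forced(self):
        assert type_consensus(["ACGT", "ACGT", "ACTT"], representative="ACGT") == "ACGT"

    def test_recovers_planted_consensus(self):
        rng = random.Random(13)
        planted = random_dna(171, rng)
        members = []
        for _ in range(20):
            seq = list(planted)
            for _ in range(3):  # ~2% independent substitutions per copy
                p = rng.randrange(len(seq))
                seq[p] = rng.choice([b for b in "ACGT" if b != seq[p]])
            members.append("".join(seq))
        assert type_consensus(members, representative=members[0]) == planted


class TestAssignTypes:
    def test_identical_copies_one_type(self):
        seq = random_dna(171, random.Random(1))
        typed, types = assign_types([_mon(i, seq) for i in range(11)])
        assert len(types) == 1
        assert types[0].member_indices == tuple(range(11))
        assert all(tm.type_id == 1 for tm in typed)

    def test_two_planted_clusters(self):
        rng = random.Random(21)
        lib = make_type_library(2, random_dna(171, rng), 10.0, seed=21)
        mons, truth = [], []
        for i in range(30):
            t = i % 2
            seq = list(lib[t])
            for _ in range(2):  # ~1% within-cluster noise
                p = rng.randrange(len(seq))
                seq[p] = rng.choice([b for b in "ACGT" if b != seq[p]])
            mons.append(_mon(i, "".join(seq)))
            truth.append(t + 1)
        typed, types = assign_types(mons)
        assert len(types) == 2
        assert [tm.type_id for tm in typed] == truth  # no member strays

    def test_generator_library_recovered_up_to_relabeling(self):
        spec = GeneratorSpec(seed=17, n_copies=20, per_copy_noise=1.0)
        rec, truth = generate(spec)
        mons = [
            _mon(i, rec.sequence[t.start : t.end])
            for i, t in enumerate(truth.monomers)
        ]
        typed, types = assign_types(mons)
        assert len(types) == 10  # canonical plan uses 10 distinct types
        mapping = {}
        for tm, t in zip(typed, truth.monomers):
            assert mapping.setdefault(t.type_id, tm.type_id) == tm.type_id
        assert len(set(mapping.values())) == len(mapping)

    def test_members_close_to_representative(self):
        spec = GeneratorSpec(seed=23, n_copies=15, per_copy_noise=1.0)
        rec, truth = generate(spec)
        mons = [
            _mon(i, rec.sequence[t.start : t.end])
            for i, t in enumerate(truth.monomers)
        ]
        typed, types = assign_types(mons, type_threshold=5.0)
        rep = {t.type_id: t.representative for t in types}
        for tm in typed:
            assert edit_divergence(tm.monomer.sequence, rep[tm.type_id]) < 10.0

    def test_type_count_non_increasing_in_threshold(self):
        spec = GeneratorSpec(seed=29, n_copies=12, per_copy_noise=1.5)
        rec, truth = generate(spec)
        mons = [
            _mon(i, rec.sequence[t.start : t.end])
            for i, t in enumerate(truth.monomers)
        ]
        counts = [
            len(assign_types(mons, type_threshold=th)[1])
            for th in (2.0, 5.0, 10.0, 26.0)
        ]
        assert counts == sorted(counts, reverse=True)
        assert counts[-1] == 1  # beyond the inter-type divergence: one blob
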