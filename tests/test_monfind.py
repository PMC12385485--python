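import random

import pytest

from alphahor.monfind import detect_monomers, group_blocks
from alphahor.montype import edit_divergence
from alphahor.seqio import SequenceRecord
from alphahor.synth import GeneratorSpec, generate

from conftest import levenshtein_dp, random_dna


def _consensus(seed=3, length=171):
    return random_dna(length, random.Random(seed))


def test_exact_tiling():
    cons = _consensus()
    rec = SequenceRecord("r", cons * 10)
    mons = detect_monomers(rec, SequenceRecord("c", cons))
    assert len(mons) == 10
    assert [m.interval.start for m in mons] == [171 * i for i in range(10)]
    assert all(m.divergence_to_consensus == 0.0 for m in mons)
    assert [m.index for m in mons] == list(range(10))


def test_planted_recovery_with_noise():
    spec = GeneratorSpec(seed=5, n_copies=50, per_copy_noise=2.0)
    rec, truth = generate(spec)
    mons = detect_monomers(rec, SequenceRecord("c", truth.base_consensus))
    assert len(mons) == len(truth.monomers)  # recall and precision both 1.0
    for m, t in zip(mons, truth.monomers):
        assert abs(m.interval.start - t.start) <= 5


def test_random_dna_negative_control():
    rng = random.Random(11)
    rec = SequenceRecord("r", random_dna(10_000, rng))
    cons = SequenceRecord("c", random_dna(171, rng))
    # independent check that no window of the record sits within threshold
    best = min(
        levenshtein_dp(cons.sequence, rec.sequence[i : i + 171])
        for i in range(0, 10_000 - 171, 500)
    )
    assert 100 * best / 171 > 30
    assert detect_monomers(rec, cons, max_divergence=30.0) == []


def test_short_record_and_bad_consensus():
    cons = _consensus()
    assert detect_monomers(SequenceRecord("r", "ACGT"), SequenceRecord("c", cons)) == []
    with pytest.raises(ValueError):
        detect_monomers(SequenceRecord("r", cons * 2), SequenceRecord("c", ""))


def test_n_runs_terminate_arrays():
    cons = _consensus()
    rec = SequenceRecord("r", cons * 3 + "N" * 10 + cons * 2)
    mons = detect_monomers(rec, SequenceRecord("c", cons))
    assert len(mons) == 5
    blocks = group_blocks(mons, gap_max=5)
    assert [b.monomer_count for b in blocks] == [3, 2]


def test_reverse_strand_scan():
    from alphahor.seqio import reverse_complement

    cons = _consensus()
    rec = SequenceRecord("r", reverse_complement(cons * 5))
    fwd_only = detect_monomers(rec, SequenceRecord("c", cons))
    both = detect_monomers(rec, SequenceRecord("c", cons), scan_both_strands=True)
    assert fwd_only == []
    assert len(both) == 5
    assert all(m.interval.strand == "-" for m in both)
    # reported sequences are in array orientation
    assert all(edit_divergence(m.sequence, cons) == 0.0 for m in both)


def test_detection_idempotent_on_block():
    spec = GeneratorSpec(seed=9, n_copies=10, per_copy_noise=1.0, flank_length=300)
    rec, truth = generate(spec)
    cons = SequenceRecord("c", truth.base_consensus)
    mons = detect_monomers(rec, cons)
    blocks = group_blocks(mons)
    assert len(blocks) == 1
    sub = SequenceRecord("sub", rec.sequence[blocks[0].interval.start : blocks[0].interval.end])
    again = detect_monomers(sub, cons)
    assert len(again) == blocks[0].monomer_count
    offs = blocks[0].interval.start
    assert [(m.interval.start - offs, m.interval.end - offs) for m in mons] == [
        (m.interval.start, m.interval.end) for m in again
    ]


def test_monomers_non_overlapping_sorted():
    spec = GeneratorSpec(seed=2, n_copies=20, per_copy_noise=2.0)
    rec, truth = generate(spec)
    mons = detect_monomers(rec, SequenceRecord("c", truth.base_consensus))
    for a, b in zip(mons, mons[1:]):
        assert a.interval.end <= b.interval.start


def test_group_blocks_two_arrays_and_empty():
    cons = _consensus()
    spacer = random_dna(1000, random.Random(4))
    rec = SequenceRecord("r", cons * 10 + spacer + cons * 10)
    mons = detect_monomers(rec, SequenceRecord("c", cons))
    blocks = group_blocks(mons)
    assert [b.monomer_count for b in blocks] == [10, 10]
    assert group_blocks([]) == []
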