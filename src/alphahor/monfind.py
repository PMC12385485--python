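"""Detection of tandemly organized satellite monomers by consensus alignment.

Alpha-satellite monomers are ~171 bp units repeated head-to-tail over hundreds
of kilobases.  Given a consensus monomer, this module tiles a genomic sequence
with monomer calls using a greedy seed-and-walk strategy:

1. find the best local (infix) alignment of the consensus in an uncovered
   region — the *seed*;
2. from the seed, walk right and left, fitting the consensus to the window
   that starts (resp. ends) exactly at the current boundary, accepting each
   fit while its edit-distance divergence stays below ``max_divergence`` and
   its length stays inside ``length_band``;
3. repeat on the remaining uncovered regions until no seed qualifies.

Walking guarantees head-to-tail tiling (monomer boundaries are propagated, so
indels in one unit do not shift the register of its neighbours), which is what
distinguishes tandem monomers from scattered consensus hits.

Runs of N terminate arrays: the sequence is split at N runs before scanning,
so no monomer ever spans an assembly gap.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib

from .seqio import Interval, SequenceRecord, reverse_complement

DEFAULT_MAX_DIVERGENCE = 30.0  # percent; intra-copy monomer divergence runs to ~31.6%
DEFAULT_LENGTH_BAND = (150, 200)  # bp band around the ~171 bp unit
DEFAULT_GAP_MAX = 5  # bp; larger gaps split arrays into separate blocks


@dataclass(frozen=True)
class Monomer:
    """One detected repeat unit.

    ``index`` is the 0-based enumeration in order of appearance across the
    whole scanned input; it is the coordinate system of the MD/GRM analyses.
    """

    index: int
    interval: Interval
    sequence: str
    divergence_to_consensus: float


@dataclass(frozen=True)
class ArrayBlock:
    """A maximal run of monomers with inter-monomer gaps <= gap_max."""

    start_index: int  # first monomer enumeration index (inclusive)
    end_index: int  # past-the-last enumeration index
    interval: Interval

    @property
    def monomer_count(self) -> int:
        return self.end_index - self.start_index


def _divergence(distance: int, len_a: int, len_b: int) -> float:
    return 100.0 * distance / max(len_a, len_b)


def _fit_at(seq: str, pos: int, limit: int, consensus: str,
            max_divergence: float, length_band: tuple[int, int]):
    """Best consensus fit starting exactly at ``pos`` (prefix-mode alignment)."""
    lmin, lmax = length_band
    window = seq[pos : min(pos + lmax, limit)]
    if len(window) < lmin:
        return None
    k = int(max_divergence / 100.0 * max(len(consensus), len(window))) + 1
    res = edlib.align(consensus, window, mode="SHW", task="locations", k=k)
    if res["editDistance"] < 0:
        return None
    length = res["locations"][0][1] + 1
    div = _divergence(res["editDistance"], len(consensus), length)
    if length < lmin or length > lmax or div > max_divergence:
        return None
    return pos, pos + length, div


def _fit_before(seq: str, pos: int, limit: int, consensus: str,
                max_divergence: float, length_band: tuple[int, int]):
    """Best consensus fit ending exactly at ``pos`` (reversed prefix fit)."""
    lmin, lmax = length_band
    lo = max(pos - lmax, limit)
    window = seq[lo:pos][::-1]
    if len(window) < lmin:
        return None
    rcons = consensus[::-1]
    k = int(max_divergence / 100.0 * max(len(rcons), len(window))) + 1
    res = edlib.align(rcons, window, mode="SHW", task="locations", k=k)
    if res["editDistance"] < 0:
        return None
    length = res["locations"][0][1] + 1
    div = _divergence(res["editDistance"], len(consensus), length)
    if length < lmin or length > lmax or div > max_divergence:
        return None
    return pos - length, pos, div


def _scan_segment(seq: str, offset: int, consensus: str, max_divergence: float,
                  length_band: tuple[int, int]) -> list[tuple[int, int, float]]:
    """Seed-and-walk over one N-free segment; returns (start, end, div) calls."""
    lmin, lmax = length_band
    k_seed = int(max_divergence / 100.0 * len(consensus)) + 1
    calls: list[tuple[int, int, float]] = []
    regions = [(0, len(seq))]
    while regions:
        a, b = regions.pop()
        if b - a < lmin:
            continue
        res = edlib.align(consensus, seq[a:b], mode="HW", task="locations", k=k_seed)
        if res["editDistance"] < 0:
            continue
        s, e = res["locations"][0]
        seed_start = a + s
        # Re-fit forward from the seed start so the seed obeys the same
        # length-band/divergence contract as every walked monomer.
        first = _fit_at(seq, seed_start, b, consensus, max_divergence, length_band)
        if first is None:
            # Seed anchor unusable (e.g. band violation at region edge):
            # discard a minimal window around it and keep scanning.
            regions.append((a, seed_start))
            regions.append((seed_start + 1, b))
            continue
        mons = [first]
        pos = first[1]
        while True:
            fit = _fit_at(seq, pos, b, consensus, max_divergence, length_band)
            if fit is None:
                break
            mons.append(fit)
            pos = fit[1]
        pos = first[0]
        while True:
            fit = _fit_before(seq, pos, a, consensus, max_divergence, length_band)
            if fit is None:
                break
            mons.append(fit)
            pos = fit[0]
        calls.extend(mons)
        lo = min(m[0] for m in mons)
        hi = max(m[1] for m in mons)
        regions.append((a, lo))
        regions.append((hi, b))
    calls.sort(key=lambda c: c[0])
    return [(offset + s, offset + e, d) for s, e, d in calls]


def _resolve_overlaps(calls: list[tuple[int, int, float]]) -> list[tuple[int, int, float]]:
    """Keep a maximal non-overlapping subset; lower divergence wins, then lower start."""
    kept: list[tuple[int, int, float]] = []
    for call in sorted(calls, key=lambda c: (c[2], c[0])):
        if all(call[1] <= k[0] or call[0] >= k[1] for k in kept):
            kept.append(call)
    kept.sort(key=lambda c: c[0])
    return kept


def detect_monomers(
    record: SequenceRecord,
    consensus: SequenceRecord,
    max_divergence: float = DEFAULT_MAX_DIVERGENCE,
    length_band: tuple[int, int] = DEFAULT_LENGTH_BAND,
    gap_max: int = DEFAULT_GAP_MAX,
    scan_both_strands: bool = False,
) -> list[Monomer]:
    """Detect tandem monomers in ``record`` against a consensus monomer.

    Returns monomers sorted by start with enumeration indices assigned after
    all calls are made.  A record shorter than the consensus yields an empty
    list.  Divergence is percent edit distance normalized by the longer of
    the two sequences (the convention used throughout the package).
    """
    if not consensus.sequence:
        raise ValueError("consensus must be non-empty")
    if not (0 < max_divergence < 100):
        raise ValueError("max_divergence must be in (0, 100)")
    lmin, lmax = length_band
    if not (lmin <= consensus.length <= lmax):
        raise ValueError(
            f"consensus length {consensus.length} outside length band {length_band}"
        )
    seq = record.sequence
    calls: list[tuple[int, int, float, str]] = []
    for m in re.finditer(r"[ACGT]+", seq):
        segment_calls = _scan_segment(
            m.group(0), m.start(), consensus.sequence, max_divergence, length_band
        )
        calls.extend((s, e, d, "+") for s, e, d in segment_calls)
        if scan_both_strands:
            rc = reverse_complement(m.group(0))
            rc_calls = _scan_segment(rc, 0, consensus.sequence, max_divergence, length_band)
            L = len(m.group(0))
            calls.extend(
                (m.start() + L - e, m.start() + L - s, d, "-") for s, e, d in rc_calls
            )
    if scan_both_strands:
        calls = _resolve_strands(calls, gap_max)
    strand_of = {(s, e): strand for s, e, _, strand in calls}
    resolved = _resolve_overlaps([(s, e, d) for s, e, d, _ in calls])
    monomers = []
    for i, (s, e, d) in enumerate(resolved):
        strand = strand_of.get((s, e), "+")
        mseq = seq[s:e] if strand == "+" else reverse_complement(seq[s:e])
        monomers.append(
            Monomer(
                index=i,
                interval=Interval(record.id, s, e, strand),
                sequence=mseq,
                divergence_to_consensus=round(d, 2),
            )
        )
    return monomers


def _resolve_strands(calls, gap_max):
    """Blocks of calls take the strand with the better mean divergence."""
    fwd = [c for c in calls if c[3] == "+"]
    rev = [c for c in calls if c[3] == "-"]

    def blockify(cs):
        cs = sorted(cs, key=lambda c: c[0])
        blocks, cur = [], []
        for c in cs:
            if cur and c[0] - cur[-1][1] > gap_max:
                blocks.append(cur)
                cur = []
            cur.append(c)
        if cur:
            blocks.append(cur)
        return blocks

    out = []
    rev_blocks = blockify(rev)
    for fb in blockify(fwd):
        f_lo, f_hi = fb[0][0], fb[-1][1]
        f_mean = sum(c[2] for c in fb) / len(fb)
        shadowed = False
        for rb in rev_blocks:
            r_lo, r_hi = rb[0][0], rb[-1][1]
            if r_lo < f_hi and f_lo < r_hi:
                r_mean = sum(c[2] for c in rb) / len(rb)
                if r_mean < f_mean:
                    shadowed = True
                break
        if not shadowed:
            out.extend(fb)
    for rb in rev_blocks:
        r_lo, r_hi = rb[0][0], rb[-1][1]
        r_mean = sum(c[2] for c in rb) / len(rb)
        shadowed = False
        for fb in blockify(fwd):
            f_lo, f_hi = fb[0][0], fb[-1][1]
            if r_lo < f_hi and f_lo < r_hi:
                f_mean = sum(c[2] for c in fb) / len(fb)
                if f_mean <= r_mean:
                    shadowed = True
                break
        if not shadowed:
            out.extend(rb)
    return sorted(out, key=lambda c: c[0])


def group_blocks(monomers: list[Monomer], gap_max: int = DEFAULT_GAP_MAX) -> list[ArrayBlock]:
    """Partition monomers into tandem blocks split where the gap exceeds gap_max.

    Monomers on different input sequences never share a block.
    """
    blocks: list[ArrayBlock] = []
    if not monomers:
        return blocks
    start = 0
    for i in range(1, len(monomers) + 1):
        boundary = i == len(monomers)
        if not boundary:
            prev, cur = monomers[i - 1], monomers[i]
            boundary = (
                cur.interval.seq_id != prev.interval.seq_id
                or cur.interval.start - prev.interval.end > gap_max
            )
        if boundary:
            first, last = monomers[start], monomers[i - 1]
            blocks.append(
                ArrayBlock(
                    start_index=first.index,
                    end_index=last.index + 1,
                    interval=Interval(
                        first.interval.seq_id, first.interval.start, last.interval.end
                    ),
                )
            )
            start = i
    return blocks
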