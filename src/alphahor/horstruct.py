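"""HOR array segmentation and structure analysis.

Starting from typed monomers and their MD points, this module

* segments candidate HOR arrays (the densest, largest-period MD-line segment
  within a region is the array's period; smaller-period segments inside it
  are subfragments);
* derives the *canonical* copy — the most common n-length monomer-type
  sequence over all rotations of the array;
* partitions the array into copies cut at the canonical anchor type and
  classifies each copy canonical/variant (variant labels V1, V2, ... are
  assigned per distinct variant sequence in order of first appearance),
  producing the C/V pattern string;
* classifies the canonical as Willard's type (all monomer types distinct,
  tau = n) or Cascading (some type recurs, tau < n) and renders the
  multi-row aligned cascading scheme;
* explains subfragment periods by exhibiting witness paths — same-type
  start-to-start distances inside and across copies.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

from .repeatmap import MDPoint, md_line_segments, _type_ids

DEFAULT_MIN_COPIES = 2  # the longest known array in this analysis has exactly 2 copies
DEFAULT_SUPPORT_FRACTION = 0.3  # a cascading 11mer has only 9/11 monomers at the top period


@dataclass(frozen=True)
class ArrayCandidate:
    """A candidate HOR array: a period plus a half-open enumeration range."""

    period: int
    start_index: int
    end_index: int

    @property
    def monomer_count(self) -> int:
        return self.end_index - self.start_index


@dataclass(frozen=True)
class HORCopy:
    copy_index: int
    start_index: int  # enumeration, inclusive
    end_index: int  # enumeration, exclusive
    type_sequence: tuple[int, ...]
    status: str  # "canonical" | "variant"
    variant_label: str | None = None

    @property
    def n_copy(self) -> int:
        return len(self.type_sequence)


@dataclass(frozen=True)
class HORArray:
    period: int
    canonical_sequence: tuple[int, ...]
    copies: tuple[HORCopy, ...]
    start_index: int
    end_index: int
    structure_class: str  # "willards" | "cascading"
    cv_pattern: str
    has_canonical: bool = True  # False: diverged array, modal copy is plurality only
    excluded: tuple[tuple[int, int], ...] = ()  # anchor-free stretches > 3n

    @property
    def distinct_type_count(self) -> int:
        return len(set(self.canonical_sequence))

    @property
    def n_canonical(self) -> int:
        return sum(1 for c in self.copies if c.status == "canonical")


@dataclass(frozen=True)
class CascadingScheme:
    """Rows of (column, type_id); repeated types align in the same column."""

    rows: tuple[tuple[tuple[int, int], ...], ...]

    def flatten(self) -> list[int]:
        return [t for row in self.rows for _, t in row]

    def render(self) -> str:
        width = max((col for row in self.rows for col, _ in row), default=0)
        cell = max(
            (len(f"t{t}") for row in self.rows for _, t in row), default=2
        ) + 1
        lines = []
        for row in self.rows:
            by_col = {col: t for col, t in row}
            lines.append(
                "".join(
                    (f"t{by_col[c]}" if c in by_col else "").ljust(cell)
                    for c in range(1, width + 1)
                ).rstrip()
            )
        return "\n".join(lines)


@dataclass(frozen=True)
class SubfragmentExplanation:
    period: int
    witness_path: tuple[int, ...]  # type ids from one occurrence to the next
    multiplicity_per_copy: Fraction
    n_pairs: int


def segment_arrays(
    typed: Sequence,
    md: Sequence[MDPoint],
    min_copies: int = DEFAULT_MIN_COPIES,
    support_fraction: float = DEFAULT_SUPPORT_FRACTION,
    blocks: Sequence[tuple[int, int]] | None = None,
) -> list[ArrayCandidate]:
    """Find candidate HOR arrays from dense MD-line segments.

    Periods are visited from largest to smallest; each dense run of
    same-period MD points spans the enumeration interval from its first
    point to one period past its last point (the landing monomer of the
    final distance).  A run must span at least ``min_copies`` periods and
    carry at least ``support_fraction`` MD points per monomer of span; runs
    lying mostly inside an already-claimed (larger-period) array are its
    subfragments and are skipped.
    """
    if min_copies < 2:
        raise ValueError("min_copies must be >= 2")
    ids = _type_ids(typed)
    n = len(ids)
    if blocks is None:
        blocks = [(0, n)] if n else []
    block_end = {}
    for s, e in blocks:
        for i in range(s, e):
            block_end[i] = e
    claimed = [False] * n
    out: list[ArrayCandidate] = []
    for period in sorted({p.period for p in md}, reverse=True):
        # A variant copy interrupts the array-period MD points for up to
        # two copies, so runs tolerate gaps of two periods.
        for seg in md_line_segments(md, period, min_run=2, max_gap=2 * period):
            start = seg.start_index
            end = min(seg.end_index + period + 1, block_end.get(start, n))
            span = end - start
            if span < min_copies * period:
                continue
            # MD points at the array period can only originate from the
            # first (span - period) monomers of the span.
            if seg.n_points < support_fraction * max(span - period, 1):
                continue
            overlap = sum(claimed[start:end])
            if overlap > 0.5 * span:
                continue
            for i in range(start, end):
                claimed[i] = True
            out.append(ArrayCandidate(period=period, start_index=start, end_index=end))
    out.sort(key=lambda a: a.start_index)
    return out


def derive_canonical(
    candidate: ArrayCandidate, typed: Sequence
) -> tuple[tuple[int, ...], int, bool]:
    """Most common p-length type window in the array, anchored at a copy start.

    Returns (canonical_sequence, anchor_offset, has_canonical).  Every
    p-length window at every start position is counted — a fixed-stride
    frame would lose the register after a deletion or insertion variant, so
    the count must be frame-free.  The modal window is the canonical copy;
    ties prefer the lexicographically smallest sequence, which anchors the
    rotation at the earliest-appearing type (type labels are assigned in
    order of first genomic appearance, so a tandem array's copy-boundary
    rotation starts with its smallest label).  ``anchor_offset`` is the
    offset of the first occurrence of the canonical's leading type.  If no
    window repeats (modal count < 2) the array is diverged — it has no
    canonical copy in the strict sense — and the plurality window is
    returned with ``has_canonical`` False.
    """
    ids = _type_ids(typed)
    ts = ids[candidate.start_index : candidate.end_index]
    p = candidate.period
    if len(ts) < p:
        raise ValueError("array too short for its period")
    counts = Counter(tuple(ts[i : i + p]) for i in range(len(ts) - p + 1))
    top = max(counts.values())
    canonical = min(w for w, c in counts.items() if c == top)
    offset = ts.index(canonical[0])
    return canonical, offset, top >= 2


def partition_copies(
    candidate: ArrayCandidate,
    typed: Sequence,
    canonical: tuple[int, ...],
    anchor_offset: int = 0,
) -> tuple[list[HORCopy], list[tuple[int, int]]]:
    """Cut the array into copies at the canonical anchor type.

    The anchor is the canonical sequence's first type.  Monomers before the
    first anchor form a leading variant copy.  Where the anchor is silent for
    more than 3n monomers the stretch is excluded from the copy statistics
    and reported.  Segments equal to the canonical are canonical; all others
    are variants, labelled V1, V2, ... per distinct sequence in order of
    first appearance.
    """
    ids = _type_ids(typed)
    s, e = candidate.start_index, candidate.end_index
    n = len(canonical)
    anchor = canonical[0]
    ts = ids[s:e]

    # Copy boundaries: positions of the anchor type.  If the canonical
    # itself repeats its anchor, an exact canonical match consumes n
    # monomers in one step so interior anchors do not over-cut.
    boundaries: list[int] = []
    pos = anchor_offset
    segments: list[tuple[int, int]] = []  # local half-open
    excluded: list[tuple[int, int]] = []
    if pos > 0:
        segments.append((0, pos))
    while pos < len(ts):
        if tuple(ts[pos : pos + n]) == canonical:
            segments.append((pos, pos + n))
            pos += n
            continue
        nxt = None
        for j in range(pos + 1, len(ts)):
            if ts[j] == anchor:
                nxt = j
                break
        if nxt is None:
            segments.append((pos, len(ts)))
            break
        if nxt - pos > 3 * n:
            excluded.append((s + pos, s + nxt))
        elif nxt - pos > 2 * n:
            # long insertion: peel off n-length chunks as extra copies
            while nxt - pos > 2 * n:
                segments.append((pos, pos + n))
                pos += n
            segments.append((pos, nxt))
        else:
            segments.append((pos, nxt))
        pos = nxt

    copies: list[HORCopy] = []
    labels: dict[tuple[int, ...], str] = {}
    for i, (a, b) in enumerate(segments):
        seq = tuple(ts[a:b])
        if seq == canonical:
            status, label = "canonical", None
        else:
            status = "variant"
            if seq not in labels:
                labels[seq] = f"V{len(labels) + 1}"
            label = labels[seq]
        copies.append(
            HORCopy(
                copy_index=i,
                start_index=s + a,
                end_index=s + b,
                type_sequence=seq,
                status=status,
                variant_label=label,
            )
        )
    return copies, excluded


def classify_structure(canonical_sequence: Sequence[int]) -> str:
    """Willard's type iff every monomer type in the canonical copy is distinct."""
    if not canonical_sequence:
        raise ValueError("canonical sequence must be non-empty")
    seq = list(canonical_sequence)
    return "willards" if len(set(seq)) == len(seq) else "cascading"


def cascading_scheme(type_sequence: Sequence[int]) -> CascadingScheme:
    """Aligned multi-row scheme: a repeated type starts a new row in its column.

    Scanning left to right, a monomer whose type already occurs in the
    current row opens a new row, placed in the column of that earlier
    occurrence; following monomers fill subsequent columns.  Columns are
    1-based.  A Willard's-type sequence yields a single row.
    """
    rows: list[list[tuple[int, int]]] = []
    current: list[tuple[int, int]] = []
    seen: dict[int, int] = {}  # type -> column within current row
    col = 0
    for t in type_sequence:
        if t in seen:
            rows.append(current)
            col = seen[t]
            current = [(col, t)]
            seen = {t: col}
        else:
            col += 1
            current.append((col, t))
            seen[t] = col
    if current:
        rows.append(current)
    return CascadingScheme(rows=tuple(tuple(r) for r in rows))


def explain_period(
    copy_plan: Sequence[Sequence[int]], period: int
) -> list[SubfragmentExplanation]:
    """Witness paths for a subfragment period in a concatenated copy plan.

    All same-type start-to-start distances (to the *next* occurrence, as in
    the MD diagram) across the concatenation are enumerated; those equal to
    ``period`` are grouped by their witness path — the inclusive type
    subsequence from one occurrence to the next.  The multiplicity of each
    path is its pair count divided by the number of copies.  An empty result
    means the period is not explained by the plan (a genuinely independent
    repeat).
    """
    concat: list[int] = [t for copy in copy_plan for t in copy]
    n_copies = len(copy_plan)
    paths: Counter = Counter()
    order: list[tuple[int, ...]] = []
    nxt: dict[int, int] = {}
    for i in range(len(concat) - 1, -1, -1):
        t = concat[i]
        if t in nxt and nxt[t] - i == period:
            path = tuple(concat[i : nxt[t] + 1])
            if path not in paths:
                order.append(path)
            paths[path] += 1
        nxt[t] = i
    order.reverse()
    return [
        SubfragmentExplanation(
            period=period,
            witness_path=path,
            multiplicity_per_copy=Fraction(paths[path], n_copies),
            n_pairs=paths[path],
        )
        for path in order
    ]


def analyze_array(candidate: ArrayCandidate, typed: Sequence) -> HORArray:
    """Full structure analysis of one candidate array."""
    canonical, offset, has_canonical = derive_canonical(candidate, typed)
    copies, excluded = partition_copies(candidate, typed, canonical, offset)
    return HORArray(
        period=candidate.period,
        canonical_sequence=canonical,
        copies=tuple(copies),
        start_index=candidate.start_index,
        end_index=candidate.end_index,
        structure_class=classify_structure(canonical),
        cv_pattern="".join("C" if c.status == "canonical" else "V" for c in copies),
        has_canonical=has_canonical,
        excluded=tuple(excluded),
    )


def find_hors(
    typed: Sequence,
    md: Sequence[MDPoint],
    min_copies: int = DEFAULT_MIN_COPIES,
    support_fraction: float = DEFAULT_SUPPORT_FRACTION,
    blocks: Sequence[tuple[int, int]] | None = None,
) -> list[HORArray]:
    """Segment and analyze all HOR arrays in a typed monomer sequence."""
    return [
        analyze_array(c, typed)
        for c in segment_arrays(typed, md, min_copies, support_fraction, blocks)
    ]
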