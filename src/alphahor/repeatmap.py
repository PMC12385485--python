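"""Monomer-distance (MD) points, the GRM period histogram, and MD-line segments.

The MD diagram plots, for every monomer, the distance (in monomer units) to
the *next* monomer of the same type; a tandem nmer HOR shows up as a dense
horizontal segment at period n, and intra/inter-copy same-type shortcuts show
up as parallel segments at smaller periods (subfragments).  The GRM diagram
is the histogram of those periods: HORs are its peaks.

Periods are measured as monomer enumeration differences, not in bp: peak
magnitudes then equal MD-point counts, which is the bookkeeping the whole
structure analysis rests on (conservation: total MD points = number of
monomers minus the number of distinct types present, per block).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from .montype import TypedMonomer


@dataclass(frozen=True)
class MDPoint:
    monomer_index: int
    period: int  # monomer units, >= 1


@dataclass(frozen=True)
class GRMHistogram:
    counts: dict[int, int]

    @property
    def total_points(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class MDSegment:
    """A dense horizontal run of MD points at one period."""

    period: int
    start_index: int  # enumeration index of the first MD point (inclusive)
    end_index: int  # enumeration index of the last MD point (inclusive)
    n_points: int


def _type_ids(typed: Sequence) -> list[int]:
    """Accept either TypedMonomer lists or plain type-id sequences."""
    if not typed:
        return []
    if isinstance(typed[0], TypedMonomer):
        return [tm.type_id for tm in typed]
    return [int(t) for t in typed]


def compute_md(
    typed: Sequence,
    blocks: Sequence[tuple[int, int]] | None = None,
) -> list[MDPoint]:
    """Distance from each monomer to the next monomer of the same type.

    ``typed`` is a list of TypedMonomers in enumeration order (plain type-id
    sequences are accepted for structure-level analyses).  When ``blocks``
    (half-open enumeration ranges) are given, distances never cross a block
    boundary, so spacers between arrays cannot produce spurious periods; by
    default the whole input is one block.  A type's last occurrence in its
    block emits no point.
    """
    ids = _type_ids(typed)
    if blocks is None:
        blocks = [(0, len(ids))] if ids else []
    points: list[MDPoint] = []
    for s, e in blocks:
        nxt: dict[int, int] = {}
        for i in range(e - 1, s - 1, -1):
            t = ids[i]
            if t in nxt:
                points.append(MDPoint(monomer_index=i, period=nxt[t] - i))
            nxt[t] = i
    points.sort(key=lambda p: p.monomer_index)
    return points


def grm_histogram(md: Sequence[MDPoint]) -> GRMHistogram:
    """Histogram of MD periods (the GRM diagram)."""
    return GRMHistogram(counts=dict(Counter(p.period for p in md)))


def rank_peaks(hist: GRMHistogram, min_count: int = 1) -> list[tuple[int, int]]:
    """Periods with count >= min_count, by descending count then ascending period."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    peaks = [(p, c) for p, c in hist.counts.items() if c >= min_count]
    peaks.sort(key=lambda pc: (-pc[1], pc[0]))
    return peaks


def md_line_segments(
    md: Sequence[MDPoint],
    period: int,
    min_run: int = 2,
    max_gap: int | None = None,
) -> list[MDSegment]:
    """Maximal dense runs of MD points at exactly ``period``.

    Consecutive points must be at most ``max_gap`` monomers apart (default:
    one period — inside a tandem array same-period points recur at least once
    per copy) and a run must contain at least ``min_run`` points.
    """
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    gap = max_gap if max_gap is not None else period
    idx = sorted(p.monomer_index for p in md if p.period == period)
    segments: list[MDSegment] = []
    run: list[int] = []
    for i in idx + [None]:
        if i is not None and (not run or i - run[-1] <= gap):
            run.append(i)
            continue
        if len(run) >= min_run:
            segments.append(
                MDSegment(period=period, start_index=run[0], end_index=run[-1],
                          n_points=len(run))
            )
        run = [i] if i is not None else []
    return segments


def plot_grm(hist: GRMHistogram, path, max_period: int | None = None) -> None:
    """Bar plot of the GRM histogram (optional; needs matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    periods = sorted(hist.counts)
    if max_period:
        periods = [p for p in periods if p <= max_period]
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(periods, [hist.counts[p] for p in periods], width=0.8)
    ax.set_xlabel("period (monomer units)")
    ax.set_ylabel("MD-point frequency")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_md(md: Sequence[MDPoint], path) -> None:
    """Scatter plot of the MD diagram (optional; needs matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    ax.scatter([p.monomer_index for p in md], [p.period for p in md], s=4)
    ax.set_xlabel("monomer enumeration")
    ax.set_ylabel("period (monomer units)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
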