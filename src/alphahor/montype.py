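"""Monomer-type classification by edit-distance clustering.

Monomers with mutual edit divergence below 5% belong to the same *monomer
type*; distinct types within a repeat unit typically diverge by 20–40%.
Types are found by greedy representative-based clustering in order of
genomic appearance: each monomer joins the nearest existing type if its
divergence to that type's representative is below the threshold, otherwise
it opens a new type.  After the streaming pass, representatives are rebuilt
as per-column majority consensus sequences and a single refinement pass
re-assigns every monomer against the frozen representatives.  Type labels
(t1, t2, ...) are dense and ordered by first genomic appearance.

Greedy representative clustering is used instead of single-linkage on the
full pairwise matrix because single linkage chains clusters across the
threshold in noisy data, and the streaming formulation matches the
order-of-appearance enumeration the downstream period analyses rely on.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import edlib

from .monfind import Monomer

DEFAULT_TYPE_THRESHOLD = 5.0  # percent mutual divergence defining a type


@dataclass(frozen=True)
class MonomerType:
    """A cluster of monomers sharing <threshold divergence to a representative."""

    type_id: int  # dense, 1-based, ordered by first genomic appearance
    representative: str
    member_indices: tuple[int, ...]  # monomer enumeration indices


@dataclass(frozen=True)
class TypedMonomer:
    monomer: Monomer
    type_id: int


def edit_divergence(a: str, b: str) -> float:
    """Percent edit distance, normalized by the longer sequence.

    100 * levenshtein(a, b) / max(|a|, |b|); symmetric; 0 iff a == b.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if a == b:
        return 0.0
    dist = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 100.0 * dist / max(len(a), len(b))


def type_consensus(members: list[str], representative: str | None = None) -> str:
    """Per-column majority consensus of members star-aligned to a representative.

    Each member is globally aligned to the representative; member insertions
    are ignored, deletions vote as gaps.  Per representative column the
    majority base wins (ties go to the representative's base); columns where
    the gap outvotes the best base are dropped.
    """
    if not members:
        raise ValueError("need at least one member")
    rep = representative if representative is not None else members[0]
    if len(members) == 1 and members[0] == rep:
        return rep
    counts: list[Counter] = [Counter() for _ in rep]
    for m in members:
        if m == rep:
            for col, base in enumerate(rep):
                counts[col][base] += 1
            continue
        res = edlib.align(m, rep, mode="NW", task="path")
        nice = edlib.getNiceAlignment(res, m, rep)
        col = 0
        for qc, tc in zip(nice["query_aligned"], nice["target_aligned"]):
            if tc == "-":
                continue  # insertion relative to the representative
            counts[col][qc] += 1
            col += 1
    out = []
    for col, rep_base in enumerate(rep):
        gap = counts[col].get("-", 0)
        bases = {b: c for b, c in counts[col].items() if b != "-"}
        if not bases:
            continue
        top = max(bases.values())
        winners = sorted(b for b, c in bases.items() if c == top)
        if gap > top:
            continue
        out.append(rep_base if rep_base in winners else winners[0])
    return "".join(out)


def assign_types(
    monomers: list[Monomer],
    type_threshold: float = DEFAULT_TYPE_THRESHOLD,
    rescue_factor: float = 2.0,
) -> tuple[list[TypedMonomer], list[MonomerType]]:
    """Cluster monomers into types; returns (typed monomers, type table).

    Monomers must be supplied in enumeration order.  A type is a *recurring*
    monomer class: the streaming pass discovers clusters at the strict
    threshold, but a singleton cluster whose consensus lies within
    ``rescue_factor * type_threshold`` of an established multi-member type is
    a noisy instance of that type — its monomer simply drew an unlucky
    mutation load — and is re-absorbed rather than kept as a type of its
    own.  (Distinct satellite monomer types diverge by ~15% and more, so the
    rescue band is far below any genuine type boundary.)  Singletons beyond
    the band are genuinely novel and survive.  Every member of a
    multi-member type diverges from its representative by less than the
    threshold up to this rescue rule; rescued members sit within the band.
    """
    reps: list[str] = []
    members: list[list[int]] = []  # positions into `monomers`
    assignment: list[int] = []
    for pos, mon in enumerate(monomers):
        best_t, best_d = -1, None
        for t, rep in enumerate(reps):
            d = edit_divergence(mon.sequence, rep)
            if best_d is None or d < best_d:
                best_t, best_d = t, d
        if best_d is not None and best_d < type_threshold:
            assignment.append(best_t)
            members[best_t].append(pos)
        else:
            assignment.append(len(reps))
            members.append([pos])
            reps.append(mon.sequence)

    # Rebuild representatives as majority consensus.  A noisy first member
    # can seed two near-duplicate clusters for one underlying type, so
    # clusters whose consensus representatives fall within the threshold of
    # each other — the same-type relation itself — are merged before the
    # refinement pass.
    frozen = [
        type_consensus([monomers[p].sequence for p in mem], representative=rep)
        for rep, mem in zip(reps, members)
    ]
    parent = list(range(len(frozen)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(frozen)):
        for j in range(i + 1, len(frozen)):
            if find(i) != find(j) and edit_divergence(frozen[i], frozen[j]) < type_threshold:
                parent[find(j)] = find(i)
    groups: dict[int, list[int]] = {}
    for t in range(len(frozen)):
        groups.setdefault(find(t), []).append(t)
    merged_reps: list[str] = []
    merged_sizes: list[int] = []
    for root in sorted(groups):
        pool = sorted(p for t in groups[root] for p in members[t])
        merged_sizes.append(len(pool))
        merged_reps.append(
            type_consensus(
                [monomers[p].sequence for p in pool], representative=frozen[root]
            )
        )

    # Singleton clusters within the rescue band of a multi-member cluster
    # are noisy instances, not types; drop them before refinement.
    rescue_band = rescue_factor * type_threshold
    multi_reps = [r for r, s in zip(merged_reps, merged_sizes) if s > 1]
    survivors = [
        rep
        for rep, size in zip(merged_reps, merged_sizes)
        if size > 1
        or not multi_reps
        or min(edit_divergence(rep, m) for m in multi_reps) >= rescue_band
    ]

    # One refinement pass against the frozen surviving representatives.
    new_members: list[list[int]] = [[] for _ in survivors]
    new_reps = list(survivors)
    for pos, mon in enumerate(monomers):
        best_t, best_d = -1, None
        for t, rep in enumerate(new_reps):
            d = edit_divergence(mon.sequence, rep)
            if best_d is None or d < best_d:
                best_t, best_d = t, d
        if best_d is not None and best_d < rescue_band:
            new_members[best_t].append(pos)
        else:
            new_members.append([pos])
            new_reps.append(mon.sequence)

    # Dense 1-based labels in order of first genomic appearance.
    order = sorted(
        (t for t in range(len(new_reps)) if new_members[t]),
        key=lambda t: new_members[t][0],
    )
    label = {t: i + 1 for i, t in enumerate(order)}
    pos_type = {}
    types = []
    for t in order:
        for p in new_members[t]:
            pos_type[p] = label[t]
        types.append(
            MonomerType(
                type_id=label[t],
                representative=new_reps[t],
                member_indices=tuple(monomers[p].index for p in new_members[t]),
            )
        )
    typed = [TypedMonomer(mon, pos_type[p]) for p, mon in enumerate(monomers)]
    return typed, types
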