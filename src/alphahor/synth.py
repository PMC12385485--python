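"""Synthetic satellite-array generator with exact planted truth.

The generator emulates the layered structure of a centromeric satellite
array: a library of monomer *types* (sequences derived from one base
consensus at a controlled inter-type divergence), tandem HOR copies that
each spell out a monomer-type sequence, independent per-copy noise on every
monomer, variant copies (deletions / insertions / novel types) interleaved
with canonical ones, and non-satellite flanking sequence.  Alongside the
FASTA it emits a truth table — per-monomer coordinates, planted type, copy
index and copy status — so every pipeline stage can be scored exactly.

Defaults mirror the regime of a real alpha-satellite array: 171 bp
monomers, ~20% inter-type divergence (types inside one repeat unit diverge
by roughly 17–32%), ~1% per-copy noise (canonical copies of one array
diverge by well under 5%), and the Cascading 11mer canonical plan
(t1..t8, t5, t9, t10) with its most frequent deletion variant as the
default variant.

Noise model: per-base substitution with probability q, insertion and
deletion each with probability q/10 — satellite divergence is
substitution-dominated.  The type library itself is built with
substitutions only, which keeps the monomer register of the planted truth
exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .montype import edit_divergence
from .seqio import SequenceRecord

BASES = np.array(list("ACGT"))

CANONICAL_11MER = (1, 2, 3, 4, 5, 6, 7, 8, 5, 9, 10)
# Most frequent variant of the 11mer array: first-row tail deleted, with a
# novel type (11) in place of the 7,8 pair.
VARIANT_9MER = (1, 2, 3, 4, 5, 6, 11, 9, 10)


@dataclass(frozen=True)
class GeneratorSpec:
    monomer_length: int = 171
    n_types: int = 11
    inter_type_divergence: float = 20.0  # percent, pairwise target
    canonical_plan: tuple[int, ...] = CANONICAL_11MER
    copy_plan: tuple[tuple[int, ...], ...] | None = None  # explicit copies, or:
    cv_pattern: str | None = None  # e.g. "CCCVC"; V uses variant_plan
    variant_plan: tuple[int, ...] = VARIANT_9MER
    n_copies: int = 30  # used when neither copy_plan nor cv_pattern is given
    per_copy_noise: float = 1.0  # percent substitution rate per monomer
    flank_length: int = 500  # bp of random non-satellite sequence each side
    seed: int = 0
    base_consensus: str | None = None  # random if not supplied

    def resolve_copy_plan(self) -> tuple[tuple[tuple[int, ...], ...], str]:
        """Expand the spec into (copy type sequences, C/V pattern)."""
        if self.copy_plan is not None:
            pattern = "".join(
                "C" if tuple(c) == tuple(self.canonical_plan) else "V"
                for c in self.copy_plan
            )
            return tuple(tuple(c) for c in self.copy_plan), pattern
        if self.cv_pattern is not None:
            plan = tuple(
                tuple(self.canonical_plan) if ch == "C" else tuple(self.variant_plan)
                for ch in self.cv_pattern
            )
            return plan, self.cv_pattern
        return (tuple(self.canonical_plan),) * self.n_copies, "C" * self.n_copies


@dataclass(frozen=True)
class TruthMonomer:
    start: int
    end: int
    type_id: int
    copy_index: int
    copy_status: str  # "C" | "V"


@dataclass(frozen=True)
class SyntheticTruth:
    monomers: tuple[TruthMonomer, ...]
    canonical_sequence: tuple[int, ...]
    cv_pattern: str
    library: tuple[str, ...]  # library[i] is the sequence of type i+1
    base_consensus: str

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": range(len(self.monomers)),
                "start": [m.start for m in self.monomers],
                "end": [m.end for m in self.monomers],
                "type_id": [m.type_id for m in self.monomers],
                "copy_index": [m.copy_index for m in self.monomers],
                "copy_status": [m.copy_status for m in self.monomers],
            }
        )


def random_dna(length: int, rng: np.random.Generator) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def _substitute(seq: str, k: int, rng: np.random.Generator) -> str:
    """Apply exactly k substitutions at distinct positions."""
    if k == 0:
        return seq
    arr = np.array(list(seq))
    pos = rng.choice(len(arr), size=min(k, len(arr)), replace=False)
    for p in pos:
        choices = [b for b in "ACGT" if b != arr[p]]
        arr[p] = choices[rng.integers(0, 3)]
    return "".join(arr)


def mutate(seq: str, sub_rate: float, indel_rate: float,
           rng: np.random.Generator) -> str:
    """Per-base substitution at sub_rate; insertion/deletion each at indel_rate."""
    out = []
    for c in seq:
        r = rng.random()
        if r < indel_rate:
            continue  # deletion
        if r < 2 * indel_rate:
            out.append(BASES[rng.integers(0, 4)])  # insertion before the base
        if rng.random() < sub_rate:
            choices = [b for b in "ACGT" if b != c]
            out.append(choices[rng.integers(0, 3)])
        else:
            out.append(c)
    return "".join(out)


def make_type_library(
    n_types: int,
    base_consensus: str,
    inter_type_divergence: float,
    seed: int,
    tolerance: float = 5.0,
    max_tries: int = 60,
) -> list[str]:
    """Derive n type sequences from a base consensus at a target divergence.

    Each type receives independent random substitutions; the library is
    rejection-resampled (with an adaptive per-type rate) until every pairwise
    divergence lies within ``tolerance`` percentage points of the target.
    """
    if not (0 < inter_type_divergence < 75) and n_types > 1:
        raise ValueError("inter-type divergence target must be in (0, 75)")
    if n_types == 1:
        return [base_consensus]
    rng = np.random.default_rng(seed)
    L = len(base_consensus)
    # Two sequences mutated independently at rate m sit ~2m apart, minus
    # coincidences; start at half the target and adapt.
    rate = inter_type_divergence / 200.0
    for _ in range(max_tries):
        k = max(1, round(rate * L))
        library = [_substitute(base_consensus, k, rng) for _ in range(n_types)]
        divs = [
            edit_divergence(library[i], library[j])
            for i in range(n_types)
            for j in range(i + 1, n_types)
        ]
        if all(abs(d - inter_type_divergence) <= tolerance for d in divs):
            return library
        mean = sum(divs) / len(divs)
        rate *= inter_type_divergence / max(mean, 1e-9)
    raise RuntimeError(
        f"could not reach {inter_type_divergence}% +/- {tolerance} pairwise "
        f"divergence for {n_types} types in {max_tries} attempts"
    )


def generate(spec: GeneratorSpec) -> tuple[SequenceRecord, SyntheticTruth]:
    """Emit a synthetic satellite array FASTA record plus its exact truth.

    Deterministic: identical spec (including seed) gives byte-identical
    output.  Warns when per-copy noise is large enough relative to the
    inter-type divergence that type recovery is not guaranteed.
    """
    if spec.per_copy_noise >= spec.inter_type_divergence / 3:
        warnings.warn(
            "per-copy noise >= inter-type divergence / 3: "
            "type recovery is not guaranteed",
            stacklevel=2,
        )
    rng = np.random.default_rng(spec.seed)
    base = spec.base_consensus or random_dna(spec.monomer_length, rng)
    copy_plan, cv_pattern = spec.resolve_copy_plan()
    max_type = max((t for copy in copy_plan for t in copy), default=1)
    if max_type > spec.n_types:
        raise ValueError(
            f"copy plan uses type {max_type} but n_types is {spec.n_types}"
        )
    library = make_type_library(
        spec.n_types,
        base,
        spec.inter_type_divergence,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    q = spec.per_copy_noise / 100.0
    parts: list[str] = []
    truth_rows: list[TruthMonomer] = []
    pos = 0
    if spec.flank_length:
        flank = random_dna(spec.flank_length, rng)
        parts.append(flank)
        pos += len(flank)
    for copy_idx, copy in enumerate(copy_plan):
        status = cv_pattern[copy_idx]
        for t in copy:
            mon = mutate(library[t - 1], q, q / 10.0, rng)
            parts.append(mon)
            truth_rows.append(
                TruthMonomer(
                    start=pos,
                    end=pos + len(mon),
                    type_id=t,
                    copy_index=copy_idx,
                    copy_status=status,
                )
            )
            pos += len(mon)
    if spec.flank_length:
        parts.append(random_dna(spec.flank_length, rng))
    record = SequenceRecord(id=f"synthetic_seed{spec.seed}", sequence="".join(parts))
    truth = SyntheticTruth(
        monomers=tuple(truth_rows),
        canonical_sequence=tuple(spec.canonical_plan),
        cv_pattern=cv_pattern,
        library=tuple(library),
        base_consensus=base,
    )
    return record, truth
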