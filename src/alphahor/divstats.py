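"""Edit-distance divergence summaries for monomers and HOR copies.

Three comparisons characterize a HOR array:

* intra-HOR: all unordered pairs among the monomers of the canonical copy
  (self-alignments excluded) — internal heterogeneity of the repeat unit;
* inter-HOR: the full Cartesian set between the monomers of two arrays (no
  exclusions) — distinctness of two HOR families;
* copy-to-copy: all unordered pairs of whole canonical copy sequences —
  fidelity of the tandem duplication.

All percentages are edit distance normalized by the longer sequence, the
same convention as monomer typing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, product
from typing import Sequence

from .montype import edit_divergence


@dataclass(frozen=True)
class DivergenceSummary:
    mean: float
    min: float
    max: float
    n_pairs: int

    def as_dict(self, ndigits: int = 2) -> dict:
        return {
            "mean": round(self.mean, ndigits),
            "min": round(self.min, ndigits),
            "max": round(self.max, ndigits),
            "n_pairs": self.n_pairs,
        }


def _summarize(values: list[float]) -> DivergenceSummary:
    return DivergenceSummary(
        mean=math.fsum(values) / len(values),
        min=min(values),
        max=max(values),
        n_pairs=len(values),
    )


def intra_hor_divergence(monomers: Sequence[str]) -> DivergenceSummary:
    """All unordered monomer pairs within one HOR unit, self-pairs excluded."""
    if len(monomers) < 2:
        raise ValueError("need at least two monomers")
    return _summarize(
        [edit_divergence(a, b) for a, b in combinations(monomers, 2)]
    )


def inter_hor_divergence(
    monomers_a: Sequence[str], monomers_b: Sequence[str]
) -> DivergenceSummary:
    """Full Cartesian comparison between two monomer sets, no exclusions."""
    if not monomers_a or not monomers_b:
        raise ValueError("both monomer sets must be non-empty")
    return _summarize(
        [edit_divergence(a, b) for a, b in product(monomers_a, monomers_b)]
    )


def copy_divergence(copies: Sequence[str]) -> DivergenceSummary:
    """All unordered pairs of whole HOR copy sequences."""
    if len(copies) < 2:
        raise ValueError("need at least two copies")
    return _summarize([edit_divergence(a, b) for a, b in combinations(copies, 2)])
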