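# Methods

## The model

An alpha-satellite array is modelled as a sequence of ~171 bp monomers in
tandem.  Two monomers belong to the same *monomer type* when their edit
divergence — percent Levenshtein distance normalized by the longer
sequence — is below a threshold (default 5%).  An *n*mer HOR is a block of
n monomers repeated in tandem; written as type sequences, the most common
n-window is the *canonical* copy, all other copies are *variants*.  A
canonical copy with all types distinct (τ = n) is Willard's type; one with
repeated types (τ < n) is Cascading.  The package's central quantity is the
MD point: for monomer i of type T, the enumeration distance to the next
monomer of type T.  Tandem HORs give dense MD runs at period n; same-type
shortcuts within and across copies give sparser runs at smaller periods
(subfragments).  Periods are measured in monomer units, not bp, so GRM peak
magnitudes equal MD-point counts and obey an exact conservation law: per
tandem block, #MD points = #monomers − #distinct types present.  This
invariant is asserted by property tests.

## Monomer detection

No published boundary rule exists for consensus-based monomer calling, so
the detector is a greedy seed-and-walk: the best infix alignment of the
consensus in an uncovered region seeds a walk that repeatedly fits the
consensus to the window starting (or, leftwards, ending) exactly at the
current boundary via prefix-mode alignment, accepting while divergence ≤
`max_divergence` (default 30% — intra-unit monomer divergence reaches ~32%,
so the bound is permissive but excludes random DNA, whose best local match
to an unrelated 171-mer sits near 44%) and length stays in `length_band`
(default 150–200 bp).  Propagating boundaries keeps the tandem register:
an indel in one monomer cannot shift its neighbours.  Overlapping candidates
are resolved by lower divergence, then lower start.  Runs of N split the
input before scanning (no call spans an assembly gap), and gaps > `gap_max`
(default 5 bp) split monomers into separate tandem blocks.  With
`scan_both_strands`, the reverse complement is scanned too and overlapping
opposite-strand blocks keep the orientation with the better mean divergence;
monomer sequences are reported in array orientation.

## Monomer typing

Greedy representative clustering in order of genomic appearance: a monomer
joins the nearest existing type if below the threshold, else opens a new
type.  Representatives are then rebuilt as per-column majority consensus
(star alignment of members to the representative; member insertions ignored,
gap-majority columns dropped, ties to the representative's base), followed
by two corrections and one frozen re-assignment pass:

* clusters whose consensus representatives are mutually below the threshold
  are merged — a noisy first member otherwise seeds two clusters for one
  underlying type;
* a *singleton* cluster whose representative lies within 2× threshold of a
  multi-member type is dropped and its monomer re-absorbed.  A type is a
  recurring class; under realistic noise (~1%/copy) the Poisson tail
  reliably produces one monomer in a few hundred that exceeds 5% to its own
  type consensus, while genuinely distinct types sit at ≥15%.  The 2×
  band separates those regimes with a wide margin.  Singletons beyond the
  band survive as genuinely novel types.

Labels t1, t2, … are dense and ordered by first genomic appearance, so the
first monomer of an array always carries the smallest label.  Downstream
results depend only on the type partition, never on label values (tested by
permutation).  Single-linkage clustering was rejected: it chains across the
threshold in noisy data.

## Array segmentation and canonical derivation

MD points are computed per tandem block (spacers cannot fabricate periods).
Dense runs of same-period points (inter-point gap ≤ 2 periods — one
deletion variant silences the array period for up to two copies — and
support ≥ 0.3 points per MD-capable monomer; a cascading 11mer yields only
9/11) become array candidates spanning first point to one period past the
last; larger periods claim first, so subfragment runs inside an array are
never reported as arrays.  `min_copies` defaults to 2: a two-copy array is
a real HOR (the longest known units have exactly two copies).

The canonical copy is the modal n-window counted over *all* start
positions.  A fixed-stride frame was tried first and abandoned: one
deletion variant shifts the register of every later copy, mis-anchoring the
modal window.  Frame-free counting is insensitive to that; ties prefer the
lexicographically smallest window, which anchors the rotation at the
earliest-appearing type, i.e. at a copy boundary.  Copies are cut at
occurrences of the canonical's leading type (an exact canonical match
consumes n monomers in one step, so canonicals that repeat their leading
type do not over-cut); segments equal to the canonical are canonical,
others are variants labelled V1, V2, … per distinct sequence in order of
first appearance.  Anchor-free stretches longer than 3n are excluded and
reported; inter-anchor segments beyond 2n are peeled into extra n-length
copies.  If no n-window repeats, the array is flagged as diverged ("no
canonical copy") and reported with its plurality window only.

## Divergence statistics

All three summaries (intra-unit pairs excluding self, inter-family full
Cartesian set, copy-to-copy pairs) use the same normalization as typing and
are exactly reproducible by a brute-force DP oracle (tested).  Means use
compensated summation so summaries are independent of argument order.  The
pipeline's intra-unit comparison uses the *distinct* consensus monomer
types of the canonical copy: a Cascading unit repeats a type, and including
the repeat would pin the minimum at zero rather than measure heterogeneity.

## Synthetic generator

The generator emulates: a type library derived from one base consensus by
independent substitutions, rejection-resampled (adaptive rate) until all
pairwise divergences are within ±5 points of the target (default 20% —
the observed inter-type regime); tandem copies spelling a canonical plan
(default the Cascading 11mer t1..t8,t5,t9,t10) with variant copies (default
its 9-monomer deletion variant carrying a novel type) placed by a C/V
pattern; per-monomer noise (substitution q, insertion q/10, deletion q/10
per base; default q = 1% — canonical copies then diverge pairwise by ~2%,
comfortably under the 5% type rule); and random flanks (default 500 bp).
The library uses substitutions only so the planted register is exact; copy
noise does include indels.  Emitted truth (coordinates, types, copy index,
status) is exact by construction.  Identical spec + seed gives
byte-identical output.

What the generator does **not** emulate: biological consensus sequences
(the base is random unless supplied), strand switches, nested/super-HOR
organisation, unequal crossover or gene-conversion homogenization
gradients, assembly artefacts, and long-range divergence trends along real
arrays.  Passing recovery tests therefore demonstrates correctness of the
machinery under the stated noise model, not performance on every real
centromere.

## Problem sizes and numerical choices

Recovery tests use arrays of 20–30 copies (220–330 monomers, ~60 kb) with
20 fixed-seed replicates for the end-to-end recovery check; closed-form
period checks enumerate N = 2..50 copies.  All tie-breaks are
deterministic (divergence then coordinate for overlapping monomer calls;
lexicographic for modal windows; representative's base for consensus
columns).  Degenerate inputs are defined: empty monomer lists yield empty
results, a record shorter than the consensus yields no calls, a type's
last occurrence emits no MD point, and `min_copies ≥ 2` everywhere.

## Known limitations

* Arrays more diverged than the detection threshold are invisible; arrays
  with no repeated copy are flagged but excluded from canonical/variant
  statistics.
* The 5% rule is applied monomer-to-representative (with the corrections
  above), one reading of an ambiguous convention; type counts near the
  threshold are sensitive to it.
* Monomer boundaries under indels are fixed by best prefix fit, which can
  offset starts by a few bp; coordinates are accurate to ±5 bp, not exact.
* Sequence-level (bp-resolution) period spectra and spectral methods are
  out of scope, as are ideogram rendering and cross-assembly comparison.
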