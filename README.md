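# alphahor

Higher-order repeat (HOR) discovery in tandem satellite DNA.

Centromeric alpha satellite DNA is built from ~171 bp monomers repeated
head-to-tail.  Monomers within one repeat unit diverge from each other by
20–40%, but the unit itself — a block of *n* monomers, an *n*mer HOR — is
repeated in tandem with less than 5% divergence between copies.  Monomers
under 5% mutual edit divergence form a *monomer type*; writing an array as
its sequence of types makes the higher-order structure visible.  `alphahor`
finds that structure:

* **monomer detection** — tile a genomic sequence with monomer calls by
  seed-and-walk alignment against a user-supplied consensus (edlib edit
  distance, head-to-tail register propagation);
* **monomer typing** — cluster monomers into types at <5% mutual divergence,
  with per-type majority-consensus representatives;
* **MD / GRM analysis** — for each monomer, the distance (in monomer units)
  to the next monomer of the same type is an *MD point*; the histogram of
  these periods is the *GRM diagram*.  A tandem nmer HOR is a dense
  horizontal MD-line segment at period n and the corresponding GRM peak;
  smaller-period segments inside an array are *subfragments* (intra/inter-copy
  same-type shortcuts);
* **HOR structure** — segment arrays, derive the *canonical* copy (the most
  common n-length type window), classify copies canonical/variant (C/V
  pattern), classify the unit as Willard's type (all types distinct, τ = n)
  or Cascading (repeated types, τ < n), render aligned cascading schemes,
  and exhibit witness paths explaining each subfragment period;
* **divergence statistics** — intra-unit, inter-family, and copy-to-copy
  edit-distance summaries;
* **synthetic generator** — arrays with planted monomer coordinates, types,
  copy boundaries and variant labels, so the whole pipeline is testable
  without downloading an assembly.

For whom: anyone annotating centromeric/satellite repeat structure in
assemblies (or studying repeat evolution) who wants monomer-resolution HOR
calls rather than a periodicity spectrum alone.

## Worked example

The canonical Cascading 11mer HOR copy has the monomer-type sequence
t1 t2 t3 t4 t5 t6 t7 t8 t5 t9 t10 — eleven monomers, ten distinct types
(t5 recurs).  On a tandem array of 20 copies:

```python
>>> from alphahor import compute_md, grm_histogram, rank_peaks
>>> plan = [1, 2, 3, 4, 5, 6, 7, 8, 5, 9, 10]
>>> hist = grm_histogram(compute_md(plan * 20))
>>> dict(sorted(hist.counts.items()))
{4: 20, 7: 19, 11: 171}
>>> rank_peaks(hist)
[(11, 171), (4, 20), (7, 19)]
```

The top peak at period 11 is the HOR itself (9 of the 11 monomers in each
copy sit exactly one copy away from their next same-type partner: 9 × 19 =
171 points).  The minor peaks are subfragments, not separate repeat
families: period 4 is the intra-copy shortcut t5→t6→t7→t8→t5 (once per
copy), period 7 the inter-copy shortcut t5→t9→t10→t1→t2→t3→t4→t5 (once per
copy junction).  `explain_period` produces exactly these witness paths.

Running the full pipeline on a synthetic array (30 copies, three deletion
variants, 20% inter-type divergence, 1% per-copy noise — `examples/`):

```
detected 324 monomers (planted: 324)
monomer types: 11
array 0: 11mer cascading, 30 copies (27 canonical),
         pattern CCCCCCCCVCCCCCCCCCVCCCCCCCCCVC
```

which is the planted structure exactly.  See `examples/01`–`05` for short
narrative scripts covering each capability, and the `alphahor` CLI
(`monomers`, `types`, `grm`, `hors`, `divergence`, `synth`, `run-all`) for
shell use; `alphahor run-all --fasta in.fa --consensus cons.fa --out out/`
writes monomer/HOR BED and TSV tables, the GRM histogram, aligned schemes
and a divergence report.

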