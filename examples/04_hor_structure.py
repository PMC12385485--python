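"""Segment a HOR array, classify copies, and explain subfragment periods.

Runs the structure stage on a type sequence containing canonical and
variant copies, prints the canonical copy, the C/V pattern, the aligned
cascading scheme, and witness paths for the subfragment periods.
"""

from alphahor import cascading_scheme, compute_md, explain_period, find_hors

CANONICAL = [1, 2, 3, 4, 5, 6, 7, 8, 5, 9, 10]
VARIANT = [1, 2, 3, 4, 5, 6, 11, 9, 10]  # deletion variant with novel t11

plan = [CANONICAL] * 3 + [VARIANT] + [CANONICAL] * 3 + [VARIANT]
seq = [t for copy in plan for t in copy]

(array,) = find_hors(seq, compute_md(seq))
print(f"period n={array.period}, tau={array.distinct_type_count} "
      f"-> {array.structure_class}")
print(f"canonical copy: {array.canonical_sequence}")
print(f"C/V pattern   : {array.cv_pattern}  "
      f"({array.n_canonical}/{len(array.copies)} canonical)")

print("\naligned cascading scheme (repeated t5 shares column 5):")
print(cascading_scheme(array.canonical_sequence).render())

print("\nsubfragment witness paths across the triplet:")
for period in (4, 7, 9, 20):
    for e in explain_period([CANONICAL, VARIANT, CANONICAL], period):
        path = "->".join(f"t{t}" for t in e.witness_path)
        print(f"  period {period:2d}: {path}  ({e.n_pairs} pair(s))")
        break  # one witness per period is enough here
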