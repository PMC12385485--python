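"""Generate a synthetic alpha-satellite array with planted truth.

Builds a 30-copy Cascading 11mer HOR array (canonical plan t1..t8,t5,t9,t10)
with three deletion-variant copies, 20% inter-type divergence and 1%
per-copy noise, flanked by random non-satellite DNA.
"""

from alphahor import GeneratorSpec, generate

pattern = "C" * 8 + "V" + "C" * 9 + "V" + "C" * 9 + "V" + "C"
record, truth = generate(GeneratorSpec(seed=11, cv_pattern=pattern))

print(f"sequence length : {record.length} bp")
print(f"monomers planted: {len(truth.monomers)}")
print(f"copies          : {len(truth.cv_pattern)}  (pattern {truth.cv_pattern})")
print(f"canonical plan  : {truth.canonical_sequence}")
print(f"first monomer   : {truth.monomers[0].start}-{truth.monomers[0].end} "
      f"type t{truth.monomers[0].type_id}")
# The truth table is exact: every monomer's coordinates, type, copy index and
# canonical/variant status are known, so downstream stages can be scored.
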