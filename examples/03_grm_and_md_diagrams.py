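"""MD points and the GRM period histogram of a canonical 11mer array.

Every monomer contributes the distance (in monomer units) to the next
monomer of the same type; the histogram of these periods is the GRM
diagram, whose top peak is the HOR period and whose minor peaks are
subfragments.
"""

from alphahor import compute_md, grm_histogram, md_line_segments, rank_peaks

CANONICAL_11MER = [1, 2, 3, 4, 5, 6, 7, 8, 5, 9, 10]
N = 20

md = compute_md(CANONICAL_11MER * N)
hist = grm_histogram(md)
print(f"MD points: {hist.total_points}  "
      f"(= {11 * N} monomers - 10 types)")
print("GRM histogram:", dict(sorted(hist.counts.items())))
# {4: 20, 7: 19, 11: 171}: period 11 is the HOR (9 points per copy pair);
# 4 is the intra-copy t5->t5 shortcut, 7 the inter-copy t5->t5 shortcut.
print("ranked peaks :", rank_peaks(hist))

segs = md_line_segments(md, period=11)
print(f"period-11 MD-line segments: {len(segs)} "
      f"(monomers {segs[0].start_index}..{segs[0].end_index}, "
      f"{segs[0].n_points} points)")
# One dense horizontal segment spanning the whole array = one HOR array.
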