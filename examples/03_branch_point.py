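"""Branch-point search restricted to the AG exclusion zone.

The functional branch-point adenine lies in the AG-free stretch upstream of
the 3' splice site.  Candidates (every adenine with full heptamer context)
are scored with a PWM whose sixth position is the branch adenine; the best
candidate yields two derived features: distance to the 3' ss and the
pyrimidine content of the tract between them.
"""

from pexsplice import best_branch_point, build_pwm, compute_agez

# intron tail: an upstream AG bounds the exclusion zone; a TACTAAC-register
# heptamer sits inside a pyrimidine tract
tail = "CCTG" + "AG" + "TT" + "TACTAAC" + "T" * 24 + "AG"
print("intron tail:", tail)
print("AG exclusion zone:", compute_agez(tail))

pwm = build_pwm(["TACTAAC", "TACTAAT", "CACTAAC"], pseudocount=0.5)
res = best_branch_point(tail, pwm, dmin=15, dmax=60)
print(f"best branch point at offset {res.bp_offset} (distance {res.distance} nt)")
print(f"score {res.score:.2f} bits; pyrimidine content {res.ppt_fraction:.2f}")
# The distance and pyrimidine fraction are the two per-exon features carried
# into the group comparison; candidates outside the exclusion zone are never
# considered, matching how branch points are called in practice.
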