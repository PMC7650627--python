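"""Exonic and intronic splicing-regulatory-element density profiling.

Exon bodies are scanned against enhancer (ESE) and silencer (ESS) motif
sets with overlapping match counting; densities are matches per base.
Flanking introns are scanned over 300 bp windows (truncated at the
neighbouring exon) against a signed scored table: positive scores count as
intronic silencers (ISS), negative as intronic enhancers (ISE).
"""

from pexsplice import MotifResource, exonic_sre_profile, intronic_sre_profile

ese = MotifResource(
    name="ESE-toy", cls="ESE", kind="list",
    motifs=frozenset({"GAAGAA", "CAGAAG"}),
)
ess = MotifResource(
    name="ESS-toy", cls="ESS", kind="list",
    motifs=frozenset({"TAGGGT", "TTCTCT"}),
)

exon = "CCAGAAGAAGAACC" + "ATTAGGGTAT" + "GGCACCTGGA"
prof = exonic_sre_profile(exon, [ese, ess])
print(f"exon of {len(exon)} nt")
for name, c in prof.counts.items():
    print(f"  {name}: {c} matches, density {prof.densities[name]:.3f} per nt")
print(f"  ESE:ESS ratio = {prof.ese_ess_ratio:.1f}")
# Overlapping matches each count once per start position, the convention of
# the published hexamer screens.

spliceaid_like = MotifResource(
    name="intron-toy", cls="intron_scored", kind="scored_table",
    scored_entries=(("TTAGGG", 5.0), ("GGGAAA", -2.0)),
)
up = "C" * 20 + "TTAGGG" + "C" * 20    # acceptor-side window
down = "T" * 10 + "GGGAAA" + "T" * 10  # donor-side window
iprof = intronic_sre_profile(up, down, spliceaid_like)
print(f"3' ss side: ISS density {iprof.iss_density_3p:.3f}, "
      f"ISE density {iprof.ise_density_3p:.3f}")
print(f"5' ss side: ISS density {iprof.iss_density_5p:.3f}, "
      f"ISE density {iprof.ise_density_5p:.3f}")
print(f"ISS:ISE ratio over both sides = {iprof.iss_ise_ratio:.1f}")
# A strong exon profile means dense ESE/ISS and sparse ESS/ISE; pseudoexons
# tend toward the opposite, which is what the group comparison quantifies.
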