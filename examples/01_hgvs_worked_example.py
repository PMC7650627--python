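"""The index-case variant: parsing, coordinate mapping, insertion length.

A deep-intronic substitution 19 nt upstream of a canonical acceptor creates
a new 3' splice site, splicing an 18 nt intronic tract into the mature
mRNA.  This script parses the three published descriptions of that event
and shows they are mutually consistent.
"""

from pexsplice import TranscriptMap, parse_hgvs

# A minus-strand transcript fragment anchored so the first base of the
# downstream exon (coding position 7310) maps to genomic position 31,792,309.
tmap = TranscriptMap(exons=[(31800000, 31807309), (31792109, 31792309)], strand="-")

v = parse_hgvs("NM_004006.2:c.7310-19A>G", tmap=tmap)
print("coding-level description :", v.hgvs_c)
print("genomic-level equivalent :", v.hgvs_g)
# On the minus strand the transcript alleles A>G appear as T>C on the
# plus-strand genome; position 31,792,328 = acceptor position - 19.

r = parse_hgvs("r.7309_7310ins7310-18_7310-1")
print("RNA-level insertion      :", r.raw)
print("inserted tract length    :", r.ins_length, "nt")
# The inserted tract runs from offset -18 to -1 of the intron: 18 nt of
# intronic sequence retained in the mRNA, which shifts the reading frame
# context and introduces a premature termination codon.
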