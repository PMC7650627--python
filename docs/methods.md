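# Methods

## The problem and the data model

A pseudoexon (PE) is an intronic tract spliced into mature mRNA as if it
were an exon. This package analyses *activated* PEs only: each catalog
entry must carry a pathogenic genomic variant whose mechanism explains the
activation — creation of a new splice site, strengthening of a cryptic
site, creation of an exonic splicing enhancer (ESE), or disruption of an
exonic splicing silencer (ESS). The catalog reader enforces two computable
inclusion criteria (an activating variant must be present; the PE must not
overlap any canonical exon) and rejects offending rows with a logged
reason rather than failing the run.

Coordinates are 0-based half-open plus-strand internally; HGVS surfaces
(g./c./r.) are 1-based. All analysis sequences are stored transcript-sense:
minus-strand intervals are reverse-complemented at extraction, and allele
conversion between c. and g. levels reverse-complements on the minus
strand. The transcript map is the single conversion layer; intronic
offsets (`c.7310-19`) anchor to the nearer exon boundary, following
standard nomenclature.

Groups for comparison: canonical exons (CE), splice-site-mechanism PEs,
SRE-mechanism PEs, and *possible poison exons* — PEs that are highly
conserved and acquire an in-frame premature termination codon (PTC). A PE
with both splice-site and SRE mechanisms goes to the splice-site group
(precedence rule; configurable). The poison label is orthogonal: by
default a poison PE contributes a second, poison-labelled row to the
feature table while remaining in its mechanism group, because published
group listings place such exons in both; a `poison_groups_disjoint` switch
makes the four groups a partition instead. "Highly conserved" has no
canonical numeric cutoff; the default is mean per-base score ≥ 2.0 on a
GERP-like scale, always reported together with the flag.

The PTC search translates the PE in its entry phase and continues into the
downstream coding sequence, so frame-shifting PE lengths whose stop only
materialises downstream are still detected.

## Splice-site models

Window conventions: donor 9-mer = 3 exonic + 6 intronic positions with GT
at intronic positions 1–2; acceptor scoring window 23-mer = 20 intronic +
3 exonic with AG at intronic −2,−1. The acceptor *consensus-motif* window
is a separate dialect (22 intronic + 1 exonic) used only for logo/consensus
rendering. Mandatory dinucleotides are required for scoring (a `relaxed`
flag exists for internal rescans); internal models score all window
positions. A loader for externally published joint probability tables
(`KMER<TAB>probability` lines) exists for parity runs against reference
implementations.

All probabilistic families score log₂(P_model/P_background) in bits. The
background is uniform by default — the simplest defensible choice, and it
makes the degenerate-training identities exact; a 0th-order composition
background can be supplied. Training pseudocount defaults to 0.5 per base
(0 allowed for fixtures).

- **WMM**: per-position frequencies. **MM1**: initial distribution plus
  position-specific transition tables; an unobserved previous base at zero
  pseudocount receives a uniform transition row rather than 0/0.
- **MaxEnt**: fitted by iterative proportional fitting. Constraint set:
  all single-position marginals plus all adjacent-pair marginals
  (`"pairs"`, default) or singles only. Initialisation is the product of
  single-position marginals (deterministic); updates cycle over the
  constraints until the worst L∞ marginal residual is ≤ 1e-6 (max 500
  iterations; non-convergence raises with the final residual). Pair
  targets use pseudocount/4 per cell so their implied singles match the
  single-position targets exactly — IPF then has a consistent, decomposable
  constraint system. Windows wider than nine positions are decomposed into
  a chain of fragments of at most seven positions overlapping in one
  position; the joint probability is the product of fragment probabilities
  divided by the marginal probabilities of the shared positions. With
  adjacent-pair constraints this chain construction is exact (it is the
  junction-tree factorisation of the fitted Markov structure). With
  singles-only constraints the fitted distribution is the product of
  marginals, so maxent reproduces the WMM — bitwise, because both paths
  multiply the same factors in the same order; this identity is a test.
- **MDD**: consensus bases are taken position-wise from the training set;
  at each node the split position maximises Σ_j χ²(consensus-indicator_i,
  base_j). A split requires the strongest pairwise χ² to clear the
  significance threshold (default p < 0.001 at df = 3) and both children
  to have at least `min_leaf` (default 25) windows; otherwise the node
  becomes a WMM leaf. A threshold of p = 0 (never significant) collapses
  the tree to a single leaf that reproduces the WMM exactly.
- **Percent score**: 100·(t − t_min)/(t_max − t_min) over the matrix,
  clamped to [0, 100]; a degenerate matrix (t_max = t_min) scores 100.

**Variant delta-scoring.** The mutant region is built by applying the
variant; for every model the best post-variant window overlapping the
edited span (mandatory dinucleotide required) is found and the aligned
pre-variant window is scored regardless of its dinucleotide, so
`delta = post − pre` is always defined. Calling floors (0 bits for
probabilistic models, 65 for the percent score, both configurable) gate
what counts as a *site*: `creates_new_ss` requires a post-variant site
call with no callable pre-variant site; `strengthens_cryptic_ss` a
callable pre-variant site and a positive delta; everything else —
including a chance AG near the variant whose window never clears the
floor — is `no_ss_effect`.

## Branch point

The published branch-point predictor in this field is a trained SVM whose
weights are not recoverable from its description; this package implements
a PWM surrogate with the same search discipline: candidates are restricted
to the AG exclusion zone (AGEZ) — the maximal AG-free interval [−d, −3]
upstream of the acceptor AG — scored over a heptamer whose sixth position
is the branch adenine, with the best candidate reported and ties broken
toward the 3′ ss. Search range defaults to 15–100 nt upstream
(configurable; the surrogate's documentation, not an inherited value).
Derived features: BP-to-3′ss distance and the pyrimidine fraction of the
interval (bp, −3] — excluding the branch adenine and the terminal AG;
bounds are configurable and an empty interval reports 0. The PWM is
trainable from any user heptamer set; the synthetic generator supplies
one.

## SRE scanning

Match counting is overlapping by default (one count per matching start
position — the convention of the published hexamer screens; a
non-overlapping mode exists). Exonic densities divide by exon length;
intronic windows are 300 bp per side, truncated at the neighbouring
canonical exon, and densities divide by the length actually scanned — a
fixed 300 denominator would understate truncated windows. Scored-table
sign classification is exact zero: positive = ISS, negative = ISE (the
convention of the source database, applied as published); zero scores are
rejected at load. Ratios (ESE:ESS, ISS:ISE) are reported absent — never
0/0 — when the denominator count is zero. PSSM scanning is transcript
sense only.

## Consensus motifs and conservation

PWMs are built directly from pre-aligned windows (no motif discovery —
the alignment is fixed by the splice-site register). Information content
is 2 − H(column) bits against a uniform background. The IUPAC rule is
Cavener-style: a single base if its frequency exceeds 0.5 and doubles the
runner-up; else a two-base code if the top pair exceeds 0.75; else N
(thresholds configurable). Per-position conservation comparison runs a
Mann–Whitney test per column, two-sided by default with a directional
option; no multiple-testing correction by default (raw per-position
significance is the reported convention here), with an optional
Benjamini–Hochberg switch.

## Statistics

Implemented from first principles, with scipy used only for ranking and
distribution functions: tie-corrected Kruskal–Wallis
(C = 1 − Σ(t³−t)/(N³−N); all-equal input returns H = 0, p = 1 by
convention); Nemenyi on mean ranks in the studentized-range flavour
(q·√2 against the studentized-range distribution with k groups, infinite
df) — the χ² flavour is the other common variant and which one any given
software uses is rarely stated, so the choice is documented here;
Mann–Whitney U with exact full enumeration of the null distribution of U
(standard recursion) for pooled n ≤ 12 without ties, otherwise a normal
approximation with tie and continuity corrections; identical samples give
p = 1. Quartiles use linear interpolation between order statistics
(type 7). The runner performs Kruskal–Wallis per feature, Nemenyi only on
significance at α = 0.05, Mann–Whitney for pooled PEs versus CEs, and
drops missing values per feature with counts logged. No correction across
features is applied (none is conventional for this battery); a BH switch
exists.

## Synthetic data: what it emulates and what it does not

The generator's defaults are the study conditions: ~90–220 bp canonical
exons; AT-rich intron composition (A/T 0.33, C/G 0.17); log-uniform intron
lengths (10³–10³·⁵ bp, inflated when needed so every PE keeps ≥ 320 bp to
its neighbours and flanking windows are untruncated unless a test requests
truncation); splice sites sampled from canonical-register frequency
matrices (donor MAG|GTAAGT, pyrimidine-tract acceptor); per-class exonic
silencer densities 0.04/bp (CE) versus 0.06/bp (PE) — the planted 1.5×
elevation; ten PEs across the four mechanism classes; two poison PEs with
frame-preserving length, a planted in-frame TAA, elevated conservation
(mean 3.0 vs 0.0 for other PEs, 2.5 for CEs, SD 1.0 on a GERP-like scale)
and an acceptor sampled from a sharpened matrix (column exponent 3) so the
poison group's stronger 3′ ss is reproducible as a planted, directional
property. Activating variants are single-nucleotide changes acting on the
acceptor (site creation breaks/restores the AG; strengthening degrades/
restores one pyrimidine-tract position) or on the exon body (one base away
from an enhancer motif; silencer disruption); every plant is verified by
rescoring — site-mechanism variants must classify as planted, SRE-mechanism
variants must move exactly their own motif count and produce no
splice-site call — with bounded rejection sampling. Randomness is split
into named seeded streams (sequence, variants, conservation, sre, motifs,
model training) so one knob perturbs only its stream; outputs are
byte-identical under a fixed (seed, config).

Passing tests on this generator show that the pipeline recovers *planted*
structure under idealised conditions: independent columns within splice
sites, no repeat elements or genomic homology, no RNA secondary structure,
no recursive splicing, Gaussian conservation, and motif resources that are
random k-mer sets rather than the published (licensed) ones. They do not
show that real dystrophin PEs carry these signals; the curated catalog
fixture ships the published group structure with synthetic placeholder
coordinates for exactly this reason.

## Problem sizes and verification scale

Test and acceptance runs use desk-scale sizes chosen to make the checks
sharp but cheap: 1,000 windows for the bitwise maxent/WMM identity, 500
sequences for scanning-oracle equality, 50 replicates of n = 40 + 40 exons
for the silencer-elevation power experiment (detection in ≥ 90% of
replicates), 20 generator seeds (~200 PEs) for mechanism recovery
(≥ 95%), and a fixed-seed 40 + 40 × 23-position dataset for exact recovery
of five planted conservation shifts. Parity with externally published
acceptor tables (maximum-entropy scores 11.72/3.73, percent scores
91.24/69.98 for the index-case variant and the natural exon-51 acceptor)
requires the published tables and an hg19 slice that cannot be shipped
with the package; the corresponding test states exactly what is missing
and fails until those files are supplied under `tests/data/external/`.

## Known limitations

HGVS support covers substitutions, deletions, insertions (including
interval insertions at the RNA level) and delins; inversions and complex
rearrangements are stored descriptively and never silently skipped.
Large rearrangements therefore contribute to catalog summaries but not to
sequence-level rescoring. The branch-point model is a PWM surrogate, not
the published SVM. The maxent acceptor decomposition is a chain (exact for
the default constraint set) rather than the bespoke overlapping-fragment
layout of the original reference implementation; parity with its published
scores requires loading its tables. The Nemenyi variant and the poison
double-counting mode are configurable because the conventional choices are
genuinely underdetermined.
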