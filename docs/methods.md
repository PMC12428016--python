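# Methods

`mitoray` re-implements, as a tested library, the standard desk analyses
applied to a newly sequenced vertebrate mitogenome — here anchored to the
*Potamotrygon leopoldi* (white-blotched river stingray) record and its
published organization table. This note describes each model or procedure,
the parameters that matter, and the choices made where the design was
genuinely open.

## Coordinates, annotation model, and validation

Feature coordinates are 1-based inclusive end-to-end, the convention of
published mitogenome organization tables; conversion to 0-based half-open
happens only inside the GenBank/FASTA readers and writers. Records are
circular; only the control region may wrap the origin (a GenBank
`join(a..L,1..b)` collapses to one wrapping feature).

The validator recomputes every row's length (`stop - start + 1`) and the
intergenic spacer to the next start-sorted feature
(`start(i+1) - stop(i) - 1`, negative = overlap; the last row wraps to the
first). Declared lengths and spacers from the source table are compared
and *flagged*, never corrected: coordinates are the only self-consistent
source in such tables, so all downstream statistics use
computed-from-coordinates values while the declared columns are retained
for reporting. On the packaged reference table this flags five rows
(ATP6, tRNA-Glu, tRNA-Pro, the second tRNA-Ser, D-loop) and surfaces the
conflict between the declared protein-gene total (11,434 bp), the
computed total (11,435 bp), and the separately published figure
(11,444 bp). The packaged table also carries rows whose printed
intergenic values disagree with their own coordinates; these are flagged
the same way.

## Composition and strand skews

Strand asymmetry uses the standard definitions AT skew = (A−T)/(A+T) and
GC skew = (G−C)/(G+C), computed on the heavy (+) strand as deposited.
Percentages are over counted A+C+G+T only; ambiguity codes are tallied
separately and excluded from all denominators (the published fractions
carry no ambiguity class). Skews are stored at full precision; rendering
to two decimals (round-half-even) is purely a display concern — the
reference record's printed AT skew of 0.13 is a truncation of the 0.1394
implied by its own composition and is documented, not asserted.

Arithmetic on *printed* percentage tables is done by direct summation
(AT content = A% + T%), without renormalizing to 100, so published AT
contents are reproduced exactly. The reported GC skew of the reference
record is negative while its printed composition (G 30.42%, C 12.84%)
implies +0.41; the report layer flags this sign inconsistency (consistent
with a C/G label swap in the source) and leaves both values in place.

## Codon usage: genetic code, RSCU, ENc

All codon work uses NCBI translation table 2 (vertebrate mitochondrial:
ATA=Met, TGA=Trp, AGA/AGG=stop), the code the organisms force. Its
synonymous-family partition is 12 two-fold, 6 four-fold (including Arg,
reduced by the AGR stops) and 2 six-fold families — no single-codon
amino acids, so perfectly uniform usage gives ENc = 60 under this code;
the familiar maximum of 61 belongs to the standard code, which the
functions also accept.

Protein genes are split into codons on the coding strand (light-strand
genes reverse-complemented first); a trailing 1–2 nt remainder is an
incomplete stop, reported in the conventional "T(AA)" / "TA(A)" notation
(completion by post-transcriptional polyadenylation) and excluded from
usage counts, as are complete terminal stops. Start codons are counted
literally, so a GTG start lands in the Val family while the start
tabulation reports it separately.

RSCU is a codon's count divided by the mean count of its synonymous
family (family sum = degeneracy; zero-usage families have no RSCU). ENc
is Wright's statistic: per-family homozygosity
F = (n·Σp² − 1)/(n − 1), averaged within each degeneracy class, and
ENc = N_singles + Σ_d K_d / F̄_d, clamped to the code's maximum. Families
with n < 2 or F = 0 carry no bias information and are dropped from their
class mean; an empty 3-fold class borrows (F̄2 + F̄4)/2 per Wright's
recommendation, any other empty class the family-weighted mean of the
available classes. Whole-mitogenome and per-gene ENc are both reported,
since a published "average ENc" does not say what it averages over.

## Tandem repeat detection

The finder targets control-region repeat arrays: candidate periods come
from recurring k-mer spacings (k = 5; on sequences ≤ 300 bp every period
is scanned instead), each period's lag-p self-match profile is segmented
Kadane-style under match +2 / mismatch −7 (the customary scoring weights,
configurable), and each segment is given a column-majority consensus
(ties alphabetical), re-scored against the tandem consensus, and
end-trimmed to the best-scoring sub-span. Hits below the reporting
threshold (default minimum alignment score 30, the setting used for the
reference record) or spanning < 1.8 copies are discarded; fractional
trailing copies are reported.

Two deliberate choices counter period-doubling, where a 2p-period
consensus "memorizes" per-copy noise and outscores the true period:
a hit whose consensus is itself tandem-periodic at a divisor (circular
self-identity ≥ 0.75) is re-derived at that fundamental period, and
overlapping descriptions of one locus are reduced by a
description-length-penalized score (raw score minus match × period). The
reported score stays the raw alignment score and is reproducible by
re-aligning the reported span against the tandem consensus.

The alignment model is substitution-only (no gap states): control-region
copies diverge mostly by point substitution, and the planted-repeat
generator is substitution-only as well. Arrays whose copies have drifted
by indels would be found with a shifted period or split into sub-arrays;
this is a known limitation relative to full alignment-based finders.

## Gene order and breakpoints

Gene orders are signed circular permutations over a canonical vocabulary
(synonym map for COXI/COX1-style label variation; duplicated Leu/Ser
tRNAs disambiguated by coordinate rank), rotation-normalized to tRNA-Phe
when present. Breakpoints are counted on *directed* clockwise adjacencies
restricted to the shared gene set: with directed pairs, one adjacent
transposition costs 3 breakpoints and breakpoints = 0 exactly when the
orders agree up to rotation. Strand flips are tallied separately, so a
gene inverted in place contributes one strand disagreement and no
breakpoint.

## Selection screen (NG86 + foreground scan)

The pairwise screen is Nei–Gojobori (1986) counting: per codon, the
fraction of the nine single-base changes that are synonymous gives its
synonymous sites (changes *to* stop codons count as nonsynonymous sites,
keeping S + N = 3 per codon); differing codon pairs are resolved over all
equally weighted mutational pathways, pathways through stop codons
disregarded unless every pathway is. pS = Sd/S and pN = Nd/N are
Jukes–Cantor corrected (d = −¾ ln(1 − 4p/3), absent at p ≥ ¾), and
ω = dN/dS (absent when dS = 0). Codons with gaps or ambiguity are
pairwise-deleted; internal stops are an error.

The sitewise screen flags codons where a designated foreground sequence
carries an amino acid absent from an amino-acid-monomorphic background —
a transparent counting analogue of a branch-site scan, not a likelihood
method. Per-gene enrichment is a one-sided binomial test of the gene's
flag count against the pooled flag rate across genes (α = 0.05). Site
counts from such a screen are method-dependent: they are not expected to
match counts produced by other tools on other datasets, and the report
simply presents the gene → count layout so real alignments can be run
through it.

Consistency between simulator and estimator: with the S+N=3 convention,
nonsynonymous *sites* include stop-neighboring changes the simulator can
never accept, so the NG86 ω̂ of neutrally simulated data plateaus around
0.9 rather than 1.0. Recovery checks therefore run at ω ∈ {0.2, 1.0}
with a ±0.15 band, under the uniform (κ = 1) neutral kernel the counting
method assumes.

## Distances, neighbor joining, bootstrap, monophyly

Distances are p-distance or Kimura 2-parameter
(d = −½ ln(1−2P−Q) − ¼ ln(1−2Q)) with pairwise deletion of gap/ambiguous
columns; saturated K2P pairs are recorded as undefined and refuse tree
building. Neighbor joining is the standard Q-criterion agglomeration with
deterministic tie-breaking by taxon label and negative branch estimates
clamped to zero (deficit moved to the sibling); it is exact on additive
matrices, which the test suite verifies against randomly generated trees
and against DendroPy's independent implementation. Bootstrap support is
column resampling with replacement; supports are bootstrap proportions —
they occupy the Newick support slot but are not posterior probabilities.
Monophyly of a taxon set is evaluated after rooting on a designated
outgroup (outgroup rooting only, as in the reference analysis). Multiple
sequence alignment is consumed, not computed: the evolver produces true
alignments, and real data should arrive pre-aligned.

## Synthetic data: what it emulates, and what it does not

The generator emits a circular record following the packaged reference
template (vertebrate gene order, per-gene coordinate-computed lengths,
the nine light-strand genes emitted reverse-complemented, the published
start/stop codons including the two incomplete stops). Protein genes are
codon-sampled with per-family Dirichlet weights; tRNA/rRNA and
control-region backgrounds are i.i.d. draws from the published per-class
base compositions; the control region carries planted tandem arrays
(defaults: 128 bp × 4 and 20 bp × 6 at 5% per-base divergence, the two
repeat classes described for the reference control region). Defaults:

| dial | default | rationale |
| --- | --- | --- |
| composition targets | published whole-genome / rRNA / CR percentages | the study's stated composition |
| `codon_alpha` | 16 | E[F_d] = (α+1)/(dα+1) puts expected ENc at ≈ 57.6, the published bias level |
| `cr_repeats` | (128, 4, 0.05), (20, 6, 0.05) | the two reported repeat unit lengths, at mild divergence |
| `at_content` dial | off | rescales background composition preserving A:T and G:C ratios when set |

Every generator output is self-consistent (declared = computed lengths,
zero-gap layout), making it the clean-room control against which the
reference table's internal conflicts stand out. One integer seed drives a
single NumPy generator threaded through every sampler; identical seeds
give byte-identical genomes.

The evolver walks a Newick guide tree: K2P jump process for non-coding
features, codon-level process with an ω acceptance dial for protein
genes (stop-creating proposals rejected; terminal stops held fixed).
There is no indel process — true alignments stay trivial — and the
`indel_rate` dial refuses non-zero values rather than pretending.

What passing tests therefore show about real data is limited: real
mitogenomes have overlapping genes, composition heterogeneity along the
molecule, context-dependent mutation, indels in the control region, and
among-site rate variation, none of which the generator produces. The
synthetic recovery results demonstrate that each estimator inverts its
own generative model at realistic parameter settings — not that the
published values for the deposited record are reproduced, which requires
downloading the real accessions and feeding them through the same report
layout.

## Problem sizes and numerical conventions

Stochastic checks run at fixed seeds and deliberate scales: planted-repeat
recovery over 100 control regions (period within ±2 bp, ≥95% required);
NG86 against an exhaustive pathway oracle on 1,000 random 30-codon pairs;
ω recovery as the mean over 20 replicate 500-codon pairs per ω; neutral
screen false-positive rate over 200 gene tests; NJ exactness on random
additive trees of ≤ 8 taxa; monophyly recovery over 30 replicate 6-taxon
families at 10,000 sites (≥95% required). Ties everywhere break
deterministically (alphabetical consensus bases, label-ordered Q-matrix
pairs, smaller-period-then-earlier-start repeat hits); display rounding
is round-half-even to two decimals for percentages, skews, and ENc.
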