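# Methods

This note documents the models behind `amp12q`: what the simulators
emulate, the analysis criteria and their thresholds, the numerical
choices, and where the design was genuinely open. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Coordinate model and toy genome

All internal coordinates are 0-based half-open; SEG and VCF output is
1-based, as is standard. The default genome is a 24-chromosome human-like
genome with hg19 lengths scaled 1:1000 (chr1 ≈ 249 kb … chr12 ≈ 134 kb).
The mechanisms under study depend on relative genome structure, not
absolute scale, and the reduced scale keeps per-base oracles (exact
brute-force copy-number counts) tractable in tests. Centromeres are
modelled as single chromosome midpoints — sufficient to flag dicentric
derivatives, which is their only role here.

Gene models are synthetic: each toy gene has a 500 bp promoter, five
200 bp exons and 500 bp introns, with the coding sequence starting at
exon 2. Anchors follow the genes' proportional hg19 positions (*FRS2*
nudged to 73.5 kb on toy chr12 to avoid overlapping *MDM2*). Enlarged
bodies ensure that breakpoint jitter at realistic caller scales (tens of
bp) cannot dissolve the exon/intron structure the promoter-swap logic
depends on. *TP53* is on the minus strand, so its promoter sits at the
high-coordinate side and the promoter-bearing arm of a break inside the
locus carries the chromosome 17 centromere — the geometry the dicentric
mechanism requires.

## Breakend orientation convention

A breakend records the flank of its position that faces the junction.
The four intrachromosomal junction classes follow read-pair conventions:
(right,left) = D (deletion-type), (left,right) = TD (duplication-type),
(right,right) = HH, (left,left) = TT, with breakends position-sorted.
This maps bijectively onto VCF BND bracket notation (a deletion-type
junction writes the canonical `N[mate[` form); the round trip is
enumerated in the test suite.

## Chromothripsis + BFB simulator

Chromothripsis cuts one chromosome 12 copy at `n_fragments − 1` uniform
positions, retains each fragment independently with `retention_prob`,
permutes retained fragments uniformly and flips each with probability
1/2. Under this law the four junction orientation classes are
equiprobable — the footprint the orientation criterion tests. The
contiguous span covering all selected loci (the 12q13-15 amplicon region)
is shielded from cuts and always retained: the simulator conditions on
tumours that kept their driver loci, which is what selection guarantees
in the observed cases.

Amplification is focal: a compact ring is built from the amplicon span
(trimmed to the loci plus a random 0.6–1.5 kb flank) and subjected to BFB
cycles, while the shattered backbone remains a uniform single-copy gain.
Each BFB cycle fuses the ring with its inverted sister copy and breaks
the palindrome at a uniform position. Among the break products that
retain the required loci, survival probability is proportional to the
product's selected-locus copy count: a uniform choice would make copy
number a martingale with no expected growth, which cannot express
"selective amplification", so selection is explicitly size-biased
(fitness proportional to amplicon dose). The required minimum copy count
escalates with cycle number (2, 4, then 6), encoding selection pressure
toward amplification; when a cycle's requirement is geometrically
unsatisfiable (no valid break position), the cycle falls back once to the
weakest requirement instead of failing. A cycle with no valid product at
all is a die-out, resampled up to 1000 times before an error naming the
locus. Fold-back junctions emitted at fusion points are exclusively
HH/TT, which is what lets the orientation test separate pure BFB from
chromothripsis.

Templates: groups A and B shatter an *extra* chromosome 12 copy, so
their chr12 profile never contains deletions; group C shatters a normal
homologue, consuming it (baseline −1 genome-wide on chr12) so unretained
fragments manifest as deletions — exactly the rule the template-inference
operation applies in reverse.

## TP53-dicentric simulator

Chromosome 17 breaks inside *TP53* intron 1 (between promoter and CDS).
The promoter-bearing centromeric arm fuses to a partner chromosome arm
carrying its own centromere, upstream of the partner gene's CDS
(default partner *ELF1*), so the derivative is dicentric by construction
and the partner's complete coding sequence sits under the *TP53*
promoter. A fragment of a chromosome 12 homologue containing *CDK4* —
but, by construction, neither *MDM2* nor *HMGA2* — is captured into the
derivative, and BFB cycles amplify *CDK4* while each surviving product
must retain the TP53-promoter junction (at least two, then at least
three *CDK4* copies after the first cycle). Donor homologues are
consumed: baseline chromosome 12, 17 and partner-chromosome copies drop
by one, which produces the chromosome 12 deletions seen in all such
cases. One in five group D configurations instead models homozygous
*TP53* loss with an independently captured *CDK4* amplicon and no
promoter fusion.

## Observation models

*SV callers.* Three abstract callers detect each true junction
independently with sensitivity 0.9, jitter reported positions by
N(0, 50 bp) rounded to integers, and append Poisson(2) false calls with
uniform coordinates and orientations. True SV lists contain amplicon
junctions only; boundaries of background noise CNAs are not emitted as
junction calls.

*Copy number.* The exact integer profile (baseline plus derivative
multiplicity) is kept as `true_cn`; the observed profile saturates copy
numbers above 8, reflecting that array segmentation does not resolve the
internal micro-steps of high-level amplicons. Background noise CNAs
(Poisson-distributed count; 20% whole-chromosome, otherwise 5–40% of a
chromosome; gains 60%/losses 40%, losses never stacking on losses) are
placed on chromosomes other than 12 and the sex chromosomes, so
mechanism-specific chromosome 12 signatures stay interpretable. Group
rates: A = 0, B = 2.5 with at least one event (its definition requires
alterations outside chromosome 12), C and D = 45 (genome-wide).

*RNA.* Two fusion programs detect each true swap with sensitivity 0.9
plus Poisson(0.5) random false fusions each. Expression is log-normal:
log2 expression = per-gene baseline + dosage · log2(cn/2) + sample effect
+ exon noise, with exons driven by a swapped promoter gaining
log2(swap_fold) (default fold 8). Gene-level values are exon means.
Matrices are emitted on the log2 scale; exon asymmetry is computed on the
linear scale.

The RNA cohort reproduces the study composition: 69 conventional, 3
dedifferentiated parosteal, 4 parosteal, 3 low-grade central
osteosarcomas, 13 osteoblastomas, plus 3 additional profiles from
multi-sampled 12q-amplified cases — 95 samples.

## Analysis criteria and thresholds

*Consensus.* Single-linkage clustering of cross-caller matches; a match
requires the same chromosome pair, the same orientation class
(configurable off, since coordinate-only matching is a defensible
alternative), and both breakend distances within tolerance. Defaults:
1000 bp DNA–DNA, 10 kb for RNA→DNA projections (RNA breakpoints are
exon-edge coordinates); the simulation-facing pipeline uses 500 bp,
matched to the callers' 50 bp jitter. Representative positions are
per-end medians (lower median for even counts); ties and processing
order are fixed by sorting, so the output is independent of caller
order. Fusion candidates are retained only when called by both programs
*and* linked by a consensus DNA variant.

*Chromothripsis.* Four criteria on a chromosome: (1) ≥ 10 breakends;
(2) ≤ 3 dominant copy-number states covering ≥ 80% of segments;
(3) oscillation fraction ≥ 0.6 — the share of interior copy-number
transitions returning to the immediately preceding state; (4) junction
orientation equiprobability not rejected at p ≥ 0.05 (χ² with 3 df, no
continuity correction; an exact multinomial test below 20 junctions).
All four → chromothripsis; at least two → inconclusive; otherwise
absent. The 2-of-4 inconclusive rule and the threshold values are this
package's operationalisation — the source framework is qualitative — and
all are configuration-exposed. Breakpoint clustering (KS distance
against uniform placement) is reported as evidence but not thresholded
in the verdict.

*Complexity and groups.* A chromosome is affected if its segmentation
shows a visible copy-number shift or a single non-diploid segment; X and
Y count as one pair in males (Y is excluded in females, where its
expected copy number is zero). The genomic complexity score is a
shift-point surrogate — copy-number shift points plus whole-chromosome
aneuploidies — standing in for an externally defined score whose exact
formula is not reproduced here; it is clearly labelled and replaceable.
The low/high complexity clusters split at half the chromosome units
affected (a tie counts as high, since the low cluster is defined by
"less than half"). Group assignment: D requires *CDK4* without *MDM2*
amplification, altered *TP53* (promoter fusion, homozygous loss, or SNV
— an SNV counts as mutated) and high complexity; C is *MDM2*-amplified
with high complexity; A is *MDM2*-amplified with nothing altered outside
chromosome 12; B is *MDM2*-amplified, low complexity, with at least one
alteration outside chromosome 12. Amplification of a locus means
observed copy number ≥ 4 (at least two extra copies over diploid) —
chosen a priori as this package's definition, since "amplification" is
not quantified in the source material.

*Promoter swaps.* An event requires one breakend inside the promoter
gene's intron 1 (configurable to any intron) with the junction retaining
the 5' part, and the mate upstream of the partner's CDS with the
junction retaining everything 3'. The promoter region defaults to 2 kb
upstream through exon 1. Events chained through a shared gene are
reported as one multi-gene record. Partner ranking uses dense descending
ranks over all cohort samples (ties share the better rank); ranking
within subtypes is available via grouping but is not the default.

## The bundled 25-case feature table

`data/study_cases.json` encodes only per-case facts printed in the
study: per-group subtype counts, *CDK4*/*MDM2*/*HMGA2* amplification
flags, *TP53* status (one homozygous loss and four promoter fusions in
group D; two SNVs in one group C case, which per the exclusivity
statement lacks *HMGA2* amplification), and chromosome 12 deletion
statements (one group B case; all but one group C case; all group D
cases). Unprinted numeric fields (`n_chrom_altered`, `gcs`) carry
group-consistent defaults and are flagged as such in each case's notes —
including the two CDKN2A-knockout group B outliers, whose exact
affected-chromosome counts are not printed and are encoded below the
half-genome threshold consistent with their group membership.

## What the simulations do and do not show

The generator reproduces the *structure* of the study conditions — group
composition, mechanism signatures, caller imperfection, cohort sizes —
not per-case genomic coordinates, which derive from controlled-access
data. Passing recovery experiments therefore demonstrate that the
analysis operations are correct and well-calibrated on data whose
generating process matches the stated mechanisms; they do not validate
the mechanisms themselves against sequencing reads. Not modelled:
read-level data, subclonal mixtures (one dominant clone), allele-specific
copy number, replication timing, and SNV calling (group D's SNV state
appears in the curated feature table, not the simulator). Problem sizes
(100-seed recovery experiments, 200-case cohorts, 50-SV consensus runs)
are the package's defaults and complete in well under a minute each.

## Numerical and determinism choices

All randomness flows through one seeded numpy Generator per case; every
stochastic operation appends its draws to the derivative's history, and
identical seeds reproduce truth and reports byte for byte (floats are
serialised at fixed precision). Die-out resampling is bounded at 1000
attempts. Copy number 0 yields a −inf log2 ratio sentinel; log2 ratios
are derived presentation metadata and do not participate in equality.
Degenerate inputs are handled explicitly: chromosomes with fewer than
three segments have undefined oscillation and force an "absent" verdict;
an empty excluded-exon mean yields an infinite asymmetry ratio, flagged
rather than raised.
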