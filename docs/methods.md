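# Methods

This note documents the models and procedures implemented in `mesamarker`,
the defaults and why they were chosen, what the synthetic generators do and
do not emulate, and the numerical conventions.

## Data model

Input sequences are Sanger consensus calls: one sequence per individual in
which a heterozygous site is a single IUPAC ambiguity character (`R`, `Y`,
`S`, `W`, `K`, `M`, three-base codes, or `N`).  The allele matrix
(`AlleleMatrix`) is the positions × individuals grid of such calls, with
`.` for missing data — deliberately distinct from `N`, which is a *made*
but uninformative call.  Positions are 1-based everywhere users see them.
The packaged validation matrix covers six SNP positions in the esterase
(SABP2-like) gene for 38 individuals from eight birch species, 20 high
MeSA producers (`ale`, `len`, `bg`, `med`) and 18 low producers (`pen`,
`uti`, `nan`, `aln`); the species → group map is configurable.

## Diagnostic marker discovery

A call *carries* allele *a* when *a* lies in its IUPAC expansion, so
heterozygous calls carry both of their alleles.  For each position and each
of the four bases, the scanner requires (i) zero informative contrast-group
carriers, (ii) target-group penetrance ≥ θ, and optionally (iii) a contrast
group fixed for one homozygous base.  Design choices:

* **θ default 0.9.**  The validation panel includes positions where one or
  two high-group individuals lack the diagnostic allele (18/20 at the
  weakest position).  θ = 0.9 admits such near-fixed markers while
  excluding positions with substantial sharing; it is exposed per run.
* **Missing and `N` handling.**  `.` is excluded from denominators.  `N`
  expands to all four bases, so treating it as a carrier would let a single
  low-quality contrast call veto every allele; `N` is therefore excluded as
  uninformative on both sides and counted in the marker's
  `n_uninformative` field.
* **One marker per position**, the highest-penetrance allele, ties broken
  alphabetically (ties are only possible at θ ≤ 0.5).
* Marker counts are non-increasing in θ (tested as a property), and
  discovery is verified against brute-force enumeration of every
  (position, allele) pair.

A recomputation note carried in every run report: within the high group
excluding *B. medwediewii*, the packaged matrix shows heterozygous calls at
three of the six marker positions (160, 189, 304), and in *B. medwediewii*
itself at all six; the low group has none anywhere.

## Panel classification

A new individual is voted position by position: one vote per covered panel
position whose call carries the diagnostic allele.  Majority of covered
positions decides; an exact tie, or fewer than 3 covered positions, is
`ambiguous`.  Note that an individual genuinely lacking the diagnostic
allele at most positions classifies as contrast regardless of its true
group — on the packaged matrix one high-group individual (whose expanded
column stacks four non-carrying calls) does so, giving 37/38 agreement.

## Phylogeny

Distances are uncorrected p-distances with pairwise deletion of gap/missing
columns.  Two comparison modes exist for ambiguity codes:

* **overlap** (library default): codes match when their expansions
  intersect — `R` is compatible with `A`.  Conservative for distance
  estimation, but it scores a heterozygote as identical to either
  homozygote, erasing heterozygous divergence.
* **strict**: literal code comparison.  The pipeline uses this mode for
  consensus sequences, because the group signal in this system partly
  *lives in* heterozygous calls (high producers are heterozygous at marker
  positions; low producers never are), and overlap matching discards it.

Trees are built with Saitou–Nei neighbor joining (standard Q criterion,
negative branch lengths clamped to zero, ties broken by input order, so
output is deterministic).  NJ is exact on additive matrices, which the test
suite exercises with randomly generated weighted trees (n ≤ 8).  Supports
come from a column-resampling bootstrap; a replicate supports a bipartition
only if the corresponding internal edge has positive length (zero-length
edges are unresolved, so identical sequences support nothing).  Group
monophyly is tested in the unrooted sense: some edge must separate exactly
the group from the rest.  The published analysis used maximum-likelihood
trees; this package substitutes the distance-based pipeline because the
claim being checked — two clades separating the producer groups — is
topology-level.  This deviation is recorded in every run manifest.

## Pairwise protein comparison

`global_align` is a Needleman–Wunsch/Gotoh affine-gap DP (default BLOSUM62,
gap open −10, extend −0.5, the first gap residue costing the open penalty).
Traceback ties prefer match, then gap-in-subject, making the reported
alignment deterministic.  Identity is matches over columns excluding
terminal gaps; coverage is query-relative (fraction of query residues
inside the non-terminal-gap region), following BLAST's convention.  The
published identity/coverage percentages for these proteins came from
database BLAST searches and are not reproduction targets; the aligner is
validated against exhaustive enumeration of all global alignments for short
sequences and against an independent library implementation.

`check_residues` maps 1-based reference residue indices through the
reference row's gaps to alignment columns and checks each sequence for the
expected residue — e.g. the esterase catalytic triad (Ser/Asp/His, S81,
D210, H238 in the tobacco reference) or the methyltransferase
cofactor-binding motif.  Annotations ship as editable YAML because the
binding-residue lists are figure-level annotations, not printed tables.

## Promoter scanning

Cis-elements are described by IUPAC consensus strings in an editable YAML
dictionary (TATA-box `TATAWAW`, CAAT-box `CCAAT`, ABRE `ACGTG`, G-box
`CACGTG`, ...).  A window matches when every pattern symbol's allele set
contains the sequence base; both strands are scanned, minus-strand hits are
reported at the forward-coordinate start of the matched span, and the
compact `74+` report notation concatenates start and strand.  Curated motif
databases use proprietary pattern sets, so absolute counts are not
comparable with database output; what the pipeline reproduces is the
analysis shape — per-species counts and group contrasts.  Scanning is
strand-symmetric (property-tested), and concatenation with a pattern-free
spacer is additive.

## Expression

Technical replicates are averaged per biological sample (technical sd
> 0.5 cycles flags an outlier; a single replicate is flagged, sd 0).  The
reference Ct is the arithmetic mean of the reference genes' mean Cts —
equivalent to normalizing expression by the geometric mean of the
references; whether the original analysis averaged actin and ubiquitin or
used them separately is not stated, so this default is noted in output.
ΔCt = Ct_target − Ct_ref and relative expression = E^(−ΔCt) with
amplification efficiency E = 2.0 by default (exposed as a parameter).
Relative expression is invariant to per-sample plate shifts.  Species ×
tissue rows carry the mean and sd over biological samples.

## Synthetic data

The generators produce every input the pipeline consumes, with recorded
ground truth, under the study design: 38 individuals (20 high / 18 low)
from eight species, a 792 bp esterase-like CDS, six planted diagnostic
positions with penetrance (1.0, 0.95, 0.95, 0.9, 0.95, 1.0), heterozygous
consensus codes at rate 0.5 among high-group carriers and none in the low
group, promoters of several hundred bp, and Ct tables with 3 biological ×
3 technical replicates at 0.3 cycles technical noise.

Choices that matter:

* **Deterministic carrier/heterozygote assignment.**  Which individuals
  carry a planted allele, and which carriers are heterozygous, is assigned
  deterministically (penetrance is hit exactly); only background mutations
  and Ct noise consume random draws.  Both the heterozygous block and the
  non-carrier block rotate across positions, so every individual mixes
  heterozygous and homozygous diagnostic calls — as in the real validation
  matrix — rather than one individual collecting every exception.
* **Background substitution rate 0.0005 per site per individual.**  The
  observed validation matrix contains no SNPs in this gene region beyond
  the diagnostic ones; 0.0005 (≈0.4 substitutions per individual, ≈15
  segregating background sites across the panel) still overstates that.
* **Promoter generation** rejects background windows matching any
  dictionary pattern, plants instances without overlap on random strands,
  and regenerates until the final scan counts equal the planted counts
  (insertion junctions can create incidental matches).  Self-complementary
  (palindromic) consensus patterns cannot satisfy exact-count planting on
  one strand and are not used in the default planted sets.
* **Ct model**: Ct = base − log2(level) + N(0, sd) per technical replicate,
  references at level 1.  The default scenario mirrors the study design
  qualitatively: the methyltransferase high in the bark of both high
  producers, with an 8-fold bark/leaf contrast in one of them, and low
  everywhere in the low producers.

What the generators do **not** emulate: species-level population structure
within groups (background substitutions are per-individual, not shared per
species), indels and alignment error, chromatogram-level miscalls, primer
or amplification artifacts, biological replicate variance beyond technical
noise, and realistic substitution processes (no transition/transversion
bias).  Passing round-trip tests therefore demonstrates correctness of the
computations under the stated design, not robustness to all properties of
real resequencing data.

## Problem sizes and determinism

Default analysis sizes — 38 sequences × 792 bp, 100 bootstrap replicates,
50 random additive trees (n ≤ 8), exhaustive alignment enumeration up to
length ~6–8, 1000 random sequences for the strand-symmetry property — were
chosen so the full test suite and the acceptance script each run in well
under a minute while exercising every code path at the study's actual
scale.  Every stochastic component takes an explicit seed; a fixed config
and seed reproduce byte-identical pipeline outputs (checksummed in the run
manifest).
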