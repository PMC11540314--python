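# Methods

`duoqtl` analyzes an interspecific F1 hybrid population in which two kinds
of heritable variation segregate at once: natural allelic variation between
the two haplotypes *within* each outbred parent, and large induced
copy-number variation (indels from pollen irradiation) confined to the
paternal chromosomes. This note records the models, the tunable parameters
and their defaults, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open.

## Population model

An F1 line inherits one of two haplotypes (D1/D2) from the maternal parent
and one of two (N1/N2) from the paternal parent at every locus, as a
recombinant mosaic. On the paternal chromosome a line may additionally
carry an indel: a deletion removes the transmitted paternal segment
(dosage 0), an insertion is modeled as a duplication of the transmitted
segment (dosage 2, identical sequence). Dosage is therefore the paternal
copy number in {0, 1, 2}, and total copy number is 1 + dosage because the
maternal copy is always present. The duplication semantics matter: they
are what closes the joint genotype universe at exactly
2 x (1 + 2 x 2) = 10 states (`{D1,D2} x ({NA} x {0} u {N1,N2} x {1,2})`).

## Pipeline stages

**Informative SNPs.** A SNP can reveal which focal-parent haplotype a
progeny inherited iff the focal parent is heterozygous and the other
parent is homozygous or heterozygous with a different unordered allele
pair. Parental genotypes are called from high-coverage counts (allele
present at >= 20% of reads and >= 3 reads; heterozygous iff exactly two
alleles pass); these caller thresholds are conventional and configurable.
Species-diagnostic SNPs (fixed differences between the parents) carry no
within-parent information and are excluded by construction.

**Phasing.** At each informative SNP, each deep-coverage line (>= 20x by
default) is assigned the focal allele it inherited: a focal allele f is a
consistent explanation when f is observed (>= 10% of reads and >= 2 reads)
and every observed allele is attributable to f or to the other parent's
genotype; sites where zero or both focal alleles are consistent are
missing. Adjacent SNPs are then linked in cis or trans by the majority
co-inheritance pattern; a link is accepted when at least
`floor(consistency * N)` of the N doubly observed lines agree. With the
default consistency of 0.9 and the design's deep subset of N = 122 this
threshold is 109 lines. The floor form is deliberate: at N = 122 a strict
"more than 90%" reading would demand 110, but the design's stated
acceptance count is 109, so the count is taken as authoritative and
generalized by floor. Accepted links chain into phase blocks; a rejected
link starts a new block (blocks are never stitched back together), and
hap1 of each block is anchored to the alphabetically first allele of its
first SNP — phasing is only defined up to a per-block relabeling, and all
accuracy evaluation respects that.

**Genotyping at 0.5x.** A low-coverage line is genotyped at a SNP only
when a read shows a haplotype-diagnostic allele (one the other parent does
not carry); reads matching neither parental allele are ignored as
sequencing error. Calls are binned, 50 consecutive informative SNPs per
marker (the last bin of a chromosome may be shorter), and combined by
majority vote with ties and empty bins as NA. Majority is the minimal
robust combiner; ties are genuinely ambiguous. Marker intervals span
[first SNP position, last SNP position], 1-based inclusive, and marker
ids are `chrom_start_end`.

**Line QC.** The depth threshold is chosen automatically as the smallest
per-line depth at which every deep-subset line above it has genomic-vs-
deep-data bin concordance >= 0.9 and a mean of at most `max_switches`
(default 5) genotype switches per chromosome. The mean (not the maximum)
over chromosomes separates noise — shuffled genotypes switch at every
other marker — from the occasional chromosome with a legitimately high
crossover count.

**Dosage.** Per-bin coverage is double normalized: each line's bin
coverage is divided by that line's *median* bin coverage, then by the
leave-one-out population mean of the same quantity at that bin. The
median, not the mean, is the per-line scale: a carrier's own large indels
drag the mean and would inflate every euploid bin toward the insertion
cut, while the median is untouched as long as most of the line's genome
is euploid. Leave-one-out prevents a line's own indels from biasing the
population baseline at small population sizes. Ratios are thresholded at
0.75/1.25 — the maximum-margin midpoints between the expected copy ratios
0.5/1.0/1.5 — and capped at dosage 2. Runs of fewer than `min_run = 2`
consecutive non-unit bins are reset to 1, because real indels (>= 250 kb)
span several 50 kb bins while isolated outlier bins are noise.

**Integration.** The maternal binned markers are the reference grid.
The paternal genotype at a marker is imputed at the marker midpoint from
its flanking paternal markers: a gap between two equal, observed flanks
inherits that genotype; unequal or missing flanks, and chromosome ends,
are NA. Dosage is read from the bin containing the midpoint. Dosage 0
forces the paternal haplotype to NA — a deleted segment carries no
allele — and this invariant is enforced on every constructed table.

## QTL models

**Single-channel scan.** For each trait and channel the model is
`Y_i = b0 + b1 * gt_i + e_i`, OLS at every marker, with codes D1/D2 -> 0/1,
N1/N2 -> 0/1 (NA inside deletions), dosage 0/1/2. Genome-wide significance
uses the permutation null of the maximum |t|: the trait is shuffled among
phenotyped lines, every marker refit, the maximum |t| recorded; the 95th
and 99th percentiles over 1,000 permutations (default) are the significant
and confirmed thresholds, computed per trait x channel. The two-sided
statistic is used because trait directions are arbitrary and deletions
commonly lower traits. Markers with fewer than 20 complete pairs or fewer
than 5 observations off the modal genotype are skipped — explicit floors
that make the power limits of rare indels auditable. Adjacent significant
markers merge into one QTL; variance explained is the adjusted R^2 of a
joint OLS fit (member markers for a single QTL, peak markers per QTL for
a trait's total), with collinear columns handled by rank.

**Combined 10-state model.** Each line x marker is assigned its joint
state `Pd.Pn.dose`; at every marker with at least two states holding
>= `min_group = 5` phenotyped lines, all present state pairs are compared
by a two-group Monte-Carlo permutation test on |mean difference| with the
add-one estimator `p = (1 + #{permuted >= observed}) / (1 + n_perm)`.
BH adjustment is applied per comparison family — one family per state
pair across all markers genome-wide (a `per_marker_across_pairs` scope is
available as a switch). Markers with any adjusted p below alpha = 0.05
merge by adjacency; the QTL's variance explained is the adjusted R^2 of
the trait on the peak marker's state dummies.

**Classification.** Each significant pair is typed by which components
differ: dose only ({0,1} deletion, {1,2} insertion, {0,2} joint), or
haplotypes only at equal dose (Pd, Pn, or both). Two identifiability
rules temper the union: (i) joint pair types — 0 vs 2 doses, or both
haplotypes differing — are separated by an effect of either single
mechanism and therefore never override unambiguous pairs, deciding the
label only when nothing else does; (ii) deletion evidence requires that
deleted lines differ from carriers of *both* paternal haplotypes, or that
no pure paternal-allelic pair is significant at the QTL. Rule (ii) exists
because a deleted segment carries no paternal allele: deleted lines mimic
whichever haplotype is phenotypically null, so a lone deleted-vs-N2
contrast is exactly the signature of a paternal allelic QTL as well.
Dosage evidence, when confirmed, takes precedence over allelic evidence;
a QTL whose only significant pairs are untyped (dose and haplotype both
differ) is reported as "ambiguous" and flagged.

## Synthetic data

The generator is the forward direction of everything above and ships a
truth ledger for recovery testing. Defaults emulate the real design at
desk scale: 5 chromosomes x 2 Mb, het-site density 5e-4/bp per parent
(~5,000 het sites each, of which ~15% shared between parents and half of
those uninformative), 343 F1 lines at 0.5x with a 122-line deep subset at
30x, per-read error 0.005, Poisson crossovers (1.5/chromosome, uniform
positions, no interference — the real recombination map is unknown and
this is a simulation parameter, not a claim about the organism), Poisson
indel counts (2.5/line) at 66.5% deletions, indel sizes uniform on
250-750 kb. The size cap is a deliberate rescaling: events are kept at
2.5-7.5% of the desk-scale genome, matching the fractional footprint of
sub-chromosome-to-chromosome events on a real ~400 Mb genome; letting one
event span a whole 2 Mb desk chromosome would make single lines
majority-aneuploid, a regime the real design never enters and in which
relative-coverage normalization is ill-posed. Bin coverage is
Poisson(mean_cov x copies/2) on 50 kb bins with mean_cov = 250 reads — a
0.5x genome at ~100 bp reads. Phenotypes are
`Y = b0 + sum(effect x code) + N(0, noise_sd)`, with mechanism codes for
planting single-mechanism effects (deletion/insertion indicators in
addition to the three channel codes).

A second, marker-level generator draws the common marker table directly —
haplotype mosaics as a two-state Markov chain over the marker grid and
indels as marker-span events at a background rate of 0.78/line, so that
roughly half the lines carry an indel and a marker has a handful of
carriers, emulating the sparse per-locus indel coverage of the real
population. It is used for calibration and power studies (type-I rate,
detection, classification recovery), where read-level simulation adds
cost but no information; read-level recovery is always measured on the
full generator. Planted-QTL studies state effects as standardized effects
(raw coefficient = effect x noise_sd / sd(code)), which makes the
expected scan t about effect x sqrt(n) independent of carrier counts.

What the generator does not emulate: mapping bias, GC and mappability
structure, genotyping batch effects, segregation distortion, crossover
interference, mosaic/fractional dosage, and any linkage disequilibrium
structure beyond the crossover process. Passing recovery tests therefore
shows the algorithms are correct under the stated statistical model, not
that real-data artifacts are handled.

## Problem sizes and runtime

Tests and the acceptance script run the read-level pipeline at the
default desk scale above (minutes on one CPU), the type-I study on 200
null traits at 200 permutations, detection on 50 replicates at 200
permutations, and classification recovery on 10-15 replicates per
mechanism at 1,000 permutations. These sizes were chosen so the whole
suite stays desk-sized while keeping Monte-Carlo error well inside the
asserted margins.

## Known limitations

- Phase blocks are conservative: a single rejected link splits a
  chromosome even when the flanking blocks could be stitched through
  population information.
- Bins of 50 SNPs are laid down per chromosome, not per phase block, so a
  bin spanning a (rare) block boundary mixes orientations and votes
  noisily; at the default scale phasing yields chromosome-scale blocks
  and this does not occur.
- The imputer assigns whole gaps from flanking markers, so genotypes
  within one bin of a true crossover are unreliable (accepted as NA or
  either flank in evaluation).
- The combined model's classifier cannot distinguish a deletion effect
  from a paternal allelic effect when deletion carriers of only one
  haplotype exist at the locus; such QTLs take the allelic label when a
  pure allelic pair is significant, and the deletion label otherwise.
- Dosage is capped at 2 by design; higher amplifications would be called
  2.
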