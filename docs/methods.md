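# Methods

## Measurement model

A heterozygous SNP in a Sanger chromatogram produces two superposed peaks at
the variant basecall, one per allele channel.  For sample *i*, template
*t* ∈ {cDNA, gDNA} and sequencing direction *d* ∈ {F, R}, the package works
with the natural-log peak-height ratio

    r_itd = ln(h_ref / h_alt),

with both heights required strictly positive (zero-height pairs are excluded
and logged, never imputed).  Reverse reads record the complementary bases;
orientation complements them back to forward-strand alleles and negates *r*
when the numerator is not the designated reference allele, so all ratios share
one allele ordering.

Genomic DNA from the same heterozygous individuals carries a true 1:1
template ratio, so its measured log-ratio estimates the direction-specific
assay/dye bias.  The corrected statistic is

    rho_itd = r_itd − mean over gDNA measurements of direction d.

Centering uses the **cohort mean** of gDNA ratios per direction, not a
per-sample cDNA−gDNA pairing.  Two considerations force this choice: the
report format carries a gDNA column with mean 0 and a nonzero SD, which only
cohort-mean centering produces (per-sample pairing would collapse the gDNA
distribution to a point), and it keeps samples usable when one template
failed QC in one direction.  The per-sample pairing alternative is noted here
and deliberately not offered.  gDNA from family and control samples is pooled
into a single reference group.

Forward and reverse values of a sample/template are combined by averaging the
available corrected ratios ("F&R"); a sample with one passing direction
contributes that single value.  This availability rule reproduces the
observed behaviour that the combined group mean need not equal the average of
the per-direction means when per-direction sample sets differ.

Consequences used as test oracles: corrected gDNA ratios average exactly 0
per direction (asserted at |mean| < 1e-12); adding any constant to one
direction's ratios changes no corrected value; swapping reference and
alternate negates everything; with zero noise the corrected cDNA ratio equals
the configured group log fold change exactly.

## Group testing

Three groups are compared per SNP and analysis set (F, R, F&R): cDNA of the
affected family, cDNA of controls, pooled gDNA.  The global test is the
Kruskal–Wallis test on midranks with tie correction; pairwise Wilcoxon
rank-sum tests are the post-hocs.  Multiplicity is handled by the closed
testing procedure.  With exactly three groups, every intersection hypothesis
containing two pairwise nulls implies all three distributions equal — the
global null — so the closure collapses to: reject a pair iff its own p < α
and the global p < α.  Pairwise p-values are reported raw; the closure lives
in the significance calls.  The shortcut is only valid for three groups, so
other designs are refused rather than silently generalised.  α = 0.05
throughout.

Exact p-values:

* Kruskal–Wallis — full enumeration of the distinct assignments of pooled
  ranks to groups; p is the proportion with H ≥ H_observed.  Above 500 000
  assignments the enumeration switches to complete Monte-Carlo (20 000
  permutations, add-one estimator).  `auto` uses the exact path for total
  n ≤ 12.
* Wilcoxon rank-sum — the subset-sum distribution of doubled midranks
  computed by dynamic programming, which equals full enumeration of
  C(n_a+n_b, n_a) assignments at any sample size.  Two-sided p doubles the
  smaller tail, capped at 1 (the "sum of both tails at least as extreme"
  convention is a documented alternative; software conventions differ and the
  doubling rule was chosen as the more common default).  `auto` uses the
  exact path for n_a + n_b ≤ 20.
* Ties take midranks with the standard variance correction in the asymptotic
  fallbacks; statistic comparisons in the enumeration paths use a 1e-9
  absolute tolerance so midrank arithmetic cannot flip a count.

Stratified analyses (by sex, affection status, …) are deliberately plain
relabel-and-rerun: subset the samples by stratum and repeat the identical
procedure.

## Eligibility screen

Only heterozygous samples are informative, so a SNP enters DAE analysis iff

1. genotyping QC passes: Hardy–Weinberg exact p (Bonferroni-adjusted across
   the panel) > 0.05, call rate > 0.97, MAF > 0.05;
2. it has ≥ `min_het_per_group` heterozygous cell lines in both groups
   (default 3; the stricter reading of 4 is available via config — at the
   panel's printed counts both thresholds select the same six SNPs, so the
   discrepancy is surfaced rather than resolved);
3. its transcript is expressed in the assayed cells — supplied as external
   flags because expression is a wet-lab determination.

The HWE test is the Levene–Haldane exact test (conditional distribution of
the heterozygote count given allele counts, p = sum of probabilities of
outcomes no more probable than observed), computed in log-space; the
chi-square test is unreliable at a 28-sample cohort and is offered only as a
config option.  The Bonferroni multiplier is the number of SNPs entering QC
(12 for the packaged panel), not the post-filter count.  HWE is computed on
the pooled cohort; with a single multi-generation family in the sample no
kinship correction is attempted, a documented caveat of the original design
as much as of this package.

The packaged 12-SNP candidate panel encodes the published per-group
heterozygote counts and expression flags; the individual genotype assignments
behind those counts were never published and are filled deterministically
(first *k* samples heterozygous, one alternate homozygote, reference
homozygotes elsewhere).  The panel is for cascade logic, not population
genetics.

## Peak extraction

Trace input is either ABIF/AB1 (read through Biopython; processed channels
DATA9–12 mapped to bases via the dye-order record, basecalls from PLOC2/PBAS2)
or a plain-text four-channel tabular dialect shared with the synthetic
generator.  The variant basecall is located by exact match of user-supplied
flanking sequences, with the variant base itself unconstrained; zero matches
and multiple matches are distinct errors (extend the flanks, never
fuzzy-match).  Peak height is the channel maximum within ±0.5 × the local
inter-peak spacing around the basecall (half-spacing prevents capturing a
neighbouring peak); a point-intensity mode is available because trace
libraries differ in which definition they report, and the choice is exposed
as config with local-maximum default.

QC flags (configurable, flagged pairs excluded from DAE by default):
`low_signal` if an allele peak is at or below 5 × the median flanking
baseline of its own channel; `offtarget_peak` if a third base's peak in the
variant window exceeds 0.5 × the smaller allele height; `low_quality` if the
mean flanking signal purity falls below 0.5.  The thresholds are package
defaults, stated in the run manifest, not published values.

## Synthetic data generator

The generator emulates the study design so every stage is testable without
deposited data.  Defaults are the assayed conditions: 6 heterozygous family
and 7 heterozygous control cDNA samples, cDNA allelic log fold changes
θ_family = +0.42 and θ_control = −0.34 (the reported forward-row group means,
used as realistic demo effects, not as ground-truth claims), balanced gDNA
(θ = 0), small opposite direction biases (±0.1, an arbitrary but realistic
dye bias that the centering must cancel), and per-direction dropout 0.1
(mirroring the differing per-analysis sample counts of the original design).

Heights follow h₁ = L·p·e^ε1, h₂ = L·(1−p)·e^ε2 with p = σ(t),
t = θ_group + bias_direction, ε ~ N(0, σ²) i.i.d., L = 1000 arbitrary
fluorescence units.  Noise is multiplicative log-normal because Sanger peak
intensities are positive and heteroskedastic; the induced noise on ln(h₁/h₂)
is additive Gaussian with variance 2σ².  The default σ = 0.07 makes corrected
gDNA ratios scatter with SD ≈ 0.1, matching the reported gDNA column SDs.

Chromatograms are one Gaussian peak per base (default spacing 12 points,
peak SD 2.5, amplitude 300) with the two allele amplitudes superposed at the
variant and optional uniform baseline noise.  Genotype tables draw controls
from HWE (optionally perturbed by a fixation-index-style disequilibrium
parameter) and gene-drop the family through a fixed 3-generation, 10-member
pedigree template (founder grandparents, two children with founder spouses,
four grandchildren); the real pedigree's published structure is not
reproduced.  All randomness flows from named substreams of one root seed, so
identical configs give identical bytes and adding a draw does not perturb
existing streams.

What the generator does **not** emulate: dye blobs, mobility shifts,
re-phasing artifacts, mixed templates beyond two alleles, linkage between
SNPs, or real pedigree genotype configurations.  Passing tests therefore
demonstrate correctness of the computation under the stated model, not
robustness to every real-chromatogram pathology.

## Problem sizes

The simulation-based checks run at: 2000 replicate studies for the null
family-wise error (binomial 2-SE band around 0.05), 500 replicates at 50
samples/group and σ = 0.3 for parameter recovery (3σ/√n coverage ≥ 95%), 220
random datasets of total n ≤ 10 for enumeration-oracle equivalence of the
exact tests, and the full genotype-configuration grid to n = 30 for the HWE
oracle.  These sizes give Monte-Carlo error well inside the asserted bands.

## Known limitations

* The closed-test shortcut is hard-wired to three groups by design.
* Asymptotic rank tests at group sizes of 4–13 are approximations; the `auto`
  method keeps the exact paths at these sizes precisely for that reason.
* Cohort-mean gDNA centering estimates the assay bias with finite-sample
  error, which adds (small) correlated noise to every corrected value of a
  direction; the parameter-recovery bounds account for it.
* No kinship correction in HWE; no linkage or segregation analysis; no
  absolute expression quantification or cross-SNP normalisation.
* AB1 support is read-only; the generator emits only the tabular dialect.
* No FDR across SNPs: multiplicity control is within-SNP (the closure), as in
  the original design.
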