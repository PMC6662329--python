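# Methods

This note records the statistical conventions, numerical choices and known
limitations of the package, in the spirit of a software methods appendix.

## Data model

A *phased alignment* holds equal-length haplotype sequences over
{A,C,G,T,N,-}, exactly two per diploid individual (header convention
`<id>_hap1` / `<id>_hap2`, configurable by regex), with a 0-based
`frame_offset` marking the first complete codon. The default amplicon
geometry is 172 bp with `frame_offset = 2`: 56 complete codons flanked by
two bases on each side. Codon indices are 1-based within the reading frame;
alignment columns are 0-based internally and 1-based in reports. The PBR
codon partition is always an input file (JSON or whitespace-separated
indices), never hard-coded, because peptide-binding assignments are a
property of the study locus.

Microsatellite genotypes are unordered pairs of positive integer allele
labels; missingness is an explicit mask, never a sentinel allele visible to
the statistics.

## Missing-data policy

All sequence statistics use complete deletion: any column containing a gap,
or more than `max_missing_frac` N's (default 0), is removed before
anything is counted, so S, η, π and both thetas share one usable-site count
L. This is the reproducibility-first convention of the standard sequence
analysis packages. Codon statistics instead use pairwise deletion at codon
granularity: a codon containing an ambiguous base excludes that codon for
the affected sequence pair only, which preserves data in large samples.

## Diversity estimators and variances

- π is the mean per-site difference over all C(n,2) unordered pairs,
  identical (exactly, and property-tested) to the haplotype-frequency form
  with the n/(n−1) correction. Its SD comes from Nei's sampling variance
  V(π) = (n+1)π/(3(n−1)L) + 2(n²+n+3)π²/(9n(n−1)).
- Hd = n/(n−1)(1 − Σxₖ²). The default SD is Nei's single-locus sampling
  variance (the 2/(n(n−1)){2(n−2)(Σx³ − (Σx²)²) + Σx² − (Σx²)²} form); a
  large-sample "replication" variance (4/n)(Σx³ − (Σx²)²) is available via
  `sd_method="replication"`. The sampling form is the default because it
  remains sensible at the subsample sizes (n = 22 haplotypes) the
  comparison tiers use.
- θ_W = S/(a₁L). Its variance uses the moment estimator implied by
  Var(S) = a₁θ + a₂θ², with θ² estimated unbiasedly by (S² − S)/(a₁² + a₂).
- θ_Eta = η/(a₁L), where a column with b observed bases contributes b − 1
  to η; θ_W = θ_Eta whenever every segregating site is biallelic (tested).

## Nei–Gojobori analysis

Synonymous site fractions per codon are computed by enumerating the nine
single-base mutants; changes producing stop codons are excluded from the
denominator, so each sense codon always contributes exactly 3 sites.
Pairwise codon differences average over all orderings of the differing
positions, dropping orderings that pass through a stop codon; a pair with
no stop-free pathway is excluded with a log entry (the generator never
produces one, but field data could). Proportions pN, pS use site totals
averaged between the two sequences and are Jukes–Cantor corrected,
d = −(3/4)ln(1 − 4p/3); pairs with p ≥ 3/4 are excluded and logged. dN and
dS are means over all unordered pairs, computed on collapsed distinct
haplotypes with multiplicity weights so cost scales with distinct-variant
count rather than n².

The z-test resamples the analyzed codon columns with replacement
(default 1,000 replicates, seed recorded in the result); se(dN − dS) is the
bootstrap SD and the reference distribution is standard normal. The
two-sided p is reported by default; a one-sided option exists because
positive selection is a directional hypothesis. When dS = 0 the dN/dS ratio
is reported as undefined rather than infinite. Reported distances are
per-site; the ratio is scale-invariant by construction.

## Tajima's D

D = (k̄ − S/a₁)/√(e₁S + e₂S(S−1)) with k̄ the mean raw pairwise difference
count (not per-site, following the original formulation) over the filtered
column set. The nonsynonymous filter classifies each variable column within
its observed codon context: a column qualifies if exchanging its observed
bases changes the encoded amino acid; codons with several variable
positions are resolved by enumerating minimal stop-free pathways, and the
column counts as nonsynonymous only when every pathway changes the residue
at that column's step. Significance uses the beta-distribution
approximation: a beta on [D_min, D_max] (the large-S theoretical extremes)
moment-matched to mean 0 and variance 1, which is algebraically the
original parameterisation; results are reported as the conventional classes
(p > 0.10, 0.10 > p > 0.05, p < 0.05, p < 0.01). D values outside the
theoretical band (possible at very small S) are clipped to the band edge,
yielding the extreme class.

## Microsatellite statistics

He is the uncorrected 1 − Σp² (matching the conventional toolkit output);
the unbiased 2n/(2n−1) variant is a flag. HWE is a chi-square
goodness-of-fit with df = k(k−1)/2; a seeded Monte-Carlo null (re-pairing
allele copies) is available and is the instrument of choice for
calibration work, since the asymptotic test is conservative when rare
alleles inflate df. The Bonferroni family for locus filtering is
loci × populations: a locus flagged in any population is dropped for all.
Linkage disequilibrium uses a permutation G-test on the genotype×genotype
contingency table with p = (1 + hits)/(1 + n_perm); this is a documented
substitution for the MCMC exact test of the classical software, chosen for
determinism under a recorded seed. Null-allele and scoring-error detection
are out of scope; a frequency sanity screen flags high missingness and
large heterozygote deficits instead.

F_ST defaults to per-locus (Ht − H̄s)/Ht averaged over informative loci;
Weir–Cockerham θ (variance components summed over alleles, ratio-of-sums
over loci) is available because the estimator behind a published F_ST value
is often unstated. The two differ in expectation (the default is slightly
downward-biased at small n); both are exposed.

## Sampling design

Conservative draws match the reference sample's *marginal* age-class and
sex histograms exactly, the way demography-matched designs are specified
(2 calves / 15 juveniles / 38 adults and 32 males / 23 females in the
default composition). The per-age sex split is sampled uniformly from the
feasible range each draw; draws are mutually disjoint and individuals with
unknown age or sex are ineligible. Infeasible requests raise an error
naming the deficient category. Subsampling partitions each conservative
pool into disjoint sets of 11 (floor(n/11) of them by default,
overridable), giving replicate diversity values; the two-sample t-test is
pooled-variance (the df the design reports imply pooled rather than
Welch; Welch is a flag). Microsatellite measures are compared with paired
t-tests across loci (df = loci − 1). All randomness flows from one master
seed through deterministic SHA-256-derived child seeds, echoed in every
report.

## Synthetic data generator

The generator reproduces the *statistical structure* the analysis assumes,
not the evolutionary history behind it. A stop-free 172-bp base sequence is
drawn once per scenario seed; K distinct haplotypes toggle alternative
bases at V variable sites, each haplotype carrying the alternative with
probability q; within-codon site combinations that could produce a stop
codon are excluded at construction. Site placement follows weights over
(PBR-nonsynonymous, PBR-synonymous, non-PBR) candidate positions, with
nonsynonymous intent verified against the codon table — the default
(0.70, 0.12, 0.18) concentrates roughly 80% of variable sites in PBR
codons. Haplotype frequencies are symmetric Dirichlet(α); α is the single
evenness knob (α→∞ gives uniform frequencies and maximal Hd for given K).
The exact expected pairwise diversity of a realized pool is computed from
the pool itself and stored in the scenario manifest, which is what the
parameter-recovery tests check π̂ against.

Default study conditions: the designed contrast uses 239 individuals in
population A (K = 40, q = 0.28) versus 55 in population B (K = 20,
q = 0.2), giving an expected π ratio of ≈1.25–1.3 at π levels near
0.05–0.066, with identical 23-locus microsatellite settings (3–10 alleles
per locus, Dirichlet α = 1 frequencies, 2% missingness, F = 0) and the
conservative-sample demographic composition apportioned exactly. The null
scenario draws both 55-individual populations from one shared pool, so
only sampling noise separates them — the correct null for type-I-error
calibration. Diploid genotypes pair two independent haplotype draws
(random mating); the microsatellite inbreeding knob F inflates homozygosity
as P(hom k) = pₖ² + Fpₖ(1−pₖ).

What the generator does **not** emulate: mutation-rate realism, linkage,
genealogical correlation between sites, null alleles, genotyping error,
and pathogen-mediated selection dynamics. Passing tests therefore
demonstrate that the estimators and the comparison machinery behave
correctly on data with the designed structure, not that any particular
biological conclusion holds in the field.

A separate helper draws neutral infinite-sites alignments from a standard
constant-size coalescent (via msprime, one column per mutation) purely for
estimator-calibration work; the accompanying tree sequence lets tests
cross-check π and Tajima's D against tskit's independent implementations.

## Problem sizes used in calibration

The shipped calibration studies use: 1,000 null replicates for the
subsampling t-test type-I error; 100 replicates for the designed-contrast
power check; 400–1,000 neutral coalescent fixtures (n = 24 haplotypes,
θ = 5, L = 600) for estimator consistency; 200–400 loci at n = 100–200 for
HWE calibration. These sizes put Monte-Carlo standard errors well inside
the asserted tolerances while keeping a full run on one CPU in the
low minutes.

## Known limitations

- dN/dS magnitudes depend on the (documented) per-site scale; published
  tables from other software are often per-100-sites, so only the ratio
  and the z-test transfer directly.
- The chi-square HWE test over-counts df when alleles are rare; use the
  Monte-Carlo option for small or skewed samples.
- The beta approximation for Tajima's D is itself approximate at very
  small S; an observed D outside the theoretical band is reported at the
  band edge.
- Conservative matching treats the reference composition as exact counts;
  compositions with unknown-category individuals are matched on the known
  categories only.
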