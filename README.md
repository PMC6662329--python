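# divcompare

Comparative analysis of adaptive (MHC) versus neutral (microsatellite)
genetic diversity between two wildlife populations of unequal sample size —
the kind of contrast conservation geneticists draw when asking whether a
declining population carries less adaptive variation than a viable one.

The package was built around a two-population bottlenose dolphin study
system: a 172-bp MHC class II DQB exon-2 amplicon containing the
peptide-binding region (PBR), phased into two haplotypes per individual,
plus a panel of 23 polymorphic microsatellite loci and per-individual
demographic metadata (sex, age class). Everything runs equally on real
phased FASTA/CSV inputs or on the built-in synthetic two-population
generator, so the full statistical pipeline is testable without any data
download.

## What it computes

**Sequence diversity** (per sample of *n* haplotype copies over *L* usable
sites, complete deletion of gap/N columns):

- nucleotide diversity π = n/(n−1) · Σᵢⱼ xᵢxⱼπᵢⱼ, with Nei's sampling
  variance;
- haplotype diversity Hd = n/(n−1) · (1 − Σ xₖ²);
- Watterson's θ_W = S/(a₁L) from the segregating-site count S, and
  θ_Eta = η/(a₁L) from the minimum mutation count η, with a₁ = Σ₁ⁿ⁻¹ 1/i.

**Selection signals** on the in-frame amplicon:

- Nei–Gojobori codon-based dN and dS (pathway counting, Jukes–Cantor
  corrected), computed separately for PBR codons, non-PBR codons and all
  codons, with a bootstrap z-test (codon columns resampled, default 1,000
  replicates) for dN ≠ dS — the classic signature of balancing selection on
  antigen-binding codons is dN/dS > 1 inside the PBR only;
- Tajima's D on all sites and restricted to nonsynonymous columns, with
  significance classes from the beta-distribution approximation;
- the tally of variable nucleotide sites falling inside PBR codons.

**Microsatellite diversity**: per-locus Ho, He = 1 − Σp², effective allele
number Ae = 1/Σp², Shannon index ¹H = −Σp ln p; chi-square (or seeded
Monte-Carlo) Hardy–Weinberg screening with Bonferroni locus filtering; a
seeded permutation G-test for linkage disequilibrium; and multi-locus F_ST
((Ht − H̄s)/Ht by default, Weir–Cockerham θ by flag).

**Demography-matched comparison**: three sampling tiers — maximum samples,
conservative draws from the larger population exactly matching the smaller
sample's age-class and sex composition, and disjoint 11-individual
subsamples — with pooled two-sample t-tests across subsamples for the
sequence measures and paired t-tests across loci for the microsatellite
measures, plus sex-ratio chi-square screens.

## Worked example

Simulate the designed scenario (population A richer at the MHC locus,
identical microsatellite settings) and summarise its sequence diversity:

```
$ divcompare simulate --preset paper_like --seed 1 --out demo/
$ divcompare seqdiv --alignment demo/alignment.fasta --frame-offset 2
{
  "n": 588, "L": 172, "S": 43, "Eta": 51,
  "pi": 0.0648, "Hd": 0.9795, "theta_w": 0.0360, "theta_eta": 0.0426, ...
}
```

588 haplotype copies (2 × 294 individuals, both populations pooled) over
172 bp; 43 segregating sites carrying 51 inferred mutations; a pooled
nucleotide diversity of 6.5% with almost every haplotype pair distinct
(Hd ≈ 0.98).

A full run writes the five report tables:

```
$ divcompare run --config run.yaml     # seed: 1, scenario: paper_like
```

`table1.tsv` (selection; population A, PBR codons):

```
population  sites  N   dN      dS      dN_dS   z       p
A           pbr    17  0.2624  0.0398  6.5948  4.5201  0.0000
A           nonpbr 39  0.0098  0.0364  0.2685  -1.1626 0.2450
```

dN exceeds dS only inside the peptide-binding codons — positive/balancing
selection concentrated where antigens bind. `table5.tsv` (inter-population
tests):

```
marker  measure  tier         t        df  p
mhc     pi       subsampling  9.2213   18  0.0000
msat    Ho       conservative -0.0428  22  0.9663
```

The MHC nucleotide-diversity contrast between the populations is strongly
significant across disjoint subsamples while the microsatellite measures
are not — the qualitative pattern the sampling design is built to detect.

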