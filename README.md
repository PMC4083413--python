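# snvblur

Privacy-preserving aggregation of single-nucleotide-variant (SNV) cohorts
for data sharing.

Clinical resequencing labs routinely hold exome/genome SNV calls that would
help other geneticists interpret a candidate variant — but raw genotypes
plus phenotype metadata are re-identifiable, so data-privacy rules keep them
locked up. `snvblur` turns a cohort of per-sample VCFs plus a phenotype
metadata file into a *shareable* aggregated VCF in which no individual can
be singled out, while a submitter-held encrypted linkage file preserves the
ability to withdraw a sample later. It is aimed at human geneticists and
data stewards who want to publish cohort-level SNV + phenotype evidence
without releasing personal genomes.

## The method

Aggregation proceeds in three steps:

1. **Metadata ambiguity (k-anonymity).** Samples with identical HPO term
   sets form phenotype classes. The combination of released attributes
   (trait, HPO present/absent, gender, platform, enrichment) must occur for
   at least *k* = 2 samples; violating combinations are suppressed to
   "unknown", greedily in the order enrichment → platform → gender → HPO
   sets. Trait and patient/control status are never suppressed.
2. **Fragmentation.** Each sample's SNVs are split into (by default 5)
   sub-samples with weights drawn from the flat Dirichlet law on the
   simplex, so fragment sizes are deliberately *unequal* (expected size
   CV ≈ 0.82 for 5 fragments) — equal-sized fragments could be regrouped by
   size. Sub-sample ids are random 128-bit tokens. The secret
   sample ↔ sub-sample map is stored only in an encrypted,
   passphrase-protected linkage file.
3. **Rare-variant blurring.** With freq(SNV) = number of samples carrying
   ≥ 1 alt allele at a site (genotype-blind), a variant is rare iff

       freq(SNV) ≤ f · med(freq),   default factor f = 1.5

   The median is used because exome spectra have a heavy singleton excess.
   Rare SNVs — singletons above all — are the re-identification risk, so
   their sub-sample linkage and genotype counts are deleted; only locus,
   alleles, trait summary and the submitter's contact remain. Common SNVs
   keep sub-sample genotypes. On a typical 50-exome cohort the median
   occurrence count is 7, the threshold 10.5, i.e. variants seen in up to
   10 samples (20 %) are blurred.

The output is a sites-only VCF 4.2 whose `GB*` INFO keys carry all counts,
sub-sample genotypes and trait summaries (`snvblur validate` checks a file
for corruption). A query engine answers position / rsID / gene-symbol
searches with carrier, genotype and allele frequencies.

## Worked example

```
$ echo "horse battery staple" > pass.txt
$ snvblur simulate --n 10 --sites 2000 --seed 7 --out cohort/
wrote 10 sample VCFs (2000 sites, 8035 genotype calls) and cohort/meta.ini

$ snvblur aggregate --ini cohort/meta.ini --out aggregated.vcf \
      --linkage linkage.enc --seed 11 --passphrase-file pass.txt
aggregated 10 samples, 2000 sites; threshold 4.5 (factor 1.5); 1280 blurred / 720 unblurred records; 38 metadata suppressions

$ snvblur validate --store aggregated.vcf
aggregated.vcf: OK (0 violations)
```

The cohort median occurrence count here is 3, so the threshold is
1.5 × 3 = 4.5: the 1280 sites carried by ≤ 4 of the 10 samples lose their
genotype linkage, the 720 commoner sites keep sub-sample genotypes. The 38
suppression-log entries are attributes deleted to reach k-anonymity.
Querying one common and one blurred site:

```
$ snvblur query --store aggregated.vcf --term rs10000110
chr1:100085 G>T  rs10000110  carriers 7/10 (freq 0.700)  allele freq 0.500  het/hom 4/3
  traits: early-onset epilepsy (n=2), healthy control (n=2), inflammatory bowel disease (n=2), retinal dystrophy (n=1)

$ snvblur query --store aggregated.vcf --term chr1:100187
chr1:100187 C>G  -  blurred  carriers 2/10  contact: Data Steward, Synthetic Genomics Unit <steward@example.org>
  traits: early-onset epilepsy (n=1), retinal dystrophy (n=1)
```

The blurred record reveals only the locus, the trait labels of its carriers
and whom to contact — an interested geneticist follows up with the
submitter instead of downloading genotypes. Allele frequency counts het
carriers once and hom-alt carriers twice over 2n chromosomes
((4 + 2·3)/20 = 0.50 above). Consent withdrawal uses the encrypted linkage
file:

```
$ snvblur remove-sample --store aggregated.vcf --linkage linkage.enc \
      --passphrase-file pass.txt --sample sample_004 --out reduced.vcf
removed 1 sample; store now has 9 samples, 1938 records
```

`snvblur diagnose` adds the evaluation tools: `sfs` (occurrence-count
spectrum), `ratio-curve` (unblurred-data fraction vs cohort size) and
`overlap` (a re-identification experiment checking that a probe sample's
own sub-samples are not distinguishable from foreign ones by Jaccard
overlap).

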