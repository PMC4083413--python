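# Methods

## Data model

A variant locus is the 4-tuple `(chrom, pos, ref, alt)` with 1-based VCF
coordinates and single uppercase bases; it is the identity used everywhere.
Only single-nucleotide substitutions are in scope: indels, symbolic alleles
and spanning deletions in input VCFs are skipped and counted, never an
error. Multi-allelic lines are split into one key per SNV alt, and a sample
whose genotype mixes two alts (e.g. `1/2`) counts as a heterozygous carrier
of each. Homozygous-reference calls are never stored; zygosity is exactly
{het, hom_alt}, with phased separators read as unphased.

Sample metadata comes from an INI file: a `[global]` section of defaults
(trait, PI, contact, …) and one `[sample:<ID>]` section per sample (status,
gender, platform, enrichment, HPO term sets, optional per-sample overrides
and a `vcf` path). Trait, status and contact are mandatory; HPO ids must
match `HP:` + 7 digits; a term cannot be both present and absent.

## Metadata suppression (k-anonymity)

The released attribute combination of a sample is
(trait, HPO-present, HPO-absent, gender, platform, enrichment), with unset
attributes shown as `"unknown"`. Before release every combination must
occur for at least `k` samples (default k = 2, configurable upward; a
cohort smaller than k cannot be released). Suppression is greedy: while a
combination is too rare, the smallest violating group (ties broken by
sorted sample ids) loses its first still-present attribute in the fixed
order **enrichment → platform → gender → HPO sets**, chosen so that the
clinically informative HPO terms survive longest. HPO suppression clears
both sets, merging the group with the empty-HPO class rather than
generalizing to parent terms — ontology-walking generalization is a
different algorithm with different guarantees, deliberately out of scope.
When a fully suppressed group still cannot reach multiplicity k (its
trait-mates retain distinguishing attributes), the same priority-ordered
suppression is applied to the samples sharing its trait until the released
tuples merge; this completion is what makes k-anonymity attainable exactly
when every trait label occurs ≥ k times. Trait and patient/control status
are never suppressed, so a trait carried by fewer than k samples is a hard
error. Every deletion is logged as `{sample_id, attribute, reason}`.

Suppression is monotone (attributes only move toward "unknown") and
idempotent; both are property-tested, and a brute-force counting oracle
checks the ≥ k multiplicity over fuzzed cohorts.

## Fragmentation and the linkage file

Each sample's calls are partitioned into up to `n_subsamples` (default 5)
fragments. Per-sample weights are drawn once from the flat Dirichlet law on
the probability simplex (all weight vectors equally likely, concentration
1), then each SNV is assigned independently. Under this law the expected
coefficient of variation of fragment sizes is `sqrt((m-1)/(m+1))` ≈ 0.82
for m = 5 — fragments of visibly different sizes are the point, since
near-equal fragments could be regrouped into whole samples by size alone.
Empty fragments are dropped. Sub-sample ids are 128-bit random hex tokens
drawn from the pipeline RNG: they carry no information about the source
sample, and runs with different seeds produce disjoint id sets.

The sample ↔ sub-sample map, together with each sample's full call list,
its (suppressed) trait, phenotype-class token and released tuple, is
serialized to JSON and encrypted. The container uses scrypt (n = 2^14,
r = 8, p = 1) for key derivation, an HMAC-SHA256 counter-mode keystream as
the cipher, and an encrypt-then-MAC HMAC-SHA256 tag verified in constant
time before any decryption; scheme id and KDF parameters live in a
cleartext JSON header so files are self-describing. A wrong passphrase or
a single flipped bit yields an authentication error with no partial
output. The full call list is retained (not just the sub-ids) because
consent withdrawal must also decrement counts on blurred records, whose
sample linkage no longer exists anywhere else.

## Rare-variant blurring

`freq(SNV)` is the number of distinct samples carrying ≥ 1 alt allele at a
site — genotype-blind (het and hom each count once). The rare threshold is
`factor × median(freq)` with factor defaulting to 1.5; the median of an
even-length multiset is the mean of the two middle values, and "rare" means
`freq ≤ threshold` (a strict-inequality mode is available; with integer
counts and the typically fractional threshold the two differ only at exact
equality). The median is the right location statistic here because the
spectrum's singleton excess would drag a mean far down.

Blurred records keep locus, alleles, carrier count, trait summary
(label → carrier count, never per-sample) and the submitter contact;
sub-sample genotypes and het/hom counts are deleted. Unblurred records keep
the sub-sample genotype list (sorted by sub-id so record ordering leaks no
sample grouping) plus a phenotype-class token per entry. The blurred and
linked key sets are disjoint by construction and together cover the store —
the core privacy invariant, tested directly.

Raising the factor never unblurs a record (monotonicity), and a degenerate
cohort in which all counts are equal blurs everything, since k ≤ 1.5 k.

## Aggregated-VCF dialect

The shareable store is a sites-only VCF 4.2 (no sample columns — fragments
are not fixed-width columns and blurred rows have no genotypes). All
genotype information lives in `GB*` INFO keys (`GBBLUR`, `GBN`, `GBCAR`,
`GBHET`/`GBHOM`, `GBSUBS`, `GBCLASS`, `GBTRAIT`, `GBCONTACT`), declared in
header meta-lines; free-text values are percent-encoded. Cohort-level
metadata — public phenotype classes (token, HPO sets, member count), the
multiset of released tuples, threshold, and a config echo including the
seed — rides in one percent-encoded JSON header line, making
`read(write(store))` field-exact. Records are sorted by natural chromosome
order, then position, ref, alt. The validator re-checks everything a
consumer relies on (SNV-only loci, blurred rows without linkage or
genotype counts, `GBCAR` consistent with listed genotypes and
`GBHET + GBHOM`, no duplicates, sort order) and reports violations rather
than raising.

Sample ids appear nowhere in the store; this is asserted by substring scans
over fuzzed cohorts. Seeds are mandatory and echoed so a published store
can be reproduced byte-for-byte — the linkage file's KDF salt and nonce are
drawn from the same pipeline RNG for the same reason.

## Consent withdrawal

`remove_sample` decrypts the linkage file, deletes the sample's sub-calls,
and decrements carrier/het/hom/trait counts on every site it carried,
blurred records included; zero-carrier records are dropped. The threshold
is frozen rather than recomputed: re-thresholding could only *unblur*
previously rare records, and their linkage is gone from the public store. A
re-aggregation oracle (brute-force recomputation from the remaining
samples with the frozen threshold) verifies all counts.

## Synthetic cohort generator

No real cohort ships with the package; the generator reproduces the
statistical structure the method was designed for. Occurrence counts are
i.i.d. from a two-component mixture over k = 1..n:

    f(k) = (1 − w) · k^(−α) / Z  +  w · U{⌈(1−b)n⌉ .. n}

with defaults α = 1, w = 0.10, b = 0.10, 140,000 sites, n = 50 samples,
P(hom) = 1/3 for each carrier. The defaults were chosen analytically so
that three characteristic exome-cohort figures hold simultaneously at
n = 50: f(1)/f(50) = 0.2000/0.0207 ≈ 9.7 (singletons ≈ 10× common sites),
the count median is 7 (F(6) = 0.490, F(7) = 0.519), hence threshold
1.5 × 7 = 10.5 and a largest rare count of 10 = 20 % of samples, and a mean
of ≈ 41,300 SNVs per sample (inside the typical 40,000–45,000 exome band).
Carriers per site are drawn uniformly without replacement; the cohort is
exchangeable — no linkage disequilibrium, no per-sample rate variation, no
population structure. Passing tests therefore demonstrate correctness of
counting, thresholding and privacy mechanics, not realism of genome
biology; any analysis depending on LD or shared haplotypes is outside what
this generator can exercise. Synthetic metadata (a control group plus 1–3
patient trait groups of ≥ 2 members each, a small HPO vocabulary with
occasional singleton term-set variants, random genders/platforms/
enrichment kits) gives the suppression step realistic work.

## Diagnostics

* **Unblurred ratio**: fraction of genotype records (sample-site carrier
  pairs) on unblurred sites, `Σ k over k>thr / Σ k`; a per-site variant is
  emitted alongside because the two readings differ and either could be
  meant by "fraction of unblurred data". The ratio curve over cohort sizes
  is computed directly from sampled count spectra — provably identical to
  running fragmentation + blurring and measuring the store, which a test
  asserts on a small cohort — and shows logarithmic-like growth with a
  plateau: with the default generator the record-weighted plateau sits
  around 0.85–0.9 (the plateau level depends entirely on the cohort's
  frequency spectrum; the shape, growth then saturation, is the robust
  claim).
* **Overlap / re-identification experiment**: a probe sample's full SNV set
  is scored against every released sub-sample by shared count, containment
  and Jaccard. Own fragments are subsets of the probe, so containment is
  trivially 1.0 and useless to an evaluator as a realism check; the
  headline metric is top-K precision under Jaccard (K = number of own
  fragments), operationalizing "own fragments do not stand out". On
  10-sample cohorts this precision averages ≈ 0.2 over 20 seeds — own
  fragments are not reliably distinguishable. The threshold for acceptance
  (< 0.8) is a design choice, not a hypothesis test.

## Numerical and scale choices

Medians use numpy on integer count arrays; an independent sort-and-pick
oracle checks 1,000 random multisets. Default problem sizes in tests and
diagnostics are scaled to keep the suite fast while leaving every estimate
far from its decision boundary: study-condition checks use the full
140,000-site cohorts (the generator is vectorized; one cohort takes ~2 s),
the ratio curve uses 8,000–20,000-site spectra (the ratio is a per-site
functional, independent of site count up to sampling noise), and the
overlap experiment uses 20,000-site cohorts of 10 samples. The scrypt cost
parameter (2^14) balances brute-force resistance against test-suite
latency; it is recorded per file, so stronger parameters decrypt
transparently.

## Known limitations

* k-anonymity is enforced on released attribute combinations only; no
  l-diversity or t-closeness, and genotype-based linkage attacks are
  addressed by fragmentation + blurring, not by formal differential
  privacy.
* Blurred records keep carrier counts and trait labels; a submitter who
  considers those sensitive should raise the factor or withhold traits.
* No annotation, liftover, BCF, or duplicate-submission detection; gene
  queries need a user-supplied BED/GFF3, and external reference
  frequencies a user-supplied TSV (no network access anywhere).
* The consequence ranking helper orders labels (nonsense > readthrough >
  start-lost > splice-site > missense > synonymous) but the package does
  not itself predict consequences.
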