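# Methods

`methcross` analyses allele-resolved reduced representation bisulfite
sequencing (RRBS) data from a reciprocal cross of two inbred mouse strains,
C57BL/6J (B6) and DBA/2J (DBA).  The eight-animal design — both parental
strains and both reciprocal F1 hybrids (BXD: B6 mother; DXB: DBA mother),
each in both sexes — decouples the three axes the screens separate:
genotype (which strain's chromosome), sex, and parental origin (which
parent the chromosome came from).  This note documents the models, the
defaults and why they are set where they are, what the synthetic data
generator does and does not emulate, and the numerical choices that affect
results.

## Data model

A methylation *site* is one cytosine on one strand with methylated count
k and total count n; plus- and minus-strand cytosines are never pooled.
Contexts follow the trinucleotide convention (CG, CHG, CHH with H ≠ G),
classified 5'→3' on the cytosine's own strand with sequence ends padded as
non-G.  Coordinates are 1-based inclusive throughout; only BED output uses
0-based half-open.

An *epiread* is the ordered vector of CpG states (M/U/N) one sequencing
read observed, together with the base it shows at any strain SNP it
overlaps.  Epireads are the unit of haplotype phasing and of the
allelically-methylated-region (AMR) scan; everything site-level is obtained
by aggregating them.

## SNP calling and read phasing

Base counts are pooled across samples and a biallelic SNP is called when
pooled coverage ≥ 6, minor allele frequency ≥ 10%, and the top-two allele
pair is not the bisulfite confound of its strand (C/T on the plus strand,
G/A on the minus): conversion of unmethylated cytosines produces exactly
those substitutions, so such pairs are uninterpretable as genotype.  A
third allele is tolerated up to 5% of coverage (sequencing noise).  The
six-count minimum is interpreted as total coverage, not minor-allele depth.

Reads are assigned to the B6 or DBA haplotype by majority vote over the
informative SNPs they cover; C/T pairs never vote even when present in an
external genotype map, for the same conversion reason.  Ties, or a minority
vote above 25% of informative sites, yield `ambiguous`; reads covering no
informative SNP are `uninformative`.  In F1 animals the cross direction
then maps allele to parental origin (BXD: B6 = maternal; DXB: DBA =
maternal), which is what lets the imprinting screen compare maternal
against paternal chromosomes while the reciprocal design cancels genotype.

## Site screens

Two test families cover all screens.

**Pairwise binomial criterion** (two individual samples).  A site must be
covered by ≥ 10 reads in both samples; each sample's methylation fraction
must fall outside the other's exact 95% Clopper–Pearson interval (the
equal-tailed beta-quantile inversion of the binomial tails); and the
absolute difference must exceed 50%.  This is the strain screen (parent vs
parent) and the epimutation screen (parent vs the genotype-matched F1
chromosome).

**Pooled-variance two-group t-test** (per-sample or per-allele methylation
fractions).  The pooled (not Welch) form is used, matching the numerical
environment the thresholds were calibrated with; group means, the absolute
difference (delta), and a two-sided p from t with n_a+n_b−2 df are
reported.  Zero pooled variance with equal means gives p = 1; with unequal
means the separation is infinitely strong and p is reported as 0 and
flagged in the log.  Presets:

| screen     | groups                      | p cutoff | delta cutoff |
|------------|-----------------------------|----------|--------------|
| allele     | B6 vs DBA haplotypes (8 units) | 0.05   | 0.50 |
| sex        | females vs males (all 8 animals) | 0.001 | 0.20 |
| imprinting | maternal vs paternal haplotypes | 1e-6  | —    |

Sites with fewer than `min_group_size` (default 3) covered replicates in
either group are skipped and counted.  Multiple testing is handled by the
fixed thresholds plus simulation-based FDR, never per-site correction —
the thresholds *are* the procedure being calibrated.

## Simulation-based FDR (x/y)

For a screen applied to count matrices (sites × compared units), every
methylated count is replaced by a Binomial(n_unit, p_pooled) draw, where
p_pooled is the site's methylation level pooled across the compared units —
the natural no-difference null that preserves the coverage pattern.  The
screen is re-run on each of `n_sims` replicates (default 1,000 for t-test
screens); the FDR is the mean null significant count x over the observed
count y, undefined (an error) when y = 0.  x as a mean is chosen over a
single draw; `n_sims=1` reproduces the single-draw reading.

The package's standing calibrations (in `methcross.calibration`, recomputed
by `scripts/acceptance.py`) plant realistic effect blocks over large null
backgrounds and verify the documented bounds: pairwise criterion < 1%
(10,000 null + 500 true sites, differences 0.6–0.9, coverage 10–100);
allele screen < 0.05% (5,000 sites, 8 fractions per group, 5% planted at
≥ 0.6, 1,000 resamplings); sex screen < 5% (4 vs 4, 2% planted at ≥ 0.4,
200 resamplings).

Storey q-values use pi0 = min(1, mean(p > λ)/(1−λ)) with λ fixed at 0.5
(exposed as a parameter); q is the monotone envelope of pi0·m·p/rank.
Enrichment p-values are exact upper-tail hypergeometric sums.

## Epimutation detection

An intergenerational epimutation is a site where a parent's methylation
differs from the *same-genotype* chromosome in its offspring — B6 parent vs
the B6 haplotype of an F1, DBA parent vs the DBA haplotype.  Each pair is
tested with the pairwise binomial criterion (delta > 50%); sites inside
known imprinted genes are excluded, since imprinting produces exactly this
parent-vs-single-haplotype signature.  Pairs are restricted to same-sex
parent–offspring comparisons when sex labels are available: without this,
every sex-specific site is mis-called as a reproducible epimutation (the
parent and the F1 differ because of sex, not generation).  Reproducibility
classes count direction-consistent significant pairs per site: present in
≥ 1 or ≥ 2 comparisons; direction consistency is required.

## AMR scan

The AMR model asks whether reads in a fixed-width window of w = 10
consecutive CpGs segregate into two distinct methylation patterns.  The
single-pattern model fits one Bernoulli level per CpG (maximum likelihood,
clamped to [1e-3, 1−1e-3]); the two-pattern model is an equal-weight (0.5 /
0.5, two chromosomes per cell) mixture over reads with per-CpG Bernoulli
emissions, fitted by EM with fractional read responsibilities.  One EM
start duplicates the single-pattern fit — an EM fixed point whose
likelihood equals the one-pattern model, so the likelihood-ratio statistic
can never be negative — one perturbs it symmetrically (±0.1), and further
starts are random.  The LRT 2(logL₂ − logL₁) is referred to chi-square with
w degrees of freedom; this reference is approximate at a mixture boundary,
and a permutation alternative (shuffling states within CpG columns, which
preserves per-CpG levels while destroying read-level phase) is provided for
calibration.  A window is significant at p < 0.01 with mean absolute
profile difference > 50%; overlapping significant windows merge into
maximal regions (≥ 10 CpGs by construction).

The genome scan slides one CpG at a time and uses lighter optimizer
settings (deterministic inits plus two random starts, tolerance 1e-6, 100
iterations) than the standalone EM defaults (five starts, 1e-8, 200): the
LRT only needs resolving against the 0.01 threshold, and the full-polish
settings cost ~25× more time for identical calls on this data.

**Candidate imprinted regions** are AMR clusters (any-overlap linkage
across samples) present in ≥ 6 of the 8 animals *including at least one
parent and one F1*.  Parental presence is the imprinting filter: inbred
parents carry two genotypically identical chromosomes, so a parental AMR
cannot be genotype-driven allele-specific methylation.

## Expression validation screens

Allelic RNA-seq counts are tested per gene with a two-sided Fisher's exact
test on the 2×2 table cross direction × allele genotype, after a ≥ 10 total
count filter.  A significant test alone cannot distinguish imprinting from
a cis-genotype effect; the reported `parental_origin` flag requires the
allelic skew to flip between cross directions (maternal allele is B6 in
BXD but DBA in DXB).  Both the plain p < 0.05 call and a Storey-FDR < 5%
with maternal/paternal fold > 1.2 variant are reported.  The sex
differential-expression screen applies row-wise pooled t-tests to a genes ×
samples matrix, Storey q-values, and a linear-scale fold filter (> 1.2);
fold is computed on linear means as no log transform is specified for the
validation data this mirrors.

## Synthetic data generator

The generator is first-class, tested code and the package's acceptance
surface.  It emulates:

- **Haplotypes.** Random-sequence regions (default 12 regions × 2 kb,
  ~1,500 CpGs) shared by both strains; the DBA haplotype differs at planted
  SNPs.  Clean SNPs are A/T substitutions (never inside a CpG, never a
  bisulfite confound); 10% of SNPs are planted as C/T at non-CpG cytosines
  with the cytosine treated as half-methylated, so pooled counts present a
  genuine C/T candidate the caller must refuse.  The default SNP density
  (0.008/bp over eligible bases) keeps a workable fraction of reads
  genotype-informative at desk scale (~35–40%, vs ~5% genome-wide in real
  B6×DBA RRBS).
- **Methylation baselines.** CG levels are drawn from a two-component Beta
  mixture — a mostly-unmethylated island-like component Beta(0.5, 10) and a
  methylated component Beta(10, 2.5) — weighted to give the 48.39%
  genome-wide CG mean; CHG/CHH sites use near-zero Beta baselines (means
  0.71% / 0.75%).  A per-sample logit-normal shift (s.d. 0.05) emulates
  biological replicate dispersion; it is a knob, not a claimed estimate.
- **Planted effects.** Disjoint sets of strain-specific CpGs (default
  levels 0.9/0.1, delta 0.8), sex-specific CpGs (delta 0.7), imprinted
  regions of ≥ 12 consecutive CpGs expressing the maternal level on the
  maternal allele in *both* cross directions (genotype-independent by
  construction, default 0.95/0.05), and rare epimutations: one F1
  chromosome shifted from 0.05 to 0.90 in one or two F1 animals.
- **Reads.** Fixed-width windows of 6 consecutive CpGs; per-CpG states are
  Bernoulli at the level implied by (allele strain, sex, parental origin,
  epimutation status), flipped with the combined error/non-conversion
  probability (default 1%); coverage is Poisson with mean 60 per CpG.  Each
  read records its haplotype base (with the same error rate) at every SNP
  in its footprint, and carries the true haplotype in a hidden channel that
  is never serialized — it exists only for concordance scoring.

Not emulated: MspI fragment size selection (coverage is modelled directly),
minus-strand reads, quality scores, PCR duplicates, chromosome-scale
genomes, and realistic linkage between CpG density and methylation.
Passing recovery tests therefore demonstrate the statistical machinery
under the study's stated coverage/noise conditions, not robustness to
alignment artefacts or genome-scale structure.

## Problem sizes and determinism

The default end-to-end synthetic analysis (12 regions, ~1,500 CpGs, eight
samples, 1,000-replicate FDR calibration, full AMR scan) completes in
about 4 minutes on one CPU; the test suite uses smaller configurations of
the same generator (3–6 regions).  Every stochastic stage takes an explicit
seed, and a fixed configuration reproduces byte-identical outputs; the
pipeline derives per-stage seeds from the run seed via seed sequences.

## Known limitations

- The chi-square reference for the AMR LRT is anti-conservative in theory
  at the mixture boundary; with the delta > 50% filter this does not
  surface in calibration, but the permutation p is the safer choice for
  borderline regions.
- The imprinting t-test screen is power-limited by per-allele coverage and
  the 1e-6 threshold: with only 3 usable units per group the threshold is
  unreachable in principle (df = 4), mirroring the low yield of the
  SNP-restricted approach the AMR scan exists to overcome.
- Storey pi0 is unstable below ~10 tests; the imprinting expression screen
  reports q = NaN in that regime rather than a misleading estimate.
- The epimutation reproducibility classes depend on which parent–F1 pairs
  are covered; with same-sex pairing a single-animal epimutation can appear
  in at most two pairs (one per parent of that sex and strain — i.e. one).
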