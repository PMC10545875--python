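# Methods

## Scope and model

`pgtlink` analyses a nuclear family segregating a single heterozygous
autosomal-dominant variant carried by the mother (default locus
chr14:65,271,654, the *SPTB* splice variant scenario). Five coupled
models are implemented: Mendelian phasing through a reference embryo,
vote-based embryo haplotype deduction under allele dropout, a linear
mixture model for mosaic aneuploidy in binned coverage, relative
haplotype dosage with a sequential test for cfDNA, and alignment-based
transcript deletion calling. All stages assume biallelic SNPs,
diploid autosomal inheritance and a single variant locus; X-linked
logic, compound heterozygosity and segmental CNVs are out of scope.

## Phasing

Informative sites are those where exactly one parent is heterozygous.
With the father homozygous, his gamete allele is forced, so the
reference embryo's genotype minus that allele is the transmitted
maternal allele; the maternal haplotypes are then labelled M1 (risk)
or M2 by the reference embryo's known carrier status at the variant.
Both-heterozygous sites are excluded entirely — no statistical or
population phasing is attempted, so phasing is exact or absent per
site. Sites whose reference genotype is missing or impossible given
the parents are categorized but left unphased. An unknown reference
carrier status is a hard error: without it the risk haplotype cannot
be anchored.

The analysis window defaults to ±2 Mb around the variant (4 Mb
total). At least one phased maternal site is required on each flank;
fewer than 5 per flank triggers a warning, reflecting the operating
minimum at which the vote aggregation below still tolerates one
corrupted call.

## Embryo diagnosis

Per informative phased site, the forced paternal allele is subtracted
from the biopsy genotype and the remainder matched to M1/M2. A
genotype lacking the paternal allele is explicable only by a single
paternal-allele dropout and becomes ADO_SUSPECT (no vote); genotypes
impossible under any one-dropout explanation are INCONSISTENT.

Aggregation parameters (CLI-configurable):

| parameter | default | rationale |
|---|---|---|
| min_support_per_flank | 3 | one corrupted vote can never flip a 3-vote flank |
| max_minority_fraction | 0.15 | tolerates a single stray vote in flanks up to ~7 sites |

The decision cascade is: (1) if the ordered M1/M2 votes split into
exactly two pure runs, each with at least `min_support_per_flank`
votes, the embryo is RECOMBINANT and the breakpoint is reported as the
genomic interval between the two adjacent discordant calls — this
detects and localizes a crossover anywhere in the window, not only at
the variant; (2) otherwise each flank votes by majority, requiring
support and purity, and agreeing flanks give the haplotype while
cleanly disagreeing flanks give RECOMBINANT; (3) if one flank fails
purity without a clean changepoint, both flanks are pooled under the
same purity bound (support ≥ 2·min_support). The pooled fallback
exists because scattered dropout-flipped votes — each arising with
probability ado/2 at a truly heterozygous site — reach two per flank
far more often than they could ever threaten the window-wide
majority; binomially, an 11-vote flank is contaminated twice in ~3%
of embryos at 10% ADO, while flipping a 22-vote window would take
eleven. Without pooling those embryos would be discarded as no-calls.

The final status requires concordance between linkage and the direct
variant genotype: M1 + variant present → carrier, M2 + variant absent
→ non-carrier, any discordance → no-call (conservative: possible ADO
at the variant site or unrecognized recombination). A missing direct
test falls back to linkage alone, flagged lower-confidence. A trisomy
call covering the variant chromosome forces no-call, since diploid
origin-calling assumptions break. For a recombinant embryo the
variant-proximal block decides risk; when the variant falls inside
the breakpoint interval itself the nearer block is used and the
ambiguity remains visible in the reported interval.

## CNV and mosaicism

Counts are Poisson-distributed per bin. Each chromosome's mean copy
ratio is taken against a leave-one-out baseline — the median count of
all other chromosomes' non-zero bins — so an aneuploid chromosome
cannot inflate its own diploid reference (with few chromosomes a
genome-wide median is visibly biased by the trisomic bins). The
mixture inversion m = 2|r−1| (clipped to [0,1]) follows from a biopsy
in which a fraction m of cells carries three copies: mean copy number
2+m, ratio (2+m)/2. Deviations |r−1| < 0.05 (m < 0.1) are treated as
noise with direction "none" — half the euploid class bound, so the
noise floor can never reclassify a chromosome. Class bounds m < 0.2
euploid, 0.2–0.8 mosaic, > 0.8 full aneuploid follow common PGT-A
reporting convention. Whole-chromosome aggregation only; no
segmentation and no GC correction (the simulator is GC-neutral; a
per-bin covariate hook would slot into `normalize_counts`).

## NIPT-M

Plasma is modelled as a two-genome mixture: expected alt fraction
(1−ff)·g_m/2 + ff·g_f/2 with g the parental/fetal alt-allele counts.
Sequencing error e flips each read with probability e, attenuating
every expectation as p(1−2e)+e. Estimators:

- e: pooled alt fraction at sites where both parents are hom-ref
  (every alt read is an error).
- ff: at sites with mother hom-ref and father hom-alt the fetus is an
  obligate heterozygote, so ff = 2·(mean VAF − e)/(1−2e) — the exact
  inverse of the error-attenuated expectation ff/2·(1−2e)+e.

The RHDO decision is a Wald SPRT per block of at most 100 contiguous
informative sites: cumulative log-likelihood ratio of
Binom(depth, p_M1) against Binom(depth, p_M2), stopping at
log((1−β)/α) or log(β/(1−α)) with α = β = 1e−4. At ff = 0.10 and
depth 100 the mean per-site increment is ≈0.5, so decisions typically
arrive within ~20 sites; α, β and the block size are CLI flags. The
fetal status follows the variant-proximal block; other blocks serve
as a consistency check only. Only the maternal haplotype is tested
(the variant is maternal); the dosage machinery is symmetric and
would serve the paternal side unchanged.

## Transcript comparison

Global alignment with match 0, mismatch −1 and gap −1 per base; gap
opening carries a 0.01 surcharge purely to break ties among
equal-cost alignments toward one contiguous gap. A single contiguous
gap in the observed sequence is a deletion; its placement inside a
repeat is ambiguous, so the reported interval is the 3'-most member
of the equivalence class (HGVS recommendation) and the full class is
returned alongside. Frame class is length mod 3. Coordinates are
1-based on the provided CDS; genomic-to-CDS projection and intron
structure are not modelled, and the caller never silently adjusts an
interval to a neighbouring exon boundary.

## Synthetic data

The generator emulates: chip-like biallelic SNPs with alt frequencies
uniform on the configured range (default 0.1–0.5) and Hardy–Weinberg
founders; a forced variant site (mother het on M1, father hom-ref);
embryos inheriting one haplotype per parent with crossovers at
explicit breakpoints (placed, not drawn from a rate, so tests can
position a switch deterministically); ADO rendering truly
heterozygous biopsy calls homozygous with probability `ado_rate`
(dropped allele uniform) plus independent random-genotype errors;
Poisson low-pass coverage over a scaled-down genome of 5 equal
100 Mb autosomes — at the default 1000 bins that is 200 bins per
chromosome, sized so the mosaic-fraction estimator's standard error
(2·sqrt(λ/n_bins)/baseline on the m scale, plus the leave-one-out
baseline's median noise) stays near 0.017, i.e. ±0.05 is ≈3 standard
errors; and binomial cfDNA depths at the mixture expectation.

Defaults: 200 SNPs in the window, 5 embryos plus one reference
embryo, ado_rate 0.05 (WGA-typical; the scenario's source material
reports no measured rate), genotype_error_rate 0.002, fetal fraction
0.10 with depth 100 (typical first-trimester targeted panel),
cfdna_error_rate 0.002. Each operation draws from its own stream
seeded from (seed, operation tag), so identical seeds are
reproducible bitwise and adding stages never perturbs earlier
outputs.

Not emulated: linkage disequilibrium (sites are independent given
frequencies), GC and mappability structure, read-level artifacts,
segmental CNVs, sex chromosomes, maternal somatic CNVs in plasma.
Passing tests therefore demonstrate the inference logic under the
stated noise models, not robustness to real-chip batch effects or
capture bias.

## Numerical and degenerate-input conventions

Variant coordinates are 1-based inclusive; coverage bins 0-based
half-open. Missing genotypes are "NC" (TSV) / "./." (VCF). Zero-count
bins are masked, fully-masked chromosomes yield no call (with a
warning) rather than a fabricated one. Ties in flank votes
(n_M1 = n_M2) are never broken — the flank abstains. SPRT blocks with
ff = 0 are undecidable by construction (the two hypotheses coincide).
Distributional tests use fixed seeds and 3-sigma tolerances; recovery
suites state their replicate counts in the test docstrings.

## Known limitations

- One reference embryo only; two-proband consistency phasing is not
  implemented.
- The recombination model detects at most one clean switch per
  embryo; double crossovers inside the window degrade to no-call.
- Mosaic fraction is meaningful only for whole-chromosome events; a
  segmental event dilutes into the chromosome mean.
- The NIPT-M consistency check across blocks is reported, not
  enforced; clinical use would require a confirmation policy.
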