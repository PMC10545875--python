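# pgtlink

SNP-linkage analysis for preimplantation genetic testing of monogenic
disease (PGT-M) and its noninvasive prenatal follow-up (NIPT-M).

## The problem

A couple carries a dominant pathogenic variant — here modelled on a
maternal heterozygous splice variant in *SPTB* (hereditary
spherocytosis) at chr14:65,271,654 — and undergoes IVF with embryo
biopsy. Direct genotyping of whole-genome-amplified biopsy cells is
unreliable because of allele dropout (ADO): a heterozygous site can
look homozygous when one allele fails to amplify. The standard
safeguard is linkage: phase the parents' haplotypes over informative
SNPs flanking the variant, determine which maternal haplotype each
embryo inherited, and require the linkage result and the direct
variant test to agree. After transfer, the same phased haplotypes let
a maternal plasma cfDNA sample predict the fetal genotype without
amniocentesis.

`pgtlink` implements that workflow end to end for analysts building or
validating such pipelines, together with a synthetic-family generator
so every stage can be exercised and benchmarked without any patient
data.

## What it computes

- **Phasing (`haplotyping`)** — at sites where the mother is
  heterozygous and the father homozygous, the reference embryo (a
  non-transferable "waste" embryo of known carrier status) reveals the
  transmitted maternal allele by Mendelian subtraction. The maternal
  haplotype carrying the variant is labelled M1 (risk), the other M2.
- **Embryo diagnosis (`embryo_pgt`)** — per-site origin calls
  (M1/M2/ADO-suspect), flank-wise majority voting around the variant
  with recombination-breakpoint localization, and a final status that
  must be concordant with the direct variant genotype.
- **CNV/mosaicism (`cnv_mosaic`)** — per-chromosome mean copy ratio r
  from binned low-pass read counts; a mosaic trisomy of cell fraction
  m gives r = (2+m)/2, inverted as m = 2(r−1) (gains) or 2(1−r)
  (losses), classed euploid / mosaic / full aneuploid at m = 0.2/0.8.
- **NIPT-M (`nipt_m`)** — relative haplotype dosage: at informative
  sites the plasma alt fraction is 1/2 ± ff/2 depending on the
  transmitted maternal haplotype (ff = fetal fraction, estimated from
  paternal-specific alleles; sequencing error estimated from
  double-hom-ref sites). A sequential probability ratio test on the
  cumulative binomial log-likelihood ratio decides M1 vs M2
  transmission per block of sites.
- **Splice verification (`transcript_compare`)** — global alignment of
  an observed transcript against the reference CDS, calling deletions
  in HGVS c. coordinates (3'-normalized) with frame classification.
- **Simulation (`simulate`)** — Hardy–Weinberg founders, explicit
  recombination breakpoints, ADO and genotyping error in biopsies,
  Poisson low-pass coverage with mosaic trisomies, binomial cfDNA
  mixtures at a stated fetal fraction.

## Worked example

```sh
pgtlink demo --seed 0 --out-dir demo_out
```

runs the whole chain on a synthetic five-embryo family (one carrier
embryo, two mosaic trisomies, maternal plasma at 10% fetal fraction)
and prints:

```
INFO [pgtlink] [simulate] wrote family with 201 SNPs, 5 embryos to demo_out
INFO [pgtlink] [phase] 56 maternal sites phased
INFO [pgtlink] [pgt] E01: haplotype=M2 direct=variant_absent -> non_carrier
INFO [pgtlink] [pgt] E02: haplotype=M2 direct=variant_absent -> non_carrier
INFO [pgtlink] [pgt] E03: haplotype=M2 direct=variant_absent -> non_carrier
INFO [pgtlink] [pgt] E04: haplotype=M1 direct=variant_present -> carrier
INFO [pgtlink] [pgt] E05: haplotype=M2 direct=variant_absent -> non_carrier
INFO [pgtlink] [cnv] abnormal karyotype; abnormal: ['chr3']
INFO [pgtlink] [cnv] abnormal karyotype; abnormal: ['chr5']
INFO [pgtlink] [nipt] e=0.001591 ff=0.108 -> non_carrier
INFO [pgtlink] [splice] c.279_299del (21 bases, in_frame)
```

Reading the output: 56 informative SNPs in the ±2 Mb window were
phased through the reference embryo; embryo E04 inherited the risk
haplotype M1 and the direct test confirms the variant (carrier), the
other four inherited M2 and are non-carriers; E01 and E03 carry
mosaic trisomies (chr3, chr5 of the simulated genome) on top of their
linkage results; the plasma sample (estimated sequencing error 0.16%,
fetal fraction 10.8%) shows M2 transmission, so the fetus is predicted
disease-free; and the transcript stage calls the 21-base in-frame
deletion `c.279_299del` produced by the simulated cryptic splice site.

Each stage is also available separately (`pgtlink simulate | phase |
pgt | cnv | nipt | splice`) on the documented TSV/VCF/FASTA formats,
with a JSON manifest of checksums, parameters and seed per stage.

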