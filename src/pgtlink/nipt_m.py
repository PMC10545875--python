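"""Noninvasive fetal haplotype prediction from maternal plasma cfDNA.

Relative haplotype dosage (RHDO): at SNPs where the mother is
heterozygous and the father homozygous, the plasma alt-allele fraction
is shifted by +-ff/2 (ff = fetal fraction) depending on which maternal
haplotype the fetus inherited. Sites are scanned in genomic order and
a sequential probability ratio test (SPRT) on the cumulative binomial
log-likelihood ratio decides between "M1 transmitted" (fetus carries
the risk haplotype) and "M2 transmitted". The sequencing error rate e
is estimated from sites where both parents are homozygous reference,
the fetal fraction from paternal-specific alleles (mother hom-ref,
father hom-alt, fetus obligate heterozygote), and e attenuates every
expected fraction as p(1-2e) + e.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom

from .genotype_io import GenotypeMatrix, Pedigree, HOM_REF, HET, HOM_ALT
from .haplotyping import ParentalHaplotypes


class NiptError(ValueError):
    """Raised when a required site class is absent from the cfDNA table."""


@dataclass
class SprtParams:
    alpha: float = 1e-4
    beta: float = 1e-4
    block_size: int = 100   # max informative sites per SPRT block

    @property
    def upper_bound(self) -> float:
        return math.log((1.0 - self.beta) / self.alpha)

    @property
    def lower_bound(self) -> float:
        return math.log(self.beta / (1.0 - self.alpha))


@dataclass
class BlockDecision:
    start_pos: int
    end_pos: int
    n_sites: int
    n_sites_used: int       # sites consumed before the LLR crossed a bound
    llr: float
    decision: str           # M1_transmitted / M2_transmitted / undecided
    contains_variant: bool = False


@dataclass
class FetalCall:
    error_rate: float
    fetal_fraction: float
    blocks: list[BlockDecision] = field(default_factory=list)
    final_status: str = "no_call"   # carrier / non_carrier / no_call
    consistent_flanks: bool | None = None


def estimate_error_rate(table: pd.DataFrame) -> float:
    """Sequencing error rate from sites where both parents are hom-ref.

    Every alt read at such a site is an error (the fetus is obligate
    hom-ref too, bar de novo events): e = sum(alt)/sum(alt + ref).
    """
    sel = table[(table["mother_gt"] == HOM_REF) & (table["father_gt"] == HOM_REF)]
    if len(sel) == 0:
        raise NiptError("no sites with both parents homozygous reference")
    total = float((sel["ref_depth"] + sel["alt_depth"]).sum())
    if total == 0:
        raise NiptError("zero depth at error-rate sites")
    return float(sel["alt_depth"].sum()) / total


def estimate_fetal_fraction(table: pd.DataFrame, error_rate: float = 0.0) -> float:
    """Fetal fraction from paternal-specific alleles.

    At sites where the mother is hom-ref and the father hom-alt the
    fetus is an obligate heterozygote, so the expected plasma alt
    fraction is ff/2 (attenuated by sequencing error): ff is twice the
    mean alt fraction after inverting the error model.
    """
    sel = table[(table["mother_gt"] == HOM_REF) & (table["father_gt"] == HOM_ALT)]
    sel = sel[(sel["ref_depth"] + sel["alt_depth"]) > 0]
    if len(sel) == 0:
        raise NiptError("no sites with mother hom-ref and father hom-alt")
    vaf = (sel["alt_depth"] / (sel["ref_depth"] + sel["alt_depth"])).mean()
    ff = 2.0 * (float(vaf) - error_rate) / (1.0 - 2.0 * error_rate)
    return float(np.clip(ff, 0.0, 1.0))


def site_dosage_expectation(maternal_transmitted_allele: int,
                            father_allele: int, ff: float,
                            error_rate: float = 0.0) -> float:
    """Expected plasma alt fraction at a maternal-informative site.

    Mother is heterozygous (plasma background 1/2); the fetal genotype
    is the transmitted maternal allele plus the father's homozygous
    allele. Linear in ff and exactly 1/2 at ff = 0, where transmission
    carries no dosage information.
    """
    g_fetus = maternal_transmitted_allele + father_allele
    p = (1.0 - ff) * 0.5 + ff * g_fetus / 2.0
    return p * (1.0 - 2.0 * error_rate) + error_rate


def sprt_classify_block(block: pd.DataFrame, ff: float,
                        params: SprtParams | None = None,
                        error_rate: float = 0.0) -> BlockDecision:
    """Sequential test of M1- vs M2-transmission over one block.

    ``block`` rows need alt_depth, ref_depth, M1/M2 alleles (0/1 alt
    counts) and father_allele, sorted by position. The cumulative
    binomial log-likelihood ratio of the two transmission hypotheses
    is compared against the Wald bounds after each site; the scan
    stops at the first crossing.
    """
    params = params or SprtParams()
    if len(block) == 0:
        raise NiptError("empty SPRT block")
    if ff <= 0:
        return BlockDecision(int(block["pos"].min()), int(block["pos"].max()),
                             len(block), 0, 0.0, "undecided")
    llr, used, decision = 0.0, 0, "undecided"
    for row in block.itertuples():
        n = int(row.ref_depth + row.alt_depth)
        if n == 0:
            continue
        p1 = site_dosage_expectation(int(row.M1), int(row.father_allele),
                                     ff, error_rate)
        p2 = site_dosage_expectation(int(row.M2), int(row.father_allele),
                                     ff, error_rate)
        k = int(row.alt_depth)
        llr += float(binom.logpmf(k, n, p1) - binom.logpmf(k, n, p2))
        used += 1
        if llr >= params.upper_bound:
            decision = "M1_transmitted"
            break
        if llr <= params.lower_bound:
            decision = "M2_transmitted"
            break
    return BlockDecision(int(block["pos"].min()), int(block["pos"].max()),
                         len(block), used, llr, decision)


def _informative_blocks(table: pd.DataFrame, params: SprtParams) -> list[pd.DataFrame]:
    inf = table[(table["mother_gt"] == HET)
                & (table["father_gt"].isin((HOM_REF, HOM_ALT)))
                & table["M1"].notna()]
    inf = inf.sort_values("pos", kind="stable").reset_index(drop=True)
    return [inf.iloc[i:i + params.block_size]
            for i in range(0, len(inf), params.block_size)]


def diagnose_fetus(table: pd.DataFrame, variant_pos: int,
                   params: SprtParams | None = None,
                   error_rate: float | None = None,
                   fetal_fraction: float | None = None) -> FetalCall:
    """Full NIPT-M call from an annotated cfDNA table.

    ``table`` columns: chrom, pos, ref_depth, alt_depth, mother_gt,
    father_gt, M1, M2, father_allele. The window is tiled into SPRT
    blocks of contiguous informative sites; the fetal status follows
    the variant-proximal block (M1 -> carrier, M2 -> non_carrier,
    undecided -> no_call) and flanking-block agreement is reported as
    a consistency flag.
    """
    params = params or SprtParams()
    e = estimate_error_rate(table) if error_rate is None else error_rate
    ff = (estimate_fetal_fraction(table, e)
          if fetal_fraction is None else fetal_fraction)
    call = FetalCall(error_rate=e, fetal_fraction=ff)
    if ff <= 0:
        return call

    blocks = _informative_blocks(table, params)
    if not blocks:
        raise NiptError("no informative phased sites for RHDO")
    decisions = [sprt_classify_block(b, ff, params, e) for b in blocks]

    # the variant-proximal block: the one whose span contains the variant,
    # else the nearest by distance
    def dist(d: BlockDecision) -> int:
        if d.start_pos <= variant_pos <= d.end_pos:
            return -1
        return min(abs(variant_pos - d.start_pos), abs(variant_pos - d.end_pos))

    target = min(decisions, key=dist)
    target.contains_variant = True
    call.blocks = decisions
    if target.decision == "M1_transmitted":
        call.final_status = "carrier"
    elif target.decision == "M2_transmitted":
        call.final_status = "non_carrier"
    else:
        call.final_status = "no_call"
    others = [d.decision for d in decisions
              if d is not target and d.decision != "undecided"]
    call.consistent_flanks = (all(d == target.decision for d in others)
                              if others and target.decision != "undecided"
                              else None)
    return call


def annotate_cfdna_table(cfdna: pd.DataFrame, matrix: GenotypeMatrix,
                         ped: Pedigree,
                         haps: ParentalHaplotypes) -> pd.DataFrame:
    """Join plasma depths with parental genotypes and the maternal phase.

    Returns the diagnose_fetus input table; sites absent from the
    genotype matrix are dropped.
    """
    geno = pd.DataFrame({
        "chrom": [s.chrom for s in matrix.sites],
        "pos": [s.pos for s in matrix.sites],
        "mother_gt": matrix.column(ped.mother.sample_id),
        "father_gt": matrix.column(ped.father.sample_id),
    })
    out = cfdna.merge(geno, on=["chrom", "pos"], how="inner")
    phase = haps.table[["chrom", "pos", "M1", "M2"]]
    out = out.merge(phase, on=["chrom", "pos"], how="left")
    # the father's gamete allele is forced wherever he is homozygous
    out["father_allele"] = np.where(out["father_gt"] == HOM_ALT, 1,
                                    np.where(out["father_gt"] == HOM_REF, 0, -1))
    return out
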