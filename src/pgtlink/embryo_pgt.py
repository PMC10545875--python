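"""Embryo haplotype deduction and carrier diagnosis under allele dropout.

Per informative site the forced paternal allele is subtracted from the
embryo's biopsy genotype and the remaining allele matched to the
phased maternal haplotypes M1/M2. Site calls are aggregated by
flank-wise majority vote around the variant locus so that isolated
dropout or genotyping errors cannot flip a call, a discordant flank
pattern is reported as recombination with a localized breakpoint, and
the linkage result is cross-checked against the direct variant-site
genotype before the final carrier status is issued.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, Pedigree, HOM_REF, HET, HOM_ALT, MISSING
from .haplotyping import ParentalHaplotypes


class SiteOrigin(Enum):
    M1 = "M1"
    M2 = "M2"
    AMBIGUOUS = "AMBIGUOUS"
    ADO_SUSPECT = "ADO_SUSPECT"
    INCONSISTENT = "INCONSISTENT"
    NO_CALL = "NO_CALL"


class HaplotypeCall(Enum):
    M1 = "M1"
    M2 = "M2"
    RECOMBINANT = "RECOMBINANT"
    NO_CALL = "NO_CALL"


@dataclass
class AggregationParams:
    """Flank-vote thresholds; defaults let no single error flip a call."""

    min_support_per_flank: int = 3
    max_minority_fraction: float = 0.15


@dataclass
class EmbryoDiagnosis:
    embryo_id: str
    n_M1_up: int = 0
    n_M2_up: int = 0
    n_M1_down: int = 0
    n_M2_down: int = 0
    haplotype_call: str = "NO_CALL"
    variant_side_hap: str = "NO_CALL"   # haplotype of the variant-proximal block
    recombination_breakpoints: list[tuple[int, int]] = field(default_factory=list)
    direct_test: str = "missing"        # variant_present / variant_absent / missing
    concordant: bool | None = None
    final_status: str = "no_call"       # carrier / non_carrier / no_call
    reason: str = ""


def call_site_origin(embryo_gt: int, father_gt: int,
                     m1_allele: int, m2_allele: int) -> SiteOrigin:
    """Deduce which maternal haplotype an embryo shows at one site.

    Requires a phased maternal-informative site (father homozygous,
    M1/M2 alleles differ). The paternal allele is forced; an embryo
    genotype lacking it can only arise through a single paternal-allele
    dropout (ADO_SUSPECT). Genotypes impossible under any
    (haplotype, one-dropout) explanation are INCONSISTENT.
    """
    if m1_allele == m2_allele:
        raise ValueError("site not maternal-informative: M1 == M2")
    if father_gt not in (HOM_REF, HOM_ALT):
        raise ValueError("father must be homozygous at a MAT_INF site")
    if embryo_gt == MISSING:
        return SiteOrigin.NO_CALL
    paternal = 0 if father_gt == HOM_REF else 1
    remaining = embryo_gt - paternal
    if remaining == m1_allele:
        return SiteOrigin.M1
    if remaining == m2_allele:
        return SiteOrigin.M2
    # embryo genotype lacks the forced paternal allele: explicable only by
    # dropout of the paternal allele, leaving the maternal one ambiguous
    if embryo_gt in (HOM_REF, HOM_ALT):
        return SiteOrigin.ADO_SUSPECT
    return SiteOrigin.INCONSISTENT


def site_origin_calls(embryo_gt: np.ndarray, father_gt: np.ndarray,
                      phased: pd.DataFrame) -> pd.DataFrame:
    """Vectorized per-site origin calls over a phased maternal table.

    ``phased`` is ParentalHaplotypes.table; only rows with phased
    M1/M2 yield M1/M2-class calls, everything else is NO_CALL.
    """
    rows = []
    for (_, row), e_gt, f_gt in zip(phased.iterrows(), embryo_gt, father_gt):
        if pd.isna(row["M1"]) or pd.isna(row["M2"]):
            origin = SiteOrigin.NO_CALL
        else:
            origin = call_site_origin(int(e_gt), int(f_gt),
                                      int(row["M1"]), int(row["M2"]))
        rows.append({"chrom": row["chrom"], "pos": row["pos"],
                     "origin": origin.value})
    return pd.DataFrame(rows, columns=["chrom", "pos", "origin"])


def _flank_votes(calls: pd.DataFrame, variant_pos: int):
    votes = calls[calls["origin"].isin(("M1", "M2"))]
    up = votes[votes["pos"] < variant_pos]
    down = votes[votes["pos"] > variant_pos]
    return votes, up, down


def _flank_majority(flank: pd.DataFrame, params: AggregationParams):
    n1 = int((flank["origin"] == "M1").sum())
    n2 = int((flank["origin"] == "M2").sum())
    total = n1 + n2
    if total < params.min_support_per_flank or n1 == n2:
        return None, n1, n2
    minority = min(n1, n2) / total
    if minority > params.max_minority_fraction:
        return None, n1, n2
    return ("M1" if n1 > n2 else "M2"), n1, n2


def aggregate_embryo(calls: pd.DataFrame, variant_pos: int,
                     params: AggregationParams | None = None) -> EmbryoDiagnosis:
    """Aggregate ordered site-origin calls into a haplotype call.

    Majority vote runs separately on the upstream and downstream flanks
    (only M1/M2 calls count). Agreeing flanks with adequate support and
    purity give that haplotype; cleanly disagreeing flanks give
    RECOMBINANT with the breakpoint localized between the last pair of
    discordant informative sites; a within-flank haplotype switch that
    splits the ordered calls into two pure runs (each meeting the
    support minimum) is likewise RECOMBINANT; anything else is NO_CALL.
    """
    params = params or AggregationParams()
    calls = calls.sort_values("pos", kind="stable").reset_index(drop=True)
    diag = EmbryoDiagnosis(embryo_id="")
    votes, up, down = _flank_votes(calls, variant_pos)
    call_up, diag.n_M1_up, diag.n_M2_up = _flank_majority(up, params)
    call_down, diag.n_M1_down, diag.n_M2_down = _flank_majority(down, params)

    if len(votes) == 0:
        diag.reason = "zero countable M1/M2 calls"
        return diag

    # a single clean haplotype switch anywhere in the ordered calls:
    # two pure runs, each meeting the support minimum
    seq = votes["origin"].to_numpy()
    pos = votes["pos"].to_numpy()
    for k in range(1, len(seq)):
        left, right = seq[:k], seq[k:]
        if (len(set(left)) == 1 and len(set(right)) == 1
                and left[0] != right[0]
                and len(left) >= params.min_support_per_flank
                and len(right) >= params.min_support_per_flank):
            diag.haplotype_call = HaplotypeCall.RECOMBINANT.value
            diag.recombination_breakpoints = [(int(pos[k - 1]), int(pos[k]))]
            # the variant-proximal block decides carrier risk; when the
            # variant falls inside the breakpoint gap, take the nearer side
            diag.variant_side_hap = str(
                left[0] if variant_pos <= pos[k - 1] else
                right[0] if variant_pos >= pos[k] else
                (left[0] if variant_pos - pos[k - 1] <= pos[k] - variant_pos
                 else right[0]))
            return diag

    if call_up is not None and call_down is not None:
        if call_up == call_down:
            diag.haplotype_call = call_up
            diag.variant_side_hap = call_up
            return diag
        # flanks disagree with adequate support but with minority noise:
        # recombination bracketed by the last discordant pair of calls
        last_up = int(up[up["origin"] == call_up]["pos"].max())
        first_down = int(down[down["origin"] == call_down]["pos"].min())
        diag.haplotype_call = HaplotypeCall.RECOMBINANT.value
        diag.recombination_breakpoints = [(last_up, first_down)]
        diag.variant_side_hap = call_up if abs(variant_pos - last_up) <= \
            abs(first_down - variant_pos) else call_down
        return diag

    # one flank impure or undersupported and no clean switch: pool both
    # flanks under the same purity bound before giving up — scattered
    # dropout-flipped votes fail a short flank long before they endanger
    # the window-wide majority
    n1, n2 = int((seq == "M1").sum()), int((seq == "M2").sum())
    total = n1 + n2
    if total >= 2 * params.min_support_per_flank and n1 != n2 \
            and min(n1, n2) / total <= params.max_minority_fraction:
        diag.haplotype_call = "M1" if n1 > n2 else "M2"
        diag.variant_side_hap = diag.haplotype_call
        diag.reason = "pooled-window majority (one flank below purity)"
        return diag

    diag.reason = "insufficient flank support or purity"
    return diag


def diagnose_embryo(embryo_id: str, aggregated: EmbryoDiagnosis,
                    direct_test: str) -> EmbryoDiagnosis:
    """Combine the linkage haplotype call with the direct variant test.

    M1 + variant_present -> carrier; M2 + variant_absent -> non_carrier;
    any linkage/direct discordance -> no_call (possible ADO at the
    variant site or an unrecognized recombination); a missing direct
    test falls back to linkage alone, flagged lower-confidence.
    """
    d = aggregated
    d.embryo_id = embryo_id
    d.direct_test = direct_test
    linkage = d.variant_side_hap if d.haplotype_call == "RECOMBINANT" \
        else d.haplotype_call
    if linkage not in ("M1", "M2"):
        d.final_status = "no_call"
        d.concordant = None
        d.reason = d.reason or "no linkage haplotype call"
        return d
    linkage_status = "carrier" if linkage == "M1" else "non_carrier"
    if direct_test == "missing":
        d.final_status = linkage_status
        d.concordant = None
        d.reason = "direct test missing; status from linkage alone " \
                   "(lower confidence)"
        return d
    direct_status = "carrier" if direct_test == "variant_present" \
        else "non_carrier"
    d.concordant = direct_status == linkage_status
    if d.concordant:
        d.final_status = linkage_status
    else:
        d.final_status = "no_call"
        d.reason = ("linkage/direct discordance — possible ADO at variant "
                    "site or recombination")
    return d


def direct_variant_test(embryo_gt: int) -> str:
    """Direct genotype at the pathogenic variant site."""
    if embryo_gt in (HET, HOM_ALT):
        return "variant_present"
    if embryo_gt == HOM_REF:
        return "variant_absent"
    return "missing"


def diagnose_all_embryos(matrix: GenotypeMatrix, ped: Pedigree,
                         haps: ParentalHaplotypes,
                         params: AggregationParams | None = None,
                         trisomic_chroms: dict[str, set[str]] | None = None,
                         ) -> list[EmbryoDiagnosis]:
    """Run site-origin calling, aggregation and diagnosis for every embryo.

    ``trisomic_chroms`` maps embryo_id to chromosomes called trisomic
    (mosaic or full) by the CNV stage; a trisomy covering the variant
    chromosome invalidates the diploid origin-calling model and forces
    no_call for that embryo.
    """
    father = ped.father.sample_id
    phased = haps.table
    site_rows = [matrix.site_index(c, p)
                 for c, p in zip(phased["chrom"], phased["pos"])]
    father_gt = matrix.column(father)[site_rows]
    variant_idx = matrix.site_index(haps.window[0], haps.variant_pos)

    out = []
    for emb in ped.embryos:
        embryo_gt = matrix.column(emb.sample_id)[site_rows]
        calls = site_origin_calls(embryo_gt, father_gt, phased)
        agg = aggregate_embryo(calls, haps.variant_pos, params)
        direct = direct_variant_test(
            int(matrix.column(emb.sample_id)[variant_idx]))
        diag = diagnose_embryo(emb.sample_id, agg, direct)
        if trisomic_chroms and haps.window[0] in \
                trisomic_chroms.get(emb.sample_id, set()):
            diag.final_status = "no_call"
            diag.reason = ("trisomy on the variant chromosome: diploid "
                           "linkage model invalid")
        out.append(diag)
    return out
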