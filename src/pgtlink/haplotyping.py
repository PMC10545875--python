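"""Parental haplotype phasing through a reference embryo.

SNP informativeness follows the single-parent-heterozygous rule: the
maternal haplotype is phased at sites where the mother is heterozygous
and the father homozygous (and symmetrically for the father). At such
a site the reference embryo's genotype, minus the allele forced by the
homozygous parent, reveals which maternal allele was transmitted; the
transmitted haplotype is then labelled M1 (the risk haplotype) or M2
according to the reference embryo's known carrier status at the
pathogenic variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import (
    GenotypeMatrix,
    Pedigree,
    HOM_REF,
    HET,
    HOM_ALT,
    MISSING,
)


class SiteCategory(Enum):
    MAT_INF = "MAT_INF"                  # mother het, father hom
    PAT_INF = "PAT_INF"                  # father het, mother hom
    BOTH_HET = "BOTH_HET"                # both parents het: excluded from phasing
    UNINFORMATIVE = "UNINFORMATIVE"      # both parents hom
    MENDEL_INCONSISTENT = "MENDEL_INCONSISTENT"
    MISSING = "MISSING"


class PhasingError(ValueError):
    """Raised when parental phase cannot be anchored or supported."""


def _mendel_possible(mother_gt: int, father_gt: int, child_gt: int) -> bool:
    """Can (mother, father) produce child under diploid Mendelian rules?"""
    if MISSING in (mother_gt, father_gt, child_gt):
        return True
    m_alleles = {0: (0,), 1: (0, 1), 2: (1,)}
    for a in m_alleles[mother_gt]:
        for b in m_alleles[father_gt]:
            if a + b == child_gt:
                return True
    return False


def classify_sites(matrix: GenotypeMatrix, ped: Pedigree) -> list[SiteCategory]:
    """Assign each site exactly one informativeness category.

    Sites where a parental genotype is missing are MISSING; sites where
    the reference embryo's genotype is impossible given the parents are
    MENDEL_INCONSISTENT (and excluded from phasing downstream).
    """
    mother = matrix.column(ped.mother.sample_id)
    father = matrix.column(ped.father.sample_id)
    ref = (matrix.column(ped.reference_embryo.sample_id)
           if ped.reference_embryo is not None else None)

    out = []
    for i in range(matrix.n_sites):
        m, f = int(mother[i]), int(father[i])
        if m == MISSING or f == MISSING:
            out.append(SiteCategory.MISSING)
            continue
        if ref is not None and not _mendel_possible(m, f, int(ref[i])):
            out.append(SiteCategory.MENDEL_INCONSISTENT)
            continue
        if m == HET and f in (HOM_REF, HOM_ALT):
            out.append(SiteCategory.MAT_INF)
        elif f == HET and m in (HOM_REF, HOM_ALT):
            out.append(SiteCategory.PAT_INF)
        elif m == HET and f == HET:
            out.append(SiteCategory.BOTH_HET)
        else:
            out.append(SiteCategory.UNINFORMATIVE)
    return out


def phase_parent_by_reference(het_parent_gt: int, hom_parent_gt: int,
                              reference_gt: int) -> int | None:
    """Transmitted allele (0/1 alt count) of the heterozygous parent.

    At an informative site the homozygous parent forces one allele of
    the reference child; the other allele is the heterozygous parent's
    transmitted one. Returns ``None`` when the reference genotype is
    missing or incompatible with the parents (the site is then dropped
    from phasing).
    """
    if het_parent_gt != HET or hom_parent_gt not in (HOM_REF, HOM_ALT):
        raise PhasingError("phase_parent_by_reference requires an informative site")
    if reference_gt == MISSING:
        return None
    forced = 0 if hom_parent_gt == HOM_REF else 1
    remaining = reference_gt - forced
    if remaining not in (0, 1):
        return None  # e.g. father A/A but child B/B: paternal allele impossible
    return int(remaining)


@dataclass
class ParentalHaplotypes:
    """Phased parental alleles over informative sites in the window.

    ``table`` has one row per site in the window with columns
    ``chrom, pos, site_id, category, M1, M2, P1, P2`` — allele values
    are alt-allele counts (0/1) or NaN where unphased. M1 is defined
    as the maternal haplotype carrying the pathogenic variant.
    """

    table: pd.DataFrame
    window: tuple[str, int, int]
    variant_pos: int
    phase_support: int = 0
    paternal_support: int = 0
    warnings: list[str] = field(default_factory=list)

    def maternal_alleles(self) -> pd.DataFrame:
        """Rows where M1/M2 are phased."""
        return self.table.dropna(subset=["M1", "M2"])

    def write_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        for col in ("M1", "M2", "P1", "P2"):
            out[col] = out[col].map(
                lambda v: "." if pd.isna(v) else str(int(v)))
        out.to_csv(path, sep="\t", index=False)


MIN_SUPPORT_WARN = 5  # recommended operating minimum per flank


def build_parental_haplotypes(matrix: GenotypeMatrix, ped: Pedigree,
                              window_bp: int = 4_000_000,
                              variant_chrom: str | None = None,
                              variant_pos: int | None = None,
                              phase_paternal: bool = True) -> ParentalHaplotypes:
    """Phase M1/M2 (and optionally P1/P2) through the reference embryo.

    The risk haplotype M1 is anchored by the reference embryo: if it
    is a carrier its transmitted maternal haplotype is M1, otherwise
    the non-transmitted one is. Requires a reference embryo with known
    carrier status and at least one phased maternal site per flank.
    """
    ref_sample = ped.reference_embryo
    if ref_sample is None:
        raise PhasingError("no reference embryo in pedigree")
    if ref_sample.carrier_status == "unknown":
        raise PhasingError("risk haplotype unanchored: reference embryo "
                           "carrier status unknown")
    ref_is_carrier = ref_sample.carrier_status == "carrier"

    if variant_pos is None:
        idx = [i for i, s in enumerate(matrix.sites)
               if s.site_id == "pathogenic_variant"]
        if not idx:
            raise PhasingError("variant_pos not given and no site labelled "
                               "'pathogenic_variant'")
        variant_chrom = matrix.sites[idx[0]].chrom
        variant_pos = matrix.sites[idx[0]].pos
    if variant_chrom is None:
        raise PhasingError("variant_chrom required with explicit variant_pos")

    half = window_bp // 2
    window = (variant_chrom, max(1, variant_pos - half), variant_pos + half)

    categories = classify_sites(matrix, ped)
    mother = matrix.column(ped.mother.sample_id)
    father = matrix.column(ped.father.sample_id)
    ref = matrix.column(ref_sample.sample_id)

    rows = []
    for i, site in enumerate(matrix.sites):
        if site.chrom != window[0] or not window[1] <= site.pos <= window[2]:
            continue
        cat = categories[i]
        row = {"chrom": site.chrom, "pos": site.pos, "site_id": site.site_id,
               "category": cat.value, "M1": np.nan, "M2": np.nan,
               "P1": np.nan, "P2": np.nan}
        if cat is SiteCategory.MAT_INF:
            t = phase_parent_by_reference(int(mother[i]), int(father[i]),
                                          int(ref[i]))
            if t is not None:
                # transmitted allele t, untransmitted 1-t; label by carrier status
                row["M1"], row["M2"] = (t, 1 - t) if ref_is_carrier else (1 - t, t)
        elif cat is SiteCategory.PAT_INF and phase_paternal:
            t = phase_parent_by_reference(int(father[i]), int(mother[i]),
                                          int(ref[i]))
            if t is not None:
                row["P1"], row["P2"] = (t, 1 - t) if ref_is_carrier else (1 - t, t)
        rows.append(row)

    table = pd.DataFrame(rows, columns=["chrom", "pos", "site_id", "category",
                                        "M1", "M2", "P1", "P2"])
    phased = table.dropna(subset=["M1"])
    n_up = int((phased["pos"] < variant_pos).sum())
    n_down = int((phased["pos"] > variant_pos).sum())
    # the variant site itself (mother het, father hom-ref) counts as phased
    # but sits on neither flank
    if len(phased) == 0:
        raise PhasingError("zero informative maternal sites phased in window")
    warns = []
    for flank, n in (("upstream", n_up), ("downstream", n_down)):
        if n < 1:
            raise PhasingError(f"no phased maternal site on the {flank} flank")
        if n < MIN_SUPPORT_WARN:
            warns.append(f"only {n} phased maternal sites on the {flank} flank "
                         f"(recommended >= {MIN_SUPPORT_WARN})")
    return ParentalHaplotypes(
        table=table, window=window, variant_pos=variant_pos,
        phase_support=int(len(phased)),
        paternal_support=int(table["P1"].notna().sum()),
        warnings=warns)
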