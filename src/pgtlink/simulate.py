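"""Synthetic nuclear-family data with the statistical structure PGT-M assumes.

The generator emulates a family segregating a maternal heterozygous
autosomal-dominant variant (default locus chr14:65,271,654): founder
haplotypes are drawn under Hardy-Weinberg from per-site allele
frequencies, embryos inherit one haplotype per parent with optional
explicit recombination breakpoints, biopsy genotypes are corrupted by
allele dropout (ADO) and random genotyping error, low-pass coverage is
Poisson with mosaic-trisomy inflation, and maternal plasma allele
depths are binomial mixtures of maternal and fetal genotypes at a
stated fetal fraction.

Each operation draws from its own pseudo-random stream seeded from
(seed, operation tag), so adding downstream stages never perturbs
earlier outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import zlib

import numpy as np
import pandas as pd

from .genotype_io import (
    GenotypeMatrix,
    Pedigree,
    PedigreeSample,
    VariantSite,
    HET,
)

# operation tags for the per-operation random streams
_TAG_FAMILY, _TAG_BIOPSY, _TAG_LOWPASS, _TAG_CFDNA = 11, 23, 37, 53

# Scaled-down genome for low-pass coverage: 5 equal-length autosomes.
# At the default 1000 bins this gives 200 bins per chromosome, enough
# for the per-chromosome copy-ratio mean to resolve a mosaic fraction
# to +-0.05 at ~3 standard errors with 100 reads per bin.
SIM_AUTOSOMES = tuple(f"chr{i}" for i in range(1, 6))
SIM_CHROM_LENGTH = 100_000_000

MATERNAL_HAPS = ("M1", "M2")
PATERNAL_HAPS = ("P1", "P2")


@dataclass(frozen=True)
class EmbryoTruth:
    """True inheritance of one conceptus.

    ``recombination_breakpoints`` are bp positions of maternal
    crossovers inside the SNP window: the transmitted maternal
    haplotype switches at each breakpoint, starting from
    ``maternal_hap`` at the left edge. ``trisomy`` is an optional
    (chrom, mosaic fraction) whole-chromosome gain.
    """

    maternal_hap: str = "M1"
    paternal_hap: str = "P1"
    recombination_breakpoints: tuple[int, ...] = ()
    trisomy: tuple[str, float] | None = None

    def __post_init__(self):
        if self.maternal_hap not in MATERNAL_HAPS:
            raise ValueError(f"maternal_hap must be M1/M2, got {self.maternal_hap}")
        if self.paternal_hap not in PATERNAL_HAPS:
            raise ValueError(f"paternal_hap must be P1/P2, got {self.paternal_hap}")
        if self.trisomy is not None and not 0.0 <= self.trisomy[1] <= 1.0:
            raise ValueError("mosaic fraction must be in [0, 1]")


@dataclass
class SimulationConfig:
    """Parameters of one synthetic PGT-M family.

    Defaults mirror the clinical scenario the pipeline targets: a
    4 Mb SNP window centred on the pathogenic variant, chip-like
    common SNPs, five blastocysts plus one non-transferable reference
    embryo, WGA-level allele dropout, and a first-trimester plasma
    sample.
    """

    seed: int = 0
    n_snps: int = 200
    window_bp: int = 4_000_000
    variant_chrom: str = "chr14"
    variant_pos: int = 65_271_654
    maf_range: tuple[float, float] = (0.1, 0.5)
    n_embryos: int = 5
    embryo_truth: Sequence[EmbryoTruth] | None = None
    reference_truth: EmbryoTruth = field(
        default_factory=lambda: EmbryoTruth("M1", "P1"))
    fetus_truth: EmbryoTruth = field(
        default_factory=lambda: EmbryoTruth("M2", "P2"))
    ado_rate: float = 0.05
    genotype_error_rate: float = 0.002
    n_bins: int = 1000
    mean_reads_per_bin: float = 100.0
    fetal_fraction: float = 0.10
    cfdna_depth: int = 100
    cfdna_error_rate: float = 0.002

    def __post_init__(self):
        if self.n_snps <= 0:
            raise ValueError("n_snps must be positive")
        for name in ("ado_rate", "genotype_error_rate", "cfdna_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if not 0.0 < self.fetal_fraction < 1.0:
            raise ValueError("fetal_fraction must be in (0, 1)")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        half = self.window_bp // 2
        if not (self.variant_pos - half < self.variant_pos
                < self.variant_pos + half + 1):
            raise ValueError("variant_pos must lie inside the window")
        if self.embryo_truth is not None and len(self.embryo_truth) != self.n_embryos:
            raise ValueError("embryo_truth length must equal n_embryos")

    @property
    def window(self) -> tuple[str, int, int]:
        half = self.window_bp // 2
        return (self.variant_chrom, max(1, self.variant_pos - half),
                self.variant_pos + half)


@dataclass
class FamilyTruth:
    """Error-free ground truth: phased founders and true inheritance."""

    sites: list[VariantSite]
    allele_freqs: np.ndarray          # alt-allele frequency per site
    maternal: dict[str, np.ndarray]   # "M1"/"M2" -> 0/1 allele vectors
    paternal: dict[str, np.ndarray]   # "P1"/"P2"
    embryos: dict[str, EmbryoTruth]   # includes the reference embryo
    fetus: EmbryoTruth
    variant_index: int
    window: tuple[str, int, int]

    @property
    def variant_site(self) -> VariantSite:
        return self.sites[self.variant_index]

    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)

    def maternal_transmitted(self, truth: EmbryoTruth) -> np.ndarray:
        """Per-site transmitted maternal allele, applying crossovers."""
        pos = self.positions()
        start = MATERNAL_HAPS.index(truth.maternal_hap)
        flips = np.zeros(len(pos), dtype=np.int64)
        for bp in truth.recombination_breakpoints:
            flips += pos > bp
        which = (start + flips) % 2
        stacked = np.stack([self.maternal["M1"], self.maternal["M2"]])
        return stacked[which, np.arange(len(pos))]

    def paternal_transmitted(self, truth: EmbryoTruth) -> np.ndarray:
        return self.paternal[truth.paternal_hap].copy()

    def child_genotypes(self, truth: EmbryoTruth) -> np.ndarray:
        """Noise-free diploid genotype codes (alt-allele counts)."""
        return (self.maternal_transmitted(truth)
                + self.paternal_transmitted(truth)).astype(np.int8)

    def parent_genotypes(self, who: str) -> np.ndarray:
        haps = self.maternal if who == "mother" else self.paternal
        a, b = haps.values()
        return (a + b).astype(np.int8)

    def is_carrier(self, truth: EmbryoTruth) -> bool:
        """Variant allele present, i.e. M1 transmitted at the variant locus."""
        return bool(self.maternal_transmitted(truth)[self.variant_index] == 1)


def _rng(seed: int, tag: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(tag), *map(int, extra)])


def simulate_family(config: SimulationConfig) -> tuple[FamilyTruth,
                                                       GenotypeMatrix, Pedigree]:
    """Build one family: truth, (noisy) genotype matrix and pedigree.

    The matrix holds clean blood genotypes for the parents and
    biopsy-noise genotypes (ADO + genotyping error per ``config``) for
    the reference embryo and every test embryo. Sites are sorted by
    position, all biallelic; the mother is heterozygous at the variant
    site (variant on M1) and the father homozygous reference.
    """
    rng = _rng(config.seed, _TAG_FAMILY)
    chrom, win_start, win_end = config.window

    pos = np.sort(rng.choice(
        np.arange(win_start, win_end + 1), size=config.n_snps, replace=False))
    # reserve the variant locus itself as an explicit site
    pos = pos[pos != config.variant_pos]
    pos = np.sort(np.append(pos, config.variant_pos))
    n = len(pos)
    variant_index = int(np.searchsorted(pos, config.variant_pos))

    lo, hi = config.maf_range
    freqs = rng.uniform(lo, hi, size=n)

    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4

    haps = {name: (rng.random(n) < freqs).astype(np.int8)
            for name in ("M1", "M2", "P1", "P2")}
    # anchor the pathogenic variant: alt on M1 only, father hom-ref
    haps["M1"][variant_index] = 1
    haps["M2"][variant_index] = 0
    haps["P1"][variant_index] = 0
    haps["P2"][variant_index] = 0

    sites = []
    for i in range(n):
        sid = ("pathogenic_variant" if i == variant_index
               else f"rs_sim_{i:05d}")
        sites.append(VariantSite(chrom, int(pos[i]), bases[ref_idx[i]],
                                 bases[alt_idx[i]], sid))

    if config.embryo_truth is not None:
        embryo_truths = list(config.embryo_truth)
    else:
        embryo_truths = [
            EmbryoTruth(MATERNAL_HAPS[rng.integers(2)],
                        PATERNAL_HAPS[rng.integers(2)])
            for _ in range(config.n_embryos)]

    embryo_ids = [f"E{k + 1:02d}" for k in range(config.n_embryos)]
    embryos = {"REF_EMBRYO": config.reference_truth}
    embryos.update(zip(embryo_ids, embryo_truths))

    truth = FamilyTruth(
        sites=sites, allele_freqs=freqs,
        maternal={"M1": haps["M1"], "M2": haps["M2"]},
        paternal={"P1": haps["P1"], "P2": haps["P2"]},
        embryos=embryos, fetus=config.fetus_truth,
        variant_index=variant_index, window=config.window)

    sample_ids = ["FATHER", "MOTHER", "REF_EMBRYO", *embryo_ids]
    cols = [truth.parent_genotypes("father"), truth.parent_genotypes("mother")]
    for k, eid in enumerate(["REF_EMBRYO", *embryo_ids]):
        cols.append(simulate_embryo_biopsy(
            truth, eid, config.ado_rate, config.genotype_error_rate,
            seed=config.seed, _salt=k))
    matrix = GenotypeMatrix(sites, sample_ids, np.column_stack(cols))

    ref_status = "carrier" if truth.is_carrier(config.reference_truth) \
        else "non_carrier"
    ped = Pedigree([
        PedigreeSample("FATHER", "father", "non_carrier"),
        PedigreeSample("MOTHER", "mother", "carrier"),
        PedigreeSample("REF_EMBRYO", "reference_embryo", ref_status),
        *[PedigreeSample(eid, "embryo", "unknown") for eid in embryo_ids],
    ])
    return truth, matrix, ped


def simulate_embryo_biopsy(truth: FamilyTruth, embryo_id: str,
                           ado_rate: float, genotype_error_rate: float,
                           seed: int = 0, _salt: int = 0) -> np.ndarray:
    """One embryo's WGA biopsy genotypes.

    Each truly heterozygous call loses one allele uniformly with
    probability ``ado_rate`` (rendering it homozygous); independently,
    each emitted call is then replaced by a random valid genotype with
    probability ``genotype_error_rate``.
    """
    if embryo_id not in truth.embryos:
        raise KeyError(f"unknown embryo_id {embryo_id!r}")
    rng = _rng(seed, _TAG_BIOPSY, _salt, zlib.crc32(embryo_id.encode()))
    gt = truth.child_genotypes(truth.embryos[embryo_id]).copy()

    het = gt == HET
    drop = het & (rng.random(len(gt)) < ado_rate)
    # dropped heterozygote becomes hom for a uniformly chosen allele
    gt[drop] = np.where(rng.random(int(drop.sum())) < 0.5, 0, 2)

    err = rng.random(len(gt)) < genotype_error_rate
    gt[err] = rng.integers(0, 3, size=int(err.sum()))
    return gt.astype(np.int8)


def simulate_low_pass_counts(truth: FamilyTruth, embryo_id: str,
                             n_bins: int, mean_reads_per_bin: float,
                             seed: int = 0) -> pd.DataFrame:
    """Low-pass coverage: equal-width bins over 22 simulated autosomes.

    Bin counts are Poisson with mean ``mean_reads_per_bin * cn / 2``
    where a chromosome carrying a mosaic trisomy of fraction m has
    copy number 2 + m.
    """
    if n_bins <= 0:
        raise ValueError("n_bins must be positive")
    if embryo_id not in truth.embryos:
        raise KeyError(f"unknown embryo_id {embryo_id!r}")
    rng = _rng(seed, _TAG_LOWPASS, zlib.crc32(embryo_id.encode()))
    tri = truth.embryos[embryo_id].trisomy

    genome = SIM_CHROM_LENGTH * len(SIM_AUTOSOMES)
    width = genome // n_bins
    if width == 0:
        raise ValueError("more bins than simulated base pairs")
    gstart = np.arange(n_bins, dtype=np.int64) * width
    chrom_idx = np.minimum(gstart // SIM_CHROM_LENGTH, len(SIM_AUTOSOMES) - 1)
    chroms = np.array(SIM_AUTOSOMES)[chrom_idx]
    start = gstart % SIM_CHROM_LENGTH
    cn = np.full(n_bins, 2.0)
    if tri is not None:
        cn[chroms == tri[0]] += tri[1]
    counts = rng.poisson(mean_reads_per_bin * cn / 2.0)
    return pd.DataFrame({"chrom": chroms, "start": start,
                         "end": start + width, "count": counts})


def simulate_cfdna(truth: FamilyTruth, fetal_fraction: float, depth: int,
                   cfdna_error_rate: float, seed: int = 0) -> pd.DataFrame:
    """Maternal plasma allele depths at every simulated SNP.

    The alt-read probability at a site is the plasma mixture
    ``(1-ff) * g_mother/2 + ff * g_fetus/2`` (g = alt-allele count),
    attenuated by sequencing error e as ``p(1-2e) + e`` — every read
    flips to the other allele with probability e.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not 0.0 <= fetal_fraction < 1.0:
        raise ValueError("fetal_fraction must be in [0, 1)")
    rng = _rng(seed, _TAG_CFDNA)
    g_m = truth.parent_genotypes("mother").astype(float)
    g_f = truth.child_genotypes(truth.fetus).astype(float)
    p = (1.0 - fetal_fraction) * g_m / 2.0 + fetal_fraction * g_f / 2.0
    p = p * (1.0 - 2.0 * cfdna_error_rate) + cfdna_error_rate
    alt = rng.binomial(depth, p)
    return pd.DataFrame({
        "chrom": [s.chrom for s in truth.sites],
        "pos": [s.pos for s in truth.sites],
        "ref": [s.ref_allele for s in truth.sites],
        "alt": [s.alt_allele for s in truth.sites],
        "ref_depth": depth - alt,
        "alt_depth": alt,
    })


def simulate_aberrant_transcript(ref_cds: str,
                                 skip_interval: tuple[int, int]) -> str:
    """Remove a closed 1-based coding interval from a reference CDS.

    Models an aberrant splice product in which a cryptic donor deletes
    ``skip_interval = (c_start, c_end)`` inclusive from the mature
    transcript.
    """
    start, end = skip_interval
    if start > end:
        raise ValueError(f"empty interval: start {start} > end {end}")
    if start < 1 or end > len(ref_cds):
        raise ValueError(f"interval ({start}, {end}) outside 1..{len(ref_cds)}")
    return ref_cds[:start - 1] + ref_cds[end:]


def random_cds(length: int, rng: np.random.Generator) -> str:
    """Uniform random DNA string, used to fabricate reference CDS fixtures."""
    return "".join(rng.choice(list("ACGT"), size=length))
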