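"""Shared fixtures and independent oracles for the pgtlink suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from pgtlink import EmbryoTruth, SimulationConfig, simulate_family
from pgtlink.genotype_io import VariantSite
from pgtlink.simulate import FamilyTruth

settings.register_profile("suite", derandomize=True, max_examples=60,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def clean_family():
    """Noise-free family: biopsy genotypes equal truth exactly."""
    cfg = SimulationConfig(seed=11, n_snps=300, ado_rate=0.0,
                           genotype_error_rate=0.0)
    return simulate_family(cfg)


@pytest.fixture(scope="session")
def noisy_family():
    cfg = SimulationConfig(seed=13, n_snps=300)
    return simulate_family(cfg)


# ---------------------------------------------------------------------------
# hand-built capture-panel family truth
# ---------------------------------------------------------------------------

def make_panel_truth(n_rhdo: int = 200, n_ff: int = 500, n_err: int = 500,
                     seed: int = 0,
                     fetus: EmbryoTruth | None = None) -> FamilyTruth:
    """Family truth shaped like a targeted NIPT-M capture panel.

    Site classes by construction: ``n_rhdo`` maternal-informative sites
    (mother het, father hom-ref; which haplotype carries the alt allele
    is random), ``n_ff`` paternal-specific sites (mother hom-ref,
    father hom-alt) for fetal-fraction estimation, and ``n_err``
    double-hom-ref sites for error-rate estimation, interleaved across
    a 4 Mb window around the variant locus.
    """
    rng = np.random.default_rng(seed)
    variant_pos = 65_271_654
    n = n_rhdo + n_ff + n_err + 1
    pos = np.sort(rng.choice(np.arange(variant_pos - 2_000_000,
                                       variant_pos + 2_000_000),
                             size=n, replace=False))
    pos = pos[pos != variant_pos]
    pos = np.sort(np.append(pos[:n - 1], variant_pos))
    variant_index = int(np.searchsorted(pos, variant_pos))

    classes = np.array(["rhdo"] * n_rhdo + ["ff"] * n_ff + ["err"] * n_err)
    rng.shuffle(classes)
    classes = np.insert(classes, variant_index, "variant")

    M1 = np.zeros(n, dtype=np.int8)
    M2 = np.zeros(n, dtype=np.int8)
    P1 = np.zeros(n, dtype=np.int8)
    P2 = np.zeros(n, dtype=np.int8)
    rhdo = classes == "rhdo"
    M1[rhdo] = rng.integers(0, 2, size=int(rhdo.sum()))
    M2[rhdo] = 1 - M1[rhdo]
    P1[classes == "ff"] = 1
    P2[classes == "ff"] = 1
    M1[variant_index] = 1  # risk allele on M1, father hom-ref

    sites = [VariantSite("chr14", int(p),
                         "A", "G", "pathogenic_variant"
                         if i == variant_index else f"panel_{i:05d}")
             for i, p in enumerate(pos)]
    return FamilyTruth(
        sites=sites, allele_freqs=np.full(n, 0.25),
        maternal={"M1": M1, "M2": M2}, paternal={"P1": P1, "P2": P2},
        embryos={"REF_EMBRYO": EmbryoTruth("M1", "P1")},
        fetus=fetus or EmbryoTruth("M2", "P2"),
        variant_index=variant_index,
        window=("chr14", variant_pos - 2_000_000, variant_pos + 2_000_000))


def make_linkage_truth(n_per_flank: int = 11, seed: int = 0) -> FamilyTruth:
    """Family truth with a fixed count of maternal-informative SNPs.

    ``n_per_flank`` sites upstream and downstream of the variant, all
    mother-het / father-hom-ref (which maternal haplotype carries the
    alt allele is random), plus the variant site itself — the layout
    of an effective-SNP linkage panel.
    """
    rng = np.random.default_rng(seed)
    variant_pos = 65_271_654
    up = np.linspace(variant_pos - 1_900_000, variant_pos - 100_000,
                     n_per_flank).astype(np.int64)
    down = np.linspace(variant_pos + 100_000, variant_pos + 1_900_000,
                       n_per_flank).astype(np.int64)
    pos = np.concatenate([up, [variant_pos], down])
    n = len(pos)
    variant_index = n_per_flank
    M1 = rng.integers(0, 2, size=n).astype(np.int8)
    M1[variant_index] = 1
    M2 = (1 - M1).astype(np.int8)
    zeros = np.zeros(n, dtype=np.int8)
    sites = [VariantSite("chr14", int(p), "A", "G",
                         "pathogenic_variant" if i == variant_index
                         else f"snp_{i:03d}")
             for i, p in enumerate(pos)]
    return FamilyTruth(
        sites=sites, allele_freqs=np.full(n, 0.5),
        maternal={"M1": M1, "M2": M2},
        paternal={"P1": zeros, "P2": zeros.copy()},
        embryos={"REF_EMBRYO": EmbryoTruth("M1", "P1")},
        fetus=EmbryoTruth("M2", "P2"), variant_index=variant_index,
        window=("chr14", variant_pos - 2_000_000, variant_pos + 2_000_000))


def phased_table_from_truth(truth: FamilyTruth):
    """True maternal phase rendered as a phased-haplotype table."""
    import pandas as pd

    m_gt = truth.parent_genotypes("mother")
    f_gt = truth.parent_genotypes("father")
    informative = (m_gt == 1) & (f_gt != 1)
    return pd.DataFrame({
        "chrom": [s.chrom for s in truth.sites],
        "pos": [s.pos for s in truth.sites],
        "site_id": [s.site_id for s in truth.sites],
        "category": np.where(informative, "MAT_INF", "OTHER"),
        "M1": np.where(informative, truth.maternal["M1"], np.nan),
        "M2": np.where(informative, truth.maternal["M2"], np.nan),
        "P1": np.nan, "P2": np.nan,
    })


def annotate_from_truth(truth: FamilyTruth, cfdna) -> "object":
    """Attach parental genotypes and the true maternal phase to a
    simulated cfDNA table, producing the fetal-diagnosis input."""
    import pandas as pd

    table = cfdna.copy()
    m_gt = truth.parent_genotypes("mother")
    f_gt = truth.parent_genotypes("father")
    table["mother_gt"] = m_gt
    table["father_gt"] = f_gt
    informative = (m_gt == 1) & (f_gt != 1)
    table["M1"] = np.where(informative, truth.maternal["M1"], np.nan)
    table["M2"] = np.where(informative, truth.maternal["M2"], np.nan)
    table["father_allele"] = np.where(f_gt == 2, 1,
                                      np.where(f_gt == 0, 0, -1))
    return table


# ---------------------------------------------------------------------------
# oracle: exhaustive maternal-phase enumeration for a trio
# ---------------------------------------------------------------------------

def enumerate_maternal_transmission(mother: np.ndarray, father: np.ndarray,
                                    child: np.ndarray) -> dict[int, set[int]]:
    """Brute-force all maternal phase assignments consistent with a trio.

    Enumerates every assignment of the mother's alleles to two
    haplotypes over her heterozygous sites (2^h) crossed with which
    haplotype she transmitted, keeps those where the child's remaining
    allele is available from the father at every site, and returns,
    per site, the set of maternal alleles the child may have received.
    Independent of the package's per-site deduction path.
    """
    het_idx = [i for i in range(len(mother)) if mother[i] == 1]
    consistent: dict[int, set[int]] = {i: set() for i in range(len(mother))}
    f_alleles = [{0: (0,), 1: (0, 1), 2: (1,)}[int(g)] for g in father]
    for mask in range(2 ** len(het_idx)):
        hapA = np.where(mother == 2, 1, 0)
        for b, i in enumerate(het_idx):
            hapA[i] = (mask >> b) & 1
        hapB = mother - hapA
        for transmitted in (hapA, hapB):
            ok = all(
                int(child[i]) - int(transmitted[i]) in f_alleles[i]
                for i in range(len(mother)))
            if ok:
                for i in range(len(mother)):
                    consistent[i].add(int(transmitted[i]))
    return consistent


# ---------------------------------------------------------------------------
# oracle: all placements of a single contiguous deletion
# ---------------------------------------------------------------------------

def all_deletion_placements(ref: str, obs: str) -> list[tuple[int, int]]:
    """Every 1-based closed interval whose removal turns ref into obs."""
    L = len(ref) - len(obs)
    if L <= 0:
        return []
    return [(s + 1, s + L) for s in range(len(obs) + 1)
            if ref[:s] + ref[s + L:] == obs]


# ---------------------------------------------------------------------------
# oracle: plain Needleman-Wunsch edit distance
# ---------------------------------------------------------------------------

def edit_distance(a: str, b: str) -> int:
    """Unit-cost global alignment score by dynamic programming."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1,
                           prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]
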