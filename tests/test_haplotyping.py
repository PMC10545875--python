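"""Phasing rules, truth recovery and the exhaustive-enumeration oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from conftest import enumerate_maternal_transmission
from pgtlink import (
    SimulationConfig,
    build_parental_haplotypes,
    classify_sites,
    phase_parent_by_reference,
    simulate_family,
)
from pgtlink.genotype_io import (
    GenotypeMatrix, Pedigree, PedigreeSample, VariantSite,
    HOM_REF, HET, HOM_ALT, MISSING,
)
from pgtlink.haplotyping import PhasingError, SiteCategory


def _trio_matrix(mother, father, ref, chrom="chr14", start=100):
    """Build a matrix with FATHER/MOTHER/REF_EMBRYO columns."""
    n = len(mother)
    sites = [VariantSite(chrom, start + 10 * i, "A", "G") for i in range(n)]
    calls = np.column_stack([father, mother, ref]).astype(np.int8)
    return GenotypeMatrix(sites, ["FATHER", "MOTHER", "REF_EMBRYO"], calls)


_PED = Pedigree([PedigreeSample("FATHER", "father", "non_carrier"),
                 PedigreeSample("MOTHER", "mother", "carrier"),
                 PedigreeSample("REF_EMBRYO", "reference_embryo", "carrier")])


class TestClassifySites:
    @pytest.mark.parametrize("mother, father, ref, expected", [
        (HET, HOM_REF, HET, SiteCategory.MAT_INF),
        (HET, HOM_ALT, HET, SiteCategory.MAT_INF),
        (HOM_REF, HET, HET, SiteCategory.PAT_INF),
        (HOM_REF, HOM_REF, HOM_REF, SiteCategory.UNINFORMATIVE),
        (HET, HET, HET, SiteCategory.BOTH_HET),
        (MISSING, HOM_REF, HOM_REF, SiteCategory.MISSING),
        (HOM_REF, HOM_REF, HOM_ALT, SiteCategory.MENDEL_INCONSISTENT),
        (HET, HOM_REF, HOM_ALT, SiteCategory.MENDEL_INCONSISTENT),
    ])
    def test_rules(self, mother, father, ref, expected):
        m = _trio_matrix([mother], [father], [ref])
        assert classify_sites(m, _PED) == [expected]

    def test_every_site_gets_exactly_one_category(self, noisy_family):
        _, matrix, ped = noisy_family
        cats = classify_sites(matrix, ped)
        assert len(cats) == matrix.n_sites
        assert all(isinstance(c, SiteCategory) for c in cats)


class TestPhaseByReference:
    @pytest.mark.parametrize("ref_gt, transmitted", [
        (HET, 1),       # mother A/G, father A/A, child A/G: maternal G
        (HOM_REF, 0),   # child A/A: maternal A
    ])
    def test_deduction(self, ref_gt, transmitted):
        assert phase_parent_by_reference(HET, HOM_REF, ref_gt) == transmitted

    def test_incompatible_reference_dropped(self):
        # father A/A cannot give G, so child G/G is impossible
        assert phase_parent_by_reference(HET, HOM_REF, HOM_ALT) is None

    def test_missing_reference_unphased(self):
        assert phase_parent_by_reference(HET, HOM_REF, MISSING) is None

    def test_requires_informative_site(self):
        with pytest.raises(PhasingError):
            phase_parent_by_reference(HOM_REF, HOM_REF, HET)


class TestBuildParentalHaplotypes:
    def test_noise_free_equals_truth(self, clean_family):
        truth, matrix, ped = clean_family
        haps = build_parental_haplotypes(matrix, ped)
        phased = haps.maternal_alleles()
        assert len(phased) > 10
        pos_to_idx = {s.pos: i for i, s in enumerate(matrix.sites)}
        for row in phased.itertuples():
            i = pos_to_idx[row.pos]
            assert int(row.M1) == truth.maternal["M1"][i]
            assert int(row.M2) == truth.maternal["M2"][i]

    def test_m1_m2_multiset_matches_mother(self, noisy_family):
        _, matrix, ped = noisy_family
        haps = build_parental_haplotypes(matrix, ped)
        mother = matrix.column("MOTHER")
        pos_to_idx = {s.pos: i for i, s in enumerate(matrix.sites)}
        for row in haps.maternal_alleles().itertuples():
            assert int(row.M1) + int(row.M2) == mother[pos_to_idx[row.pos]] == HET

    def test_non_carrier_reference_flips_labels(self, clean_family):
        truth, matrix, ped = clean_family
        flipped = Pedigree([
            PedigreeSample("FATHER", "father", "non_carrier"),
            PedigreeSample("MOTHER", "mother", "carrier"),
            PedigreeSample("REF_EMBRYO", "reference_embryo",
                           "non_carrier" if ped.reference_embryo.carrier_status
                           == "carrier" else "carrier"),
            *[PedigreeSample(e.sample_id, "embryo") for e in ped.embryos],
        ])
        h1 = build_parental_haplotypes(matrix, ped)
        h2 = build_parental_haplotypes(matrix, flipped)
        a, b = h1.maternal_alleles(), h2.maternal_alleles()
        assert list(a["M1"]) == list(b["M2"]) and list(a["M2"]) == list(b["M1"])

    def test_unknown_carrier_status_is_hard_error(self, clean_family):
        _, matrix, ped = clean_family
        bad = Pedigree([
            PedigreeSample("FATHER", "father"),
            PedigreeSample("MOTHER", "mother"),
            PedigreeSample("REF_EMBRYO", "reference_embryo", "unknown"),
        ])
        with pytest.raises(PhasingError, match="unanchored"):
            build_parental_haplotypes(matrix, bad)

    def test_site_order_permutation_invariant(self, clean_family):
        _, matrix, ped = clean_family
        rng = np.random.default_rng(0)
        perm = rng.permutation(matrix.n_sites)
        shuffled = GenotypeMatrix([matrix.sites[i] for i in perm],
                                  matrix.sample_ids, matrix.calls[perm])
        h1 = build_parental_haplotypes(matrix, ped)
        h2 = build_parental_haplotypes(shuffled, ped)
        pd.testing.assert_frame_equal(h1.table, h2.table)

    @given(st.integers(0, 10_000))
    def test_oracle_equivalence_random_trios(self, seed):
        """Per-site deduction equals exhaustive maternal-phase enumeration.

        Random <=10-site trios (child drawn Mendelian from random
        parental diplotypes); at every maternal-informative site the
        brute-force set of transmissible maternal alleles must be the
        singleton the pipeline phased.
        """
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        haps = rng.integers(0, 2, size=(4, n))  # mA mB fA fB
        mother = haps[0] + haps[1]
        father = haps[2] + haps[3]
        child = haps[rng.integers(0, 2)] + haps[2 + rng.integers(0, 2)]
        m = _trio_matrix(mother, father, child)
        variant_pos = 100 + 10 * (n // 2)

        cats = classify_sites(m, _PED)
        oracle = enumerate_maternal_transmission(mother, father, child)
        for i, cat in enumerate(cats):
            if cat is not SiteCategory.MAT_INF:
                continue
            transmitted = phase_parent_by_reference(
                int(mother[i]), int(father[i]), int(child[i]))
            assert oracle[i] == {transmitted}

        # and the full builder agrees wherever it phases (reference is a
        # carrier here iff it received the maternal allele labelled M1)
        try:
            haps_out = build_parental_haplotypes(
                m, _PED, variant_chrom="chr14", variant_pos=variant_pos)
        except PhasingError:
            return  # degenerate trio without per-flank informative sites
        pos_to_idx = {s.pos: i for i, s in enumerate(m.sites)}
        for row in haps_out.maternal_alleles().itertuples():
            assert oracle[pos_to_idx[row.pos]] == {int(row.M1)}
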