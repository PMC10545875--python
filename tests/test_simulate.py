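"""Distributional and structural checks on the synthetic-family generator."""

import numpy as np
import pytest

from pgtlink import (
    EmbryoTruth,
    SimulationConfig,
    simulate_aberrant_transcript,
    simulate_cfdna,
    simulate_embryo_biopsy,
    simulate_family,
    simulate_low_pass_counts,
)
from pgtlink.genotype_io import HET, HOM_REF
from pgtlink.haplotyping import _mendel_possible


def _truth(seed=5, n_snps=400, **kw):
    return simulate_family(SimulationConfig(seed=seed, n_snps=n_snps, **kw))


class TestSimulateFamily:
    def test_seed_determinism(self):
        cfg = SimulationConfig(seed=42, n_snps=150)
        _, m1, _ = simulate_family(cfg)
        _, m2, _ = simulate_family(cfg)
        assert m1 == m2

    def test_structure(self):
        truth, matrix, ped = _truth()
        pos = matrix.positions()
        assert np.all(np.diff(pos) > 0)
        vi = truth.variant_index
        assert matrix.sites[vi].pos == 65_271_654
        assert matrix.sites[vi].chrom == "chr14"
        # mother het at the variant (on M1), father hom-ref
        assert matrix.column("MOTHER")[vi] == HET
        assert matrix.column("FATHER")[vi] == HOM_REF
        assert truth.maternal["M1"][vi] == 1
        assert truth.maternal["M2"][vi] == 0
        assert ped.reference_embryo is not None
        assert ped.reference_embryo.carrier_status in ("carrier", "non_carrier")

    def test_error_free_children_are_mendelian(self):
        truth, matrix, _ = _truth(ado_rate=0.0, genotype_error_rate=0.0)
        mother, father = matrix.column("MOTHER"), matrix.column("FATHER")
        for eid in truth.embryos:
            child = matrix.column(eid)
            assert all(_mendel_possible(int(mother[i]), int(father[i]),
                                        int(child[i]))
                       for i in range(matrix.n_sites))

    def test_zero_snps_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_snps=0)

    def test_maternal_informative_fraction_matches_hardy_weinberg(self):
        """Observed mother-het/father-hom fraction vs the closed form.

        Per site with alt frequency p, P(MAT_INF) = 2p(1-p) * (p^2 +
        (1-p)^2); summing over the simulated frequencies gives the
        expected count, checked to 3 binomial standard errors (the
        forced variant site is excluded).
        """
        truth, matrix, _ = _truth(seed=7, n_snps=200, maf_range=(0.2, 0.5),
                                  ado_rate=0.0, genotype_error_rate=0.0)
        keep = np.arange(matrix.n_sites) != truth.variant_index
        p = truth.allele_freqs[keep]
        p_inf = 2 * p * (1 - p) * (p ** 2 + (1 - p) ** 2)
        expected, var = p_inf.sum(), (p_inf * (1 - p_inf)).sum()
        mother, father = matrix.column("MOTHER")[keep], matrix.column("FATHER")[keep]
        observed = int(((mother == HET) & (father != HET)).sum())
        assert abs(observed - expected) <= 3 * np.sqrt(var)

    def test_truth_round_trip_zero_noise(self):
        truth, _, _ = _truth()
        for eid, et in truth.embryos.items():
            regen = simulate_embryo_biopsy(truth, eid, 0.0, 0.0, seed=99)
            assert np.array_equal(regen, truth.child_genotypes(et))


class TestEmbryoBiopsy:
    def test_full_ado_makes_all_hets_homozygous(self):
        truth, _, _ = _truth()
        eid = "E01"
        clean = truth.child_genotypes(truth.embryos[eid])
        noisy = simulate_embryo_biopsy(truth, eid, 1.0, 0.0, seed=3)
        assert not np.any(noisy[clean == HET] == HET)

    def test_zero_noise_identity(self):
        truth, _, _ = _truth()
        out = simulate_embryo_biopsy(truth, "E02", 0.0, 0.0, seed=3)
        assert np.array_equal(out, truth.child_genotypes(truth.embryos["E02"]))

    def test_unknown_embryo_rejected(self):
        truth, _, _ = _truth()
        with pytest.raises(KeyError):
            simulate_embryo_biopsy(truth, "E99", 0.1, 0.0, seed=3)

    def test_ado_rate_binomial(self):
        """Dropout fraction over ~10k het sites within 3 binomial SE of 0.1."""
        truth, _, _ = _truth(seed=21, n_snps=20_000, maf_range=(0.4, 0.5))
        eid, ado = "E01", 0.1
        clean = truth.child_genotypes(truth.embryos[eid])
        noisy = simulate_embryo_biopsy(truth, eid, ado, 0.0, seed=8)
        het = clean == HET
        n = int(het.sum())
        assert n > 5000
        dropped = float((noisy[het] != HET).mean())
        assert abs(dropped - ado) <= 3 * np.sqrt(ado * (1 - ado) / n)


class TestLowPassCounts:
    def test_diploid_mean(self):
        truth, _, _ = _truth()
        cov = simulate_low_pass_counts(truth, "E02", 1000, 100.0, seed=4)
        se = np.sqrt(100.0 / 1000)
        assert abs(cov["count"].mean() - 100.0) <= 3 * se

    @pytest.mark.parametrize("m, ratio", [(1.0, 1.5), (0.4, 1.2)])
    def test_trisomy_inflation(self, m, ratio):
        truth, _, _ = _truth(
            embryo_truth=[EmbryoTruth("M1", "P1", trisomy=("chr2", m))] * 5)
        cov = simulate_low_pass_counts(truth, "E01", 1000, 100.0, seed=5)
        tri = cov[cov["chrom"] == "chr2"]["count"]
        expected = 100.0 * ratio
        se = np.sqrt(expected / len(tri))
        assert abs(tri.mean() - expected) <= 3 * se

    def test_zero_bins_rejected(self):
        truth, _, _ = _truth()
        with pytest.raises(ValueError):
            simulate_low_pass_counts(truth, "E01", 0, 100.0, seed=1)

    def test_bins_partition_half_open(self):
        truth, _, _ = _truth()
        cov = simulate_low_pass_counts(truth, "E01", 800, 50.0, seed=1)
        widths = cov["end"] - cov["start"]
        assert widths.nunique() == 1 and (widths > 0).all()
        for _, grp in cov.groupby("chrom"):
            g = grp.sort_values("start")
            assert (g["start"].to_numpy()[1:] >= g["end"].to_numpy()[:-1]).all()


class TestCfDna:
    def test_ff_zero_mean_is_maternal_vaf(self):
        truth, _, _ = _truth(seed=31, n_snps=4000)
        table = simulate_cfdna(truth, 0.0, 500, 0.0, seed=6)
        g_m = truth.parent_genotypes("mother")
        for g in (0, 1, 2):
            sel = g_m == g
            vaf = (table["alt_depth"][sel] / 500).mean()
            n = int(sel.sum()) * 500
            se = np.sqrt(max(g / 2 * (1 - g / 2), 0.25) / n)
            assert abs(vaf - g / 2) <= max(3 * se, 1e-9)

    def test_paternal_allele_fraction(self):
        """Mother hom-ref x father hom-alt sites: mean VAF ~ ff/2 = 0.05."""
        truth, _, _ = _truth(seed=33, n_snps=8000)
        table = simulate_cfdna(truth, 0.10, 100, 0.0, seed=7)
        g_m = truth.parent_genotypes("mother")
        g_f_fetus = truth.child_genotypes(truth.fetus)
        g_dad = truth.parent_genotypes("father")
        sel = (g_m == 0) & (g_dad == 2)
        assert sel.sum() > 100
        assert np.all(g_f_fetus[sel] == 1)  # obligate heterozygote
        vaf = float((table["alt_depth"][sel] / 100).mean())
        se = np.sqrt(0.05 * 0.95 / (int(sel.sum()) * 100))
        assert abs(vaf - 0.05) <= 3 * se

    def test_zero_depth_rejected(self):
        truth, _, _ = _truth()
        with pytest.raises(ValueError):
            simulate_cfdna(truth, 0.1, 0, 0.0, seed=1)


class TestAberrantTranscript:
    def test_interval_removal_lengths(self):
        ref = "ACGT" * 100
        assert len(simulate_aberrant_transcript(ref, (279, 299))) == 379
        assert len(simulate_aberrant_transcript(ref, (1, 1))) == 399

    def test_removed_segment_content(self):
        ref = "AACCGGTTAA"
        assert simulate_aberrant_transcript(ref, (3, 6)) == "AATTAA"

    @pytest.mark.parametrize("interval", [(5, 4), (0, 3), (1, 401)])
    def test_bad_intervals_rejected(self, interval):
        with pytest.raises(ValueError):
            simulate_aberrant_transcript("A" * 400, interval)
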