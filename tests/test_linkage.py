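"""Variance-components heritability, LOD scanning and family decomposition."""

import numpy as np
import pytest

from famscan import (
    FamilyLOD,
    IdentifiabilityError,
    SimConfig,
    fit_polygenic,
    family_lods,
    kinship_matrix,
    lod_scan,
    select_linked_families,
    simulate_dataset,
    simulate_pedigrees,
    support_interval,
    linkage_accounted,
)
from famscan.linkage import IBDMatrix, LinkageScan, LocusFit, PolygenicFit, VarianceComponents

from conftest import subset_ibd


class TestFitPolygenic:
    def test_unrelated_individuals_rejected(self):
        n = 40
        with pytest.raises(IdentifiabilityError):
            fit_polygenic(
                np.random.default_rng(0).normal(size=n),
                np.ones((n, 1)),
                0.5 * np.eye(n),
                families=np.arange(n),
            )

    def test_iid_trait_hits_zero_boundary(self):
        """With family structure present but a trait that is pure noise, the
        heritability estimate sits at the 0 boundary and the LRT p-value
        is 1 (or very near it)."""
        cfg = SimConfig(n_families=100, h2_polygenic=0.0, qtl_var_fraction=0.0, seed=21)
        ped = simulate_pedigrees(cfg)
        kin = kinship_matrix(ped)
        y = np.random.default_rng(21).normal(size=len(kin.ids))
        fit = fit_polygenic(y, np.ones((len(y), 1)), kin)
        assert fit.h2 < 0.12  # within boundary sampling noise of 0 at n = 600
        assert fit.h2_p > 0.05

    def test_recovers_simulated_heritability(self, qtl_scenario):
        """True slope heritability 0.368 plus a 0.30 QTL acting through a
        single diallelic locus: the polygenic model soaks up both familial
        sources, so the estimate lands near their sum."""
        s = qtl_scenario
        fit = fit_polygenic(s["y"], s["X"], s["kin"])
        truth = s["cfg"].h2_polygenic + s["cfg"].qtl_var_fraction
        assert fit.h2 == pytest.approx(truth, abs=0.12)
        assert fit.h2_p < 1e-6
        assert np.isfinite(fit.h2_se) and 0 < fit.h2_se < 0.2

    def test_scale_equivariance(self, qtl_scenario):
        s = qtl_scenario
        f1 = fit_polygenic(s["y"], s["X"], s["kin"])
        f2 = fit_polygenic(2.0 * s["y"], s["X"], s["kin"])
        assert f2.h2 == pytest.approx(f1.h2, abs=1e-4)
        assert f2.components.sigma2_g == pytest.approx(4 * f1.components.sigma2_g, rel=1e-3)
        assert f2.components.sigma2_e == pytest.approx(4 * f1.components.sigma2_e, rel=1e-3)


class TestLodScan:
    def test_expected_sharing_gives_zero_lod(self, qtl_scenario):
        """When the locus IBD matrix equals 2*Phi the locus component is
        confounded with the polygenic one: no likelihood gain, LOD = 0."""
        s = qtl_scenario
        kin2 = s["kin"].kin2.copy()
        np.fill_diagonal(kin2, 1.0)
        confounded = IBDMatrix(chrom="1", pos=1, ids=list(s["ids"]), values=kin2)
        scan = lod_scan(s["y"], s["X"], s["kin"], [confounded])
        assert 0.0 <= scan.peak_lod < 1e-6

    def test_qtl_locus_beats_unlinked_locus(self, qtl_scenario):
        s = qtl_scenario
        scan = lod_scan(s["y"], s["X"], s["kin"], s["ibd"])
        lods = {l.pos: l.lod for l in scan.loci}
        qtl_pos = int(s["state"].loci.set_index("variant_id").loc["qtl", "pos"])
        others = [v for p, v in lods.items() if p != qtl_pos]
        assert lods[qtl_pos] > max(others)
        assert all(l.lod >= 0 for l in scan.loci)
        assert all(l.loglik_h1 >= scan.loglik_h0 - 1e-8 for l in scan.loci)

    def test_bad_ibd_entries_rejected(self, qtl_scenario):
        s = qtl_scenario
        bad = np.full((len(s["ids"]), len(s["ids"])), 1.5)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            IBDMatrix(chrom="1", pos=1, ids=list(s["ids"]), values=bad)


class TestFamilyLods:
    def test_sum_equals_total_lod(self, qtl_scenario):
        s = qtl_scenario
        scan = lod_scan(s["y"], s["X"], s["kin"], s["ibd"])
        peak = scan.peak
        mat = next(m for m in s["ibd"] if (m.chrom, m.pos) == (peak.chrom, peak.pos))
        fams = family_lods(s["y"], s["X"], s["kin"], mat, scan)
        assert sum(f.pedlod for f in fams) == pytest.approx(peak.lod, abs=1e-8)
        assert all(f.n_members == 6 for f in fams)

    def test_single_family_carries_whole_lod(self):
        cfg = SimConfig(n_families=1, seed=33, qtl_var_fraction=0.5, h2_polygenic=0.1)
        ped, geno, state, pheno = simulate_dataset(cfg)
        kin = kinship_matrix(ped)
        rng = np.random.default_rng(33)
        y = rng.normal(size=len(kin.ids))
        X = np.ones((len(y), 1))
        from famscan.simulate import ibd_matrix_from_state

        mat = subset_ibd(ibd_matrix_from_state(state, "qtl"), kin.ids)
        scan = lod_scan(y, X, kin, [mat])
        fams = family_lods(y, X, kin, mat, scan)
        assert len(fams) == 1
        assert fams[0].pedlod == pytest.approx(scan.peak_lod, abs=1e-10)


class TestSelectLinkedFamilies:
    def test_worked_example(self):
        fams = [
            FamilyLOD("A", 5.0, 6),
            FamilyLOD("B", 4.5, 6),
            FamilyLOD("C", 0.2, 6),
            FamilyLOD("D", 0.05, 10),
        ]
        out = select_linked_families(fams)
        assert out["potentially_linked"] == {"A", "B", "C"}
        assert out["top_linked"] == {"A", "B"}

    def test_per_member_branch(self):
        fams = [FamilyLOD("X", 0.08, 5), FamilyLOD("Y", 12.0, 6)]
        out = select_linked_families(fams)
        assert "X" in out["potentially_linked"]  # 0.08/5 = 0.016 > 0.01

    def test_all_nonpositive_warns_and_returns_empty(self):
        fams = [FamilyLOD("X", 0.0, 5), FamilyLOD("Y", -0.2, 6)]
        with pytest.warns(UserWarning, match="cumulative"):
            out = select_linked_families(fams)
        assert out["potentially_linked"] == set()
        assert out["top_linked"] == set()


def _toy_scan(lods, positions=None, chrom="1"):
    positions = positions or list(range(1, len(lods) + 1))
    null = PolygenicFit(
        components=VarianceComponents(0.0, 0.0, 1.0),
        beta=np.zeros(1), loglik=0.0, h2=0.0, h2_se=float("nan"), h2_p=1.0, n=10,
    )
    loci = [
        LocusFit(chrom=chrom, pos=p, lod=l, loglik_h1=l * np.log(10),
                 components=VarianceComponents(0, 0, 1))
        for p, l in zip(positions, lods)
    ]
    return LinkageScan(loci=loci, loglik_h0=0.0, null_fit=null)


class TestSupportInterval:
    def test_one_lod_drop_on_toy_profile(self):
        scan = _toy_scan([0.5, 2.0, 3.6, 3.0, 2.4, 1.0])
        assert support_interval(scan) == (("1", 3), ("1", 4))

    def test_single_locus_scan(self):
        scan = _toy_scan([4.0])
        assert support_interval(scan) == (("1", 1), ("1", 1))

    def test_flat_profile_returns_whole_range_with_warning(self):
        scan = _toy_scan([3.0, 3.0, 3.0])
        with pytest.warns(UserWarning, match="full"):
            assert support_interval(scan) == (("1", 1), ("1", 3))

    def test_empty_scan_is_error(self):
        scan = _toy_scan([1.0])
        scan.loci = []
        with pytest.raises(ValueError, match="empty"):
            support_interval(scan)


class TestLinkageAccounted:
    def test_forced_arithmetic(self):
        # a peak attenuating from LOD 3.6 to 1.0 accounts for 72.2%
        assert 100 * (3.6 - 1.0) / 3.6 == pytest.approx(72.2, abs=0.05)

    def test_causal_dosage_absorbs_most_linkage(self, qtl_scenario):
        s = qtl_scenario
        qtl_pos = int(s["state"].loci.set_index("variant_id").loc["qtl", "pos"])
        mat = next(m for m in s["ibd"] if m.pos == qtl_pos)
        out = linkage_accounted(s["y"], s["X"], s["kin"], mat, s["qtl_dosage"])
        assert out["percent"] > 50.0
        assert out["lod_conditioned"] <= out["lod0"] + 1e-6

    def test_irrelevant_dosage_accounts_for_little(self, qtl_scenario):
        s = qtl_scenario
        qtl_pos = int(s["state"].loci.set_index("variant_id").loc["qtl", "pos"])
        mat = next(m for m in s["ibd"] if m.pos == qtl_pos)
        g = np.random.default_rng(1).binomial(2, 0.3, size=len(s["y"])).astype(float)
        out = linkage_accounted(s["y"], s["X"], s["kin"], mat, g)
        assert abs(out["percent"]) < 20.0
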