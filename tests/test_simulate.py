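"""Gene-dropping simulator: pedigree templates, Mendelian transmission,
exact IBD, and the E[Pi] = 2*Phi bridge to the linkage model."""

import numpy as np
import pytest

from famscan import (
    SimConfig,
    gene_drop,
    ibd_matrix_from_state,
    kinship_matrix,
    simulate_dataset,
    simulate_longitudinal_trait,
    simulate_pedigrees,
)


class TestPedigreeTemplates:
    def test_nuclear_counts(self):
        ped = simulate_pedigrees(SimConfig(n_families=2, family_template="nuclear_4_sibs"))
        assert len(ped) == 12
        assert len(ped.founders()) == 4

    def test_three_generation_structure(self):
        ped = simulate_pedigrees(SimConfig(n_families=1, family_template="three_generation"))
        assert len(ped) == 10
        assert len(ped.founders()) == 4

    def test_unknown_template_rejected(self):
        with pytest.raises(ValueError, match="template"):
            simulate_pedigrees(SimConfig(family_template="extended_clan"))

    def test_determinism(self):
        cfg = SimConfig(n_families=3, seed=9)
        p1 = simulate_pedigrees(cfg)
        p2 = simulate_pedigrees(cfg)
        assert [r for r in p1.records] == [r for r in p2.records]


@pytest.fixture(scope="module")
def dropped():
    cfg = SimConfig(n_families=40, seed=17, n_null_markers=199, qtl_maf=0.2)
    ped = simulate_pedigrees(cfg)
    geno, state = gene_drop(ped, cfg)
    return cfg, ped, geno, state


class TestGeneDrop:
    def test_no_mendelian_errors(self, dropped):
        _, ped, _, state = dropped
        pos = {iid: k for k, iid in enumerate(state.ids)}
        for rec in ped.records:
            for slot, parent in ((0, rec.father_id), (1, rec.mother_id)):
                if parent is None:
                    continue
                child_allele = state.labels[pos[rec.individual_id], :, slot]
                par = state.labels[pos[parent], :, :]
                assert np.all(
                    (child_allele == par[:, 0]) | (child_allele == par[:, 1])
                )

    def test_parent_offspring_ibd_half_everywhere(self, dropped):
        cfg, ped, _, state = dropped
        mat = ibd_matrix_from_state(state, 0)
        idx = {i: k for k, i in enumerate(mat.ids)}
        child = next(r for r in ped.records if not r.is_founder)
        assert mat.values[idx[child.individual_id], idx[child.father_id]] == 0.5

    def test_full_sib_mean_ibd_near_half(self, dropped):
        cfg, ped, _, state = dropped
        pos = {iid: k for k, iid in enumerate(state.ids)}
        fam = ped.family(ped.family_ids[0])
        sibs = [r.individual_id for r in fam if not r.is_founder][:2]
        pis = [
            ibd_matrix_from_state(state, l).values[pos[sibs[0]], pos[sibs[1]]]
            for l in range(len(state.loci))
        ]
        assert 0.4 <= float(np.mean(pis)) <= 0.6  # 200 loci; LLN check at scale in acceptance

    def test_founder_allele_frequency_matches_config(self, dropped):
        cfg, ped, _, state = dropped
        founder_labels = set()
        pos = {iid: k for k, iid in enumerate(state.ids)}
        for r in ped.founders():
            founder_labels.update(state.labels[pos[r.individual_id], 0, :])
        freq = state.is_alt[sorted(founder_labels), :].mean()
        assert freq == pytest.approx(cfg.qtl_maf, abs=0.01)

    def test_ibd_matrix_invariants(self, dropped):
        cfg, ped, _, state = dropped
        mat = ibd_matrix_from_state(state, "qtl")
        assert np.allclose(np.diag(mat.values), 1.0)
        fam_of = ped.family_of()
        fams = np.array([fam_of[i] for i in mat.ids], dtype=object)
        cross = fams[:, None] != fams[None, :]
        assert np.all(mat.values[cross] == 0.0)

    def test_mean_ibd_equals_twice_kinship(self, dropped):
        """Bridge invariant: averaged over many unlinked loci, pairwise IBD
        converges to 2*phi."""
        cfg, ped, _, state = dropped
        kin = kinship_matrix(ped)
        fam = ped.family(ped.family_ids[1])
        members = [r.individual_id for r in fam]
        kidx = {i: k for k, i in enumerate(kin.ids)}
        pos = {iid: k for k, iid in enumerate(state.ids)}
        acc = np.zeros((len(members), len(members)))
        for l in range(len(state.loci)):
            m = ibd_matrix_from_state(state, l)
            sub = m.values[np.ix_([pos[x] for x in members], [pos[x] for x in members])]
            acc += sub
        acc /= len(state.loci)
        expect = kin.kin2[np.ix_([kidx[x] for x in members], [kidx[x] for x in members])]
        np.fill_diagonal(expect, 1.0)
        assert np.max(np.abs(acc - expect)) < 0.08  # 200 loci


class TestLongitudinalTrait:
    def test_two_visits_and_slope_recovery(self):
        cfg = SimConfig(n_families=20, seed=23)
        ped, geno, state, pheno = simulate_dataset(cfg)
        assert set(pheno["visit"]) == {1, 2}
        wide = pheno.pivot(index="id", columns="visit", values=["trait", "time"])
        gap = wide[("time", 2)] - wide[("time", 1)]
        assert np.allclose(gap, cfg.visit_gap_years)
        slope = (wide[("trait", 2)] - wide[("trait", 1)]) / gap
        truth = pheno.attrs["true_slope"].reindex(wide.index)
        assert np.allclose(slope, truth, atol=1e-10)

    def test_zero_gap_rejected(self):
        with pytest.raises(ValueError, match="gap"):
            SimConfig(visit_gap_years=0.0).validate()

    def test_infeasible_variance_fractions_rejected(self):
        with pytest.raises(ValueError, match="< 1"):
            SimConfig(h2_polygenic=0.7, qtl_var_fraction=0.4).validate()

    def test_determinism_across_runs(self):
        cfg = SimConfig(n_families=5, seed=31)
        _, g1, _, p1 = simulate_dataset(cfg)
        _, g2, _, p2 = simulate_dataset(cfg)
        assert np.array_equal(g1.dosages, g2.dosages, equal_nan=True)
        assert p1.equals(p2)

    def test_pure_noise_scenario_has_no_heritability(self):
        from famscan import derive_adjusted_trait, fit_polygenic

        cfg = SimConfig(n_families=120, h2_polygenic=0.0, qtl_var_fraction=0.0, seed=29)
        ped, geno, state, pheno = simulate_dataset(cfg)
        kin = kinship_matrix(ped)
        trait = derive_adjusted_trait(pheno, ["age", "sex", "center"])
        ids = list(trait.table.index)
        fit = fit_polygenic(
            trait.table["transformed"].to_numpy(), np.ones((len(ids), 1)), kin.subset(ids)
        )
        assert fit.h2 < 0.12  # boundary estimate within sampling noise of 0
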