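"""Simulator: panel generation, gene dropping, trait simulation, ascertainment."""

import numpy as np
import pytest

from pedsem import (ConfigurationError, SimulationConfig, affection_threshold,
                    apply_ascertainment, build_model_matrices, gene_drop,
                    generate_synthetic_panel, kinship_matrix, parse_model,
                    simulate_dataset, simulate_phenotypes, true_ibd_matrix)
from pedsem.simulator import (HaplotypePanel, preset_pedigrees,
                              replicate_structures)

from conftest import sib_pair


class TestPanel:
    def test_target_maf_hit(self):
        panel = generate_synthetic_panel(n_markers=10, n_haplotypes=4000,
                                         maf_range=(0.3, 0.3),
                                         r2_adjacent=0.1, seed=0)
        freqs = panel.frequencies()
        se = np.sqrt(0.3 * 0.7 / 4000)
        assert np.all(np.abs(freqs - 0.3) < 3 * se + 1e-9)

    def test_zero_ld_target(self):
        panel = generate_synthetic_panel(n_markers=12, n_haplotypes=2000,
                                         maf_range=(0.2, 0.4),
                                         r2_adjacent=0.0, seed=1)
        H = panel.haplotypes.astype(float)
        for m in range(1, 12):
            r = np.corrcoef(H[:, m - 1], H[:, m])[0, 1]
            assert r ** 2 < 0.05

    def test_adjacent_r2_near_target(self):
        target = 0.3
        panel = generate_synthetic_panel(n_markers=12, n_haplotypes=5000,
                                         maf_range=(0.25, 0.35),
                                         r2_adjacent=target, seed=2)
        H = panel.haplotypes.astype(float)
        r2 = [np.corrcoef(H[:, m - 1], H[:, m])[0, 1] ** 2
              for m in range(1, 12)]
        assert abs(np.mean(r2) - target) < 0.1

    def test_seed_determinism(self):
        a = generate_synthetic_panel(seed=7)
        b = generate_synthetic_panel(seed=7)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert a.names == b.names

    def test_infeasible_combination_raises(self):
        with pytest.raises(ConfigurationError, match="infeasible"):
            generate_synthetic_panel(n_markers=2, n_haplotypes=100,
                                     maf_range=(0.01, 0.49),
                                     r2_adjacent=0.95, seed=3)

    def test_write_read_round_trip(self, tmp_path):
        panel = generate_synthetic_panel(n_markers=4, n_haplotypes=20, seed=4)
        path = tmp_path / "panel.txt"
        panel.write(path)
        back = HaplotypePanel.read(path)
        assert back.names == panel.names
        assert np.array_equal(back.haplotypes, panel.haplotypes)
        assert np.array_equal(back.positions, panel.positions)


class TestGeneDrop:
    def test_mendelian_homozygous_parents(self):
        # all-zero panel column: children necessarily 0
        panel = HaplotypePanel(["m1"], np.array([1000.0]),
                               np.zeros((10, 1), dtype=int))
        peds = [sib_pair()]
        res = gene_drop(peds, panel, seed=0)
        assert np.all(res.genotypes["S1"] == 0)

    def test_founder_allele_frequency(self):
        panel = generate_synthetic_panel(n_markers=1, n_haplotypes=500,
                                         maf_range=(0.3, 0.3), seed=5)
        f = panel.frequencies()[0]
        peds = replicate_structures([sib_pair()], 2000)
        res = gene_drop(peds, panel, seed=6)
        founder_alleles = []
        for ped in peds:
            g = res.genotypes[ped.family_id]
            founder_alleles.extend(g[:2, 0])  # both parents
        phat = np.mean(founder_alleles) / 2.0
        se = np.sqrt(f * (1 - f) / (2 * len(founder_alleles)))
        assert abs(phat - f) < 3 * se

    def test_parent_offspring_genotype_correlation(self):
        panel = generate_synthetic_panel(n_markers=1, n_haplotypes=1000,
                                         maf_range=(0.3, 0.3), seed=7)
        trio = preset_pedigrees("nuclear75")[0]
        peds = replicate_structures([trio], 4000)
        res = gene_drop(peds, panel, seed=8, recomb=False)
        parent, child = [], []
        for ped in peds:
            g = res.genotypes[ped.family_id]
            parent.append(g[0, 0])
            child.append(g[2, 0])
        r = np.corrcoef(parent, child)[0, 1]
        # additive genotype correlation equals twice the kinship (0.5)
        assert abs(r - 0.5) < 3.0 / np.sqrt(len(parent))

    def test_recombination_switches_descent(self):
        # two far-apart markers: descent labels must sometimes differ
        panel = HaplotypePanel(["a", "b"], np.array([1e6, 3.0e8]),
                               np.random.default_rng(0).integers(
                                   0, 2, size=(50, 2)))
        peds = replicate_structures([sib_pair()], 300)
        res = gene_drop(peds, panel, seed=9, recomb=True)
        switched = 0
        for ped in peds:
            lab = res.labels[ped.family_id]
            kid = ped.index_of("s1")
            if lab[kid, 0, 0] != lab[kid, 0, 1]:
                switched += 1
        assert switched > 0

    def test_ibd_founders_and_duplicates(self):
        lab = np.array([[[0], [1]], [[2], [3]], [[0], [1]]])
        P = true_ibd_matrix(sib_pair(), lab, 0)  # only shapes matter here
        assert P.shape == (3, 3)
        assert P[0, 1] == 0.0       # distinct founder labels
        assert P[0, 2] == 1.0       # duplicated label pair: MZ-like
        assert np.all(np.diag(P) == 1.0)

    def test_full_sib_mean_ibd(self):
        panel = HaplotypePanel(["m"], np.array([1.0]),
                               np.zeros((4, 1), dtype=int))
        peds = replicate_structures([sib_pair()], 3000)
        res = gene_drop(peds, panel, seed=10)
        pis = []
        for ped in peds:
            P = true_ibd_matrix(ped, res.labels[ped.family_id], 0)
            pis.append(P[ped.index_of("s1"), ped.index_of("s2")])
        se = np.std(pis) / np.sqrt(len(pis))
        assert abs(np.mean(pis) - 0.5) < 3 * se


class TestPhenotypes:
    def _rels(self, peds, comps):
        out = {}
        for ped in peds:
            rel = {}
            for c in comps:
                rel[c] = (np.eye(ped.size) if c == "e"
                          else 2 * kinship_matrix(ped))
            out[ped.family_id] = rel
        return out

    def test_sib_covariance_single_trait(self):
        mm = build_model_matrices(parse_model("y ~ <p,e>\n"))
        theta = mm.theta_from_dict({"mean(y)": 0.0}, default=1.0)
        peds = replicate_structures([sib_pair()], 4000)
        Y = simulate_phenotypes(peds, mm, theta, self._rels(peds, ["p", "e"]),
                                seed=11, assign=False)
        s1 = np.array([Y[p.family_id][2, 0] for p in peds])
        s2 = np.array([Y[p.family_id][3, 0] for p in peds])
        cov = np.cov(s1, s2)[0, 1]
        assert abs(cov - 0.5) < 3 * np.sqrt(2.0 / len(peds)) * 1.5

    def test_association_marginal_variance(self, example_models):
        mm = example_models["association"]
        cfg = SimulationConfig(model=mm, theta_true=1.0,
                               structures="nuclear75", n_pedigrees=300,
                               seed=12)
        data = simulate_dataset(cfg)
        y, x = [], []
        for ped in data.peds:
            for m in ped.members:
                y.append(m.phenotypes["P1"])
                x.append(m.genotypes["rs6040343"])
        y, x = np.array(y), np.array(x)
        # var(P1) = slope^2 var(g) + V_p[0,0] + V_e[0,0] = var(g) + 3
        expect = np.var(x) + 3.0
        assert np.var(y) == pytest.approx(expect, rel=0.1)

    def test_zero_variance_components_deterministic(self):
        mm = build_model_matrices(parse_model("y ~ age + <e>\n"))
        theta = mm.theta_from_dict({"var(y,e)": 0.0, "mean(y)": 0.5,
                                    "coef(age,y)": 2.0})
        peds = replicate_structures([sib_pair()], 5)
        for ped in peds:
            for m in ped.members:
                m.covariates["age"] = 1.5
        Y = simulate_phenotypes(peds, mm, theta,
                                self._rels(peds, ["e"]), seed=13,
                                assign=False)
        for ped in peds:
            assert np.allclose(Y[ped.family_id], 0.5 + 2.0 * 1.5)

    def test_indefinite_component_rejected(self):
        mm = build_model_matrices(parse_model("y ~ <e>\n"))
        theta = mm.theta_from_dict({"var(y,e)": -0.5})
        peds = replicate_structures([sib_pair()], 2)
        with pytest.raises(ConfigurationError, match="PSD"):
            simulate_phenotypes(peds, mm, theta, self._rels(peds, ["e"]),
                                seed=0)


class TestAscertainment:
    def test_threshold_calibrates_prevalence(self):
        mm = build_model_matrices(parse_model("y ~ <p,e>\n"))
        theta = mm.theta_from_dict({"mean(y)": 0.0})
        thr = affection_threshold(mm, theta, {}, prevalence=0.05,
                                  n_ref=200_000, seed=14)
        # population y ~ N(0, 2): threshold should be the 95% quantile
        from scipy import stats
        assert thr == pytest.approx(stats.norm.ppf(0.95) * np.sqrt(2.0),
                                    abs=0.03)

    def test_probability_one_keeps_every_affected_family(self):
        rng = np.random.default_rng(15)
        peds = replicate_structures([sib_pair()], 200)
        for ped in peds:
            for m in ped.members:
                m.phenotypes["y"] = float(rng.normal())
        kept = apply_ascertainment(peds, 0.2, 1.0, threshold=1.0, seed=16)
        for ped in peds:
            affected = any(m.phenotypes["y"] > 1.0 for m in ped.members)
            assert (ped in kept) == affected
        for ped in kept:
            assert sum(m.proband for m in ped.members) == 1

    def test_first_candidate_becomes_proband(self):
        ped = sib_pair()
        vals = [5.0, 5.0, 5.0, 5.0]
        for m, v in zip(ped.members, vals):
            m.phenotypes["y"] = v
        kept = apply_ascertainment([ped], 0.2, 1.0, threshold=1.0, seed=17)
        assert kept[0].proband_index == 0

    def test_rare_disease_retention_below_half(self):
        rng = np.random.default_rng(18)
        peds = replicate_structures([sib_pair()], 300)
        for ped in peds:
            for m in ped.members:
                m.phenotypes["y"] = float(rng.normal())
        from scipy import stats
        thr = stats.norm.ppf(1 - 0.001)  # prevalence 0.1%
        kept = apply_ascertainment(peds, 0.001, 0.05, threshold=thr, seed=19)
        assert len(kept) < 150

    def test_dataset_determinism(self):
        cfg = SimulationConfig(model="y ~ <p,e>\n", theta_true=1.0,
                               structures="extended5", n_pedigrees=10,
                               seed=20)
        d1 = simulate_dataset(cfg)
        d2 = simulate_dataset(cfg)
        for p1, p2 in zip(d1.peds, d2.peds):
            assert p1.family_id == p2.family_id
            for m1, m2 in zip(p1.members, p2.members):
                assert m1.phenotypes == m2.phenotypes
                assert m1.genotypes == m2.genotypes

    def test_ascertained_dataset_counts(self):
        cfg = SimulationConfig(
            model="y ~ <p,e>\n", theta_true=1.0, structures="nuclear75",
            n_pedigrees=30,
            ascertainment={"prevalence": 0.1, "proband_probability": 0.5,
                           "n_ref": 20_000})
        data = simulate_dataset(cfg, seed=21)
        assert len(data.peds) == 30
        assert data.n_simulated > 30
        for ped in data.peds:
            assert ped.proband_index is not None
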