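"""Pedigree IO, validation, kinship, and relationship matrices."""

import numpy as np
import pytest

from pedsem import (ConfigurationError, IbdStore, Individual, Pedigree,
                    PedigreeFormatError, PedigreeStructureError,
                    kinship_matrix, read_ibd_file, read_pedigree_csv,
                    relationship_matrix, validate_pedigree,
                    write_pedigree_csv)
from pedsem.simulator import preset_pedigrees, replicate_structures

from conftest import make_trio, random_pedigree, sib_pair


class TestReadWrite:
    def test_minimal_trio(self, trio_csv):
        peds = read_pedigree_csv(trio_csv)
        assert len(peds) == 1
        ped = peds[0]
        assert ped.size == 3
        kid = ped.members[ped.index_of("kid")]
        assert not kid.is_founder
        assert kid.proband
        assert ped.members[ped.index_of("dad")].is_founder
        assert ped.column("P1")[ped.index_of("kid")] == pytest.approx(2.1)

    def test_missing_mandatory_column(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("family,id,father\nF1,a,0\n")
        with pytest.raises(PedigreeFormatError, match="mother"):
            read_pedigree_csv(p)

    def test_unknown_parent_strict_vs_default(self, tmp_path):
        p = tmp_path / "orphan.csv"
        p.write_text("family,id,father,mother,sex\nF1,kid,ghost,mom,1\n"
                     "F1,mom,0,0,2\n")
        with pytest.raises(PedigreeStructureError, match="ghost"):
            read_pedigree_csv(p, strict=True)
        with pytest.warns(UserWarning, match="auto-created"):
            peds = read_pedigree_csv(p)
        assert peds[0].size == 3  # ghost founder created

    def test_half_specified_parents_rejected(self, tmp_path):
        p = tmp_path / "half.csv"
        p.write_text("family,id,father,mother\nF1,kid,dad,0\nF1,dad,0,0\n")
        with pytest.raises(PedigreeStructureError, match="one parent"):
            read_pedigree_csv(p)

    def test_cyclic_parentage_rejected(self, tmp_path):
        p = tmp_path / "cycle.csv"
        # a is its own grandparent through b
        p.write_text("family,id,father,mother,sex\n"
                     "F1,a,b,m,1\nF1,b,a,m,1\nF1,m,0,0,2\n")
        with pytest.raises(PedigreeStructureError, match="cyclic"):
            read_pedigree_csv(p)

    def test_members_topologically_sorted(self, tmp_path):
        p = tmp_path / "rev.csv"
        p.write_text("family,id,father,mother\nF1,kid,dad,mom\n"
                     "F1,dad,0,0\nF1,mom,0,0\n")
        ped = read_pedigree_csv(p)[0]
        order = [m.person_id for m in ped.members]
        assert order.index("dad") < order.index("kid")
        assert order.index("mom") < order.index("kid")

    def test_genotype_columns_recognized_and_validated(self, tmp_path):
        p = tmp_path / "geno.csv"
        p.write_text("family,id,father,mother,rs123,height\n"
                     "F1,a,0,0,2,1.8\nF1,b,0,0,1,1.6\n")
        ped = read_pedigree_csv(p)[0]
        a = ped.members[ped.index_of("a")]
        assert a.genotypes["rs123"] == 2
        assert a.phenotypes["height"] == pytest.approx(1.8)
        p.write_text("family,id,father,mother,rs123\nF1,a,0,0,3\n")
        with pytest.raises(PedigreeFormatError, match="allele count"):
            read_pedigree_csv(p)

    def test_round_trip(self, tmp_path, trio_csv):
        peds = read_pedigree_csv(trio_csv)
        out = tmp_path / "out.csv"
        write_pedigree_csv(peds, out)
        peds2 = read_pedigree_csv(out)
        assert len(peds2) == len(peds)
        for a, b in zip(peds[0].members, peds2[0].members):
            assert a.person_id == b.person_id
            assert a.father_id == b.father_id
            assert a.sex == b.sex
            assert a.proband == b.proband
            assert a.phenotypes == b.phenotypes

    def test_nuclear_preset_totals(self):
        peds = preset_pedigrees("nuclear75")
        assert len(peds) == 75
        assert sum(p.size for p in peds) == 477
        sib_sizes = {p.size - 2 for p in peds}
        assert min(sib_sizes) == 4 and max(sib_sizes) == 11

    def test_extended_preset_totals(self):
        peds = preset_pedigrees("extended5")
        assert len(peds) == 5
        assert sum(p.size for p in peds) == 50
        assert all(p.size == 10 for p in peds)


class TestValidate:
    def test_valid_trio_clean(self, trio):
        assert validate_pedigree(trio) == []

    def test_two_probands_warns(self):
        ped = make_trio()
        ped.members[0].proband = True
        ped.members[2].proband = True
        diags = validate_pedigree(ped)
        assert len(diags) == 1
        assert diags[0].severity == "warning"
        assert "proband" in diags[0].message

    def test_own_ancestor_is_error(self):
        # constructed directly so the cycle reaches validation
        ped = Pedigree("F1", [
            Individual("m", sex="female"),
            Individual("a", "b", "m", sex="male"),
            Individual("b", "a", "m", sex="male"),
        ])
        diags = validate_pedigree(ped)
        assert any(d.severity == "error" and "cycl" in d.message
                   for d in diags)

    def test_sex_inconsistency(self):
        ped = Pedigree("F1", [
            Individual("dad", sex="female"),  # listed as father below
            Individual("mom", sex="female"),
            Individual("kid", "dad", "mom"),
        ])
        diags = validate_pedigree(ped)
        assert any(d.severity == "error" and "sex" in d.message for d in diags)


class TestKinship:
    @pytest.mark.parametrize("pair,expected", [
        (("f", "s1"), 0.25),    # parent-offspring
        (("s1", "s2"), 0.25),   # full sibs
    ])
    def test_textbook_values(self, pair, expected):
        ped = sib_pair()
        K = kinship_matrix(ped)
        i, j = ped.index_of(pair[0]), ped.index_of(pair[1])
        assert K[i, j] == pytest.approx(expected)

    def test_half_sibs_and_cousins(self):
        ped = Pedigree("H", [
            Individual("f", sex="male"), Individual("m1", sex="female"),
            Individual("m2", sex="female"),
            Individual("h1", "f", "m1"), Individual("h2", "f", "m2"),
            Individual("u1", sex="male"), Individual("u2", sex="female"),
            Individual("c1", "u1", "h1"),
            Individual("c2", "u2", "h2"),
        ])
        ped.members[ped.index_of("h1")].sex = "female"
        ped.members[ped.index_of("h2")].sex = "female"
        ped.members[ped.index_of("u2")].sex = "male"
        K = kinship_matrix(ped)
        assert K[ped.index_of("h1"), ped.index_of("h2")] == pytest.approx(0.125)
        # children of half-sibs are half first cousins: phi = 1/32;
        # full first cousins need full-sib parents
        full = Pedigree("C", [
            Individual("f", sex="male"), Individual("m", sex="female"),
            Individual("s1", "f", "m", "male"),
            Individual("s2", "f", "m", "female"),
            Individual("w", sex="female"), Individual("h", sex="male"),
            Individual("c1", "s1", "w"), Individual("c2", "h", "s2"),
        ])
        K = kinship_matrix(full)
        assert K[full.index_of("c1"), full.index_of("c2")] == pytest.approx(0.0625)

    def test_inbred_full_sib_mating(self):
        ped = Pedigree("I", [
            Individual("f", sex="male"), Individual("m", sex="female"),
            Individual("s1", "f", "m", "male"),
            Individual("s2", "f", "m", "female"),
            Individual("kid", "s1", "s2"),
        ])
        K = kinship_matrix(ped)
        assert K[ped.index_of("kid"), ped.index_of("kid")] == pytest.approx(0.625)

    def test_loop_pedigree_self_kinship(self):
        # cousin mating in the extended preset: offspring are inbred
        e4 = preset_pedigrees("extended5")[3]
        K = kinship_matrix(e4)
        d1 = e4.index_of("d1")
        assert K[d1, d1] == pytest.approx(0.5 + 0.0625 / 2)

    def test_random_pedigrees_properties(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            ped = random_pedigree(rng, n_members=int(rng.integers(6, 14)))
            K = kinship_matrix(ped)
            assert np.allclose(K, K.T)
            evals = np.linalg.eigvalsh(2 * K)
            assert evals.min() > -1e-10  # 2*Phi is PSD
            for i, m in enumerate(ped.members):
                if m.is_founder:
                    assert K[i, i] == pytest.approx(0.5)
            # founder pairs are unrelated
            f = [i for i, m in enumerate(ped.members) if m.is_founder]
            for a in f:
                for b in f:
                    if a != b:
                        assert K[a, b] == 0.0

    def test_gene_drop_monte_carlo_oracle(self):
        """Kinship equals the gene-drop probability of allele IBD."""
        rng = np.random.default_rng(7)
        ped = random_pedigree(rng, n_members=10)
        K = kinship_matrix(ped)
        reps = 200_000
        copies = replicate_structures([ped], 1)[0]
        # vectorized single-locus drop across replicates
        parents = ped.parent_indices()
        n = ped.size
        labs = np.empty((reps, n, 2), dtype=np.int64)
        for i in range(n):
            if parents[i] is None:
                labs[:, i, 0] = 2 * i
                labs[:, i, 1] = 2 * i + 1
            else:
                for h, par in enumerate(parents[i]):
                    pick = rng.integers(0, 2, size=reps)
                    labs[:, i, h] = labs[np.arange(reps), par, pick]
        # random allele from i vs random allele from j
        pairs = [(1, n - 1), (0, n - 1), (n - 2, n - 1)]
        for (i, j) in pairs:
            ai = labs[np.arange(reps), i, rng.integers(0, 2, reps)]
            aj = labs[np.arange(reps), j, rng.integers(0, 2, reps)]
            phat = np.mean(ai == aj)
            se = np.sqrt(max(phat * (1 - phat), 1e-6) / reps)
            assert abs(phat - K[i, j]) < max(3 * se, 1e-3), (i, j)


class TestRelationshipMatrices:
    def test_environment_identity(self):
        ped = sib_pair()
        assert np.array_equal(relationship_matrix(ped, "environment"),
                              np.eye(4))

    def test_polygenic_sib_pair(self):
        ped = sib_pair()
        R = relationship_matrix(ped, "polygenic")
        i, j = ped.index_of("s1"), ped.index_of("s2")
        assert R[i, i] == pytest.approx(1.0)
        assert R[i, j] == pytest.approx(0.5)

    def test_household_defaults_to_whole_family(self):
        ped = sib_pair()
        assert np.array_equal(relationship_matrix(ped, "household"),
                              np.ones((4, 4)))

    def test_household_groups(self):
        ped = sib_pair()
        for m in ped.members:
            m.household = "h1" if m.person_id in ("f", "m") else "h2"
        R = relationship_matrix(ped, "household")
        assert R[ped.index_of("f"), ped.index_of("m")] == 1.0
        assert R[ped.index_of("f"), ped.index_of("s1")] == 0.0

    def test_linkage_requires_ibd(self):
        with pytest.raises(ConfigurationError):
            relationship_matrix(sib_pair(), "linkage")


class TestIbd:
    def test_symmetric_lookup(self):
        store = IbdStore()
        store.set("F1", "rs1", "a", "b", 0.5)
        assert store.get("F1", "rs1", "b", "a") == 0.5

    def test_range_error(self):
        store = IbdStore()
        with pytest.raises(PedigreeFormatError, match=r"outside \[0, 1\]"):
            store.set("F1", "rs1", "a", "b", 1.3)

    def test_read_write_and_matrix(self, tmp_path):
        path = tmp_path / "ibd.csv"
        path.write_text("family,marker,id1,id2,pi\n"
                        "S1,rs1,f,m,0.0\nS1,rs1,f,s1,0.5\nS1,rs1,f,s2,0.5\n"
                        "S1,rs1,m,s1,0.5\nS1,rs1,m,s2,0.5\nS1,rs1,s1,s2,1.0\n")
        store = read_ibd_file(path)
        ped = sib_pair()
        R = store.matrix(ped, "rs1")
        assert np.allclose(np.diag(R), 1.0)
        assert R[ped.index_of("s1"), ped.index_of("s2")] == 1.0
        assert np.allclose(R, R.T)

    def test_missing_pair_is_error(self):
        store = IbdStore()  # empty
        with pytest.raises(ConfigurationError, match="no IBD value"):
            store.matrix(sib_pair(), "rs1")

    def test_missing_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("family,marker,id1,id2\nF1,rs1,a,b\n")
        with pytest.raises(PedigreeFormatError, match="pi"):
            read_ibd_file(path)
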