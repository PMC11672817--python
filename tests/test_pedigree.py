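"""Pedigree parsing, ordering, inbreeding and relationship-matrix algebra."""

import numpy as np
import pytest

import daysopen as d
from daysopen import pedigree as pedmod

from .conftest import oracle_A, random_pedigree_triples


class TestParsing:
    def test_three_row_parse(self, tmp_path):
        p = tmp_path / "ped.txt"
        p.write_text("1 0 0\n2 0 0\n3 1 2\n")
        ped = d.read_pedigree(p)
        assert ped.n == 3
        assert len(ped.founders) == 2
        assert not ped.is_founder(ped.id_map[3])

    def test_comma_delimited_with_header(self, tmp_path):
        p = tmp_path / "ped.csv"
        p.write_text("animal,sire,dam\nA,0,0\nB,0,0\nC,A,B\n")
        ped = d.read_pedigree(p)
        assert ped.n == 3
        assert ped.id_map["A"] < ped.id_map["C"]

    def test_self_parent_is_cycle(self):
        with pytest.raises(d.PedigreeError, match="cycle"):
            d.from_triples([(3, 3, 2), (2, 0, 0)])

    def test_mutual_ancestry_is_cycle(self):
        with pytest.raises(d.PedigreeError, match="cycle"):
            d.from_triples([(1, 2, 0), (2, 1, 0)])

    def test_duplicate_animal_id(self):
        with pytest.raises(d.PedigreeError, match="duplicate"):
            d.from_triples([(1, 0, 0), (1, 0, 0)])

    def test_progeny_listed_before_parent_gets_reordered(self):
        # progeny 10 listed first; topological order must place parents first
        ped = d.from_triples([(10, 7, 8), (7, 0, 0), (8, 0, 0)])
        i10, i7, i8 = ped.id_map[10], ped.id_map[7], ped.id_map[8]
        assert i7 < i10 and i8 < i10
        assert sorted([i10, i7, i8]) == [1, 2, 3]

    def test_renumbering_round_trips(self, make_random_pedigree):
        ped = make_random_pedigree(5, 80)
        back = ped.to_external(ped.to_internal(ped.original_ids))
        assert back == ped.original_ids

    def test_implicit_parents_become_founders(self):
        ped = d.from_triples([(5, 3, 4)])
        assert ped.n == 3
        assert len(ped.founders) == 2


class TestInbreeding:
    def test_founders_have_zero_F(self):
        ped = d.from_triples([(i, 0, 0) for i in range(1, 6)])
        assert np.all(d.inbreeding(ped) == 0)

    def test_full_sib_mating_gives_quarter(self):
        # progeny of two full sibs whose parents are unrelated: F = 0.25
        ped = d.from_triples([(1, 0, 0), (2, 0, 0), (3, 1, 2), (4, 1, 2), (5, 3, 4)])
        F = d.inbreeding(ped)
        assert F[ped.id_map[5] - 1] == pytest.approx(0.25, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_tabular_oracle_on_random_pedigrees(self, seed, make_random_pedigree):
        ped = make_random_pedigree(seed, 50)
        F = d.inbreeding(ped)
        A = oracle_A(ped.sire, ped.dam)
        np.testing.assert_allclose(F, np.diag(A) - 1.0, atol=1e-12)

    def test_mean_inbreeding(self):
        ped = d.from_triples([(1, 0, 0), (2, 0, 0), (3, 1, 2), (4, 1, 2), (5, 3, 4)])
        assert d.mean_inbreeding(ped, ped.founders) == 0.0
        assert d.mean_inbreeding(ped, [ped.id_map[5]]) == pytest.approx(0.25)
        with pytest.raises(ValueError, match="empty"):
            d.mean_inbreeding(ped, [])


class TestRelationshipMatrix:
    def test_trio(self):
        ped = d.from_triples([(1, 0, 0), (2, 0, 0), (3, 1, 2)])
        A = d.build_A(ped)
        assert np.all(np.diag(A) == 1.0)
        i3 = ped.id_map[3] - 1
        for p in (1, 2):
            assert A[ped.id_map[p] - 1, i3] == 0.5

    def test_single_founder(self):
        A = d.build_A(d.from_triples([(1, 0, 0)]))
        np.testing.assert_array_equal(A, [[1.0]])

    def test_psd_on_random_pedigree(self, make_random_pedigree):
        ped = make_random_pedigree(3, 20)
        A = d.build_A(ped)
        assert np.linalg.eigvalsh(A).min() >= -1e-10

    def test_dense_guard(self, monkeypatch, make_random_pedigree):
        monkeypatch.setattr(pedmod, "DENSE_A_LIMIT", 10)
        ped = make_random_pedigree(0, 30)
        with pytest.raises(d.PedigreeError, match="sparse"):
            d.build_A(ped)

    def test_diag_minus_one_equals_inbreeding(self, make_random_pedigree):
        ped = make_random_pedigree(11, 120)
        np.testing.assert_allclose(np.diag(d.build_A(ped)) - 1.0,
                                   d.inbreeding(ped), atol=1e-12)

    def test_founders_only_inverse_is_identity(self):
        ped = d.from_triples([(i, 0, 0) for i in range(1, 8)])
        Ainv = d.build_A_inverse(ped).toarray()
        np.testing.assert_allclose(Ainv, np.eye(7), atol=1e-14)

    @pytest.mark.parametrize("seed,n", [(0, 50), (1, 50), (2, 200), (3, 120)])
    def test_inverse_against_dense_oracle(self, seed, n, make_random_pedigree):
        ped = make_random_pedigree(seed, n)
        A = d.build_A(ped)
        Ainv = d.build_A_inverse(ped)
        err = np.abs(A @ Ainv.toarray() - np.eye(n)).max()
        assert err < 1e-8

    def test_inbreeding_adjustment_matters(self):
        # inbred pedigree: ignoring parental F must break the inverse
        triples = [(1, 0, 0), (2, 0, 0), (3, 1, 2), (4, 1, 2), (5, 3, 4), (6, 5, 4)]
        ped = d.from_triples(triples)
        A = d.build_A(ped)
        good = np.abs(A @ d.build_A_inverse(ped).toarray() - np.eye(6)).max()
        bad = np.abs(
            A @ d.build_A_inverse(ped, F=np.zeros(6)).toarray() - np.eye(6)
        ).max()
        assert good < 1e-8
        assert bad > 1e-3


def test_product_identity_property_over_many_seeds(make_random_pedigree):
    # A * A^-1 = I within 1e-8 on random pedigrees up to 200 animals
    rng = np.random.default_rng(99)
    for _ in range(10):
        n = int(rng.integers(5, 200))
        ped = d.from_triples(random_pedigree_triples(rng, n))
        err = np.abs(d.build_A(ped) @ d.build_A_inverse(ped).toarray() - np.eye(n)).max()
        assert err < 1e-8


def test_pruning_preserves_relationships_of_kept_animals():
    # pruning to phenotyped animals + ancestors must not change their F
    ped = d.from_triples([(1, 0, 0), (2, 0, 0), (3, 1, 2), (4, 1, 2),
                          (5, 3, 4), (6, 0, 0), (7, 6, 0)])
    pruned = d.prune_to_phenotyped(ped, [5])
    assert pruned.n == 5  # animal 5 and its 4 ancestors; 6, 7 dropped
    F_full = d.inbreeding(ped)
    F_pruned = d.inbreeding(pruned)
    assert F_pruned[pruned.id_map[5] - 1] == F_full[ped.id_map[5] - 1]
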