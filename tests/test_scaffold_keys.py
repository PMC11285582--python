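"""The 32-key registry, SK distance closed forms, ordering and dedup."""

import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hcase.chem import MoleculeRecord, Scaffold, extract_bms
from hcase.scaffold_keys import (
    KEY_NAMES,
    N_KEYS,
    SKError,
    SKVector,
    ScaffoldRecord,
    compute_sk,
    dedup_by_sk,
    sk_distance,
    sort_scaffolds,
)


def sk_of(smiles):
    scaffold = extract_bms(MoleculeRecord(id=smiles, smiles=smiles))
    return compute_sk(scaffold)


def key(smiles, name):
    return sk_of(smiles).keys[KEY_NAMES.index(name)]


class TestKeyRegistry:
    # hand-counted values on small scaffolds
    @pytest.mark.parametrize(
        "smiles,name,expected",
        [
            ("c1ccccc1", "n_heavy_atoms", 6),
            ("c1ccccc1", "n_ring_atoms", 6),
            ("c1ccccc1", "n_aromatic_rings", 1),
            ("c1ccccc1", "n_linker_bonds", 0),
            ("c1ccc(-c2ccccc2)cc1", "n_heavy_atoms", 12),  # biphenyl
            ("c1ccc(-c2ccccc2)cc1", "n_linker_bonds", 1),
            ("c1ccc(-c2ccccc2)cc1", "n_ring_systems", 2),
            ("c1ccc(-c2ccccc2)cc1", "n_branch_atoms", 2),
            ("c1ccc2ccccc2c1", "n_fusion_atoms", 2),  # naphthalene
            ("c1ccc2ccccc2c1", "n_ring_systems", 1),
            ("c1ccc2ccccc2c1", "largest_ring_system_size", 10),
            ("c1ccncc1", "n_ring_nitrogen", 1),  # pyridine
            ("c1ccncc1", "n_aromatic_heteroatoms", 1),
            ("C1COCCN1", "n_heteroatoms", 2),  # morpholine
            ("C1COCCN1", "n_ring_oxygen", 1),
            ("C1COCCN1", "n_aromatic_atoms", 0),
            ("O=C1CCCCC1", "n_exocyclic_double_atoms", 1),  # cyclohexanone
            ("O=C1CCCCC1", "n_linker_heteroatoms", 1),
            ("O=C1CCCCC1", "n_double_bonds", 1),
            ("C1CCC2(CC1)CCCC2", "n_spiro_atoms", 1),  # spiro[4.5]decane
            ("C1CCC2(CC1)CCCC2", "smallest_ring_size", 5),
        ],
    )
    def test_hand_counted_keys(self, smiles, name, expected):
        assert key(smiles, name) == expected

    def test_deterministic_and_integral(self):
        a, b = sk_of("c1ccc2ncccc2c1"), sk_of("c1ccc2ncccc2c1")
        assert a.keys == b.keys
        assert all(isinstance(k, int) and k >= 0 for k in a.keys)

    def test_size_first_ordering(self):
        # benzene sorts before naphthalene: fewer atoms dominates
        assert sk_of("c1ccccc1").keys < sk_of("c1ccc2ccccc2c1").keys

    def test_acyclic_rejected(self):
        with pytest.raises(SKError):
            compute_sk(Scaffold(smiles="CCCC", inchikey="x"))


class TestDistance:
    def test_zero_iff_identical(self):
        v = sk_of("c1ccncc1")
        assert sk_distance(v, v) == 0.0

    @pytest.mark.parametrize("n", range(1, N_KEYS + 1))
    def test_unit_difference_contributes_inverse_index(self, n):
        a = [3] * N_KEYS
        b = list(a)
        b[n - 1] += 1
        assert sk_distance(a, b) == pytest.approx(1.0 / n)

    def test_worked_value_cubed_difference(self):
        # difference of 9 at key 4: sqrt(9^3)/4 = 27/4
        a = [0] * N_KEYS
        b = list(a)
        b[3] = 9
        assert sk_distance(a, b) == pytest.approx(6.75)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.integers(0, 40), min_size=N_KEYS, max_size=N_KEYS),
        st.lists(st.integers(0, 40), min_size=N_KEYS, max_size=N_KEYS),
    )
    def test_symmetric_nonnegative(self, a, b):
        d = sk_distance(a, b)
        assert d >= 0.0
        assert d == pytest.approx(sk_distance(b, a))
        assert (d == 0.0) == (a == b)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            sk_distance([0] * N_KEYS, [0] * (N_KEYS - 1))


def make_record(keys, inchikey, smiles="X"):
    return ScaffoldRecord(
        scaffold=Scaffold(smiles=smiles, inchikey=inchikey),
        sk=SKVector(keys=tuple(keys), inchikey=inchikey),
    )


class TestSorting:
    def records(self, space):
        return [ScaffoldRecord(r.scaffold, r.sk) for r in space.scaffolds]

    def test_ranks_contiguous_and_permutation_invariant(self, space):
        base = self.records(space)
        ranked = sort_scaffolds(base)
        assert [r.rank for r in ranked] == list(range(1, len(base) + 1))
        shuffled = list(base)
        random.Random(0).shuffle(shuffled)
        assert sort_scaffolds(shuffled) == ranked
        assert sort_scaffolds(list(reversed(base))) == ranked

    def test_idempotent_on_sorted_input(self, space):
        ranked = sort_scaffolds(self.records(space))
        assert sort_scaffolds([ScaffoldRecord(r.scaffold, r.sk) for r in ranked]) == ranked

    def test_inchikey_breaks_sk_ties(self):
        a = make_record([1] * N_KEYS, "BBBB", smiles="a")
        b = make_record([1] * N_KEYS, "AAAA", smiles="b")
        ranked = sort_scaffolds([a, b])
        assert ranked[0].scaffold.inchikey == "AAAA"
        assert ranked[0].rank == 1 and ranked[1].rank == 2

    def test_residual_tie_warns_and_keeps_input_order(self):
        a = make_record([1] * N_KEYS, "AAAA", smiles="first")
        b = make_record([1] * N_KEYS, "AAAA", smiles="second")
        with pytest.warns(UserWarning, match="residual"):
            ranked = sort_scaffolds([a, b])
        assert ranked[0].scaffold.smiles == "first"


class TestDedup:
    def test_distinct_input_unchanged(self, space):
        records = [ScaffoldRecord(r.scaffold, r.sk) for r in space.scaffolds]
        assert dedup_by_sk(records) == records

    def test_duplicate_collapses(self):
        a = make_record([2] * N_KEYS, "AAAA")
        out = dedup_by_sk([a, a])
        assert out == [a]

    def test_grouped_vectors_counted_by_brute_force(self):
        vectors = [[i] + [0] * (N_KEYS - 1) for i in range(7)]
        vectors += [[3] + [0] * (N_KEYS - 1)] * 3  # three extra copies of one
        records = [make_record(v, f"K{i:02d}") for i, v in enumerate(vectors)]
        expected_groups = {tuple(v) for v in vectors}
        assert len(dedup_by_sk(records)) == len(expected_groups)

    def test_representative_is_smallest_inchikey(self):
        recs = [
            make_record([5] * N_KEYS, "CCCC"),
            make_record([5] * N_KEYS, "AAAA"),
            make_record([5] * N_KEYS, "BBBB"),
        ]
        assert dedup_by_sk(recs)[0].scaffold.inchikey == "AAAA"

    def test_dedup_and_sort_commute(self):
        rng = random.Random(3)
        records = [
            make_record([rng.randint(0, 2)] * N_KEYS, f"K{i:02d}") for i in range(12)
        ]
        a = sort_scaffolds(dedup_by_sk(records))
        b = dedup_by_sk(sort_scaffolds(records))
        assert [r.scaffold.inchikey for r in a] == [r.scaffold.inchikey for r in b]
        assert [r.sk.keys for r in a] == [r.sk.keys for r in b]
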