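"""Scaffold-Keys: a 32-integer descriptor vector for Bemis-Murcko scaffolds.

The Scaffold-Key (SK) of a scaffold is a fixed-length vector of simple,
integer-valued structural counts ordered by decreasing importance: overall
size first, then ring/linker architecture, then chemical composition, then
finer electronic features. Sorting scaffolds by this vector (key 1 most
significant) yields the size/complexity/composition progression a
medicinal chemist would draw by hand — all benzenes before naphthalenes,
carbocycles before their aza analogues of equal size, and so on.

The registry below defines each key as a pure function of an RDKit Mol.
The original rule set circulates in prose with acknowledged ambiguities;
each entry here documents the exact count implemented so the vector is
reproducible from this file alone. The distance between two scaffolds i, j
weights early (more significant) keys more heavily:

    d_SK(i, j) = sum_{n=1..32} sqrt(|SK_i(n) - SK_j(n)|^3) / n
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence

import numpy as np
from rdkit import Chem

from .chem import Scaffold

N_KEYS = 32


class SKError(ValueError):
    """Raised when a Scaffold-Key cannot be computed for a scaffold."""


@dataclass(frozen=True)
class SKVector:
    """The 32 integer keys of one scaffold, plus the InChI-Key tie-breaker.

    The InChI-Key is *not* part of the distance (Eq. below ignores it);
    it only disambiguates the total ordering of scaffolds whose 32 keys
    coincide.
    """

    keys: tuple
    inchikey: Optional[str] = None

    def __post_init__(self):
        if len(self.keys) != N_KEYS:
            raise ValueError(f"SKVector needs exactly {N_KEYS} keys, got {len(self.keys)}")
        if any(k < 0 for k in self.keys):
            raise ValueError("Scaffold-Key entries must be non-negative")


@dataclass(frozen=True)
class ScaffoldRecord:
    """A scaffold with its SK vector and, once sorted, its 1-based rank."""

    scaffold: Scaffold
    sk: SKVector
    rank: Optional[int] = None


# --- individual key functions -------------------------------------------

def _ring_info(mol):
    return mol.GetRingInfo()


def _n_heavy(mol):  # key 1
    return mol.GetNumHeavyAtoms()


def _n_ring_atoms(mol):  # key 2
    return sum(1 for a in mol.GetAtoms() if a.IsInRing())


def _n_linker_atoms(mol):  # key 3
    return sum(1 for a in mol.GetAtoms() if not a.IsInRing())


def _n_linker_bonds(mol):  # key 4
    return sum(1 for b in mol.GetBonds() if not b.IsInRing())


def _n_rings(mol):  # key 5
    return _ring_info(mol).NumRings()


def _largest_ring(mol):  # key 6
    sizes = [len(r) for r in _ring_info(mol).AtomRings()]
    return max(sizes) if sizes else 0


def _smallest_ring(mol):  # key 7
    sizes = [len(r) for r in _ring_info(mol).AtomRings()]
    return min(sizes) if sizes else 0


def _n_aromatic_rings(mol):  # key 8
    ri = _ring_info(mol)
    return sum(
        1
        for ring in ri.BondRings()
        if all(mol.GetBondWithIdx(b).GetIsAromatic() for b in ring)
    )


def _n_aliphatic_rings(mol):  # key 9
    return _n_rings(mol) - _n_aromatic_rings(mol)


def _n_fusion_atoms(mol):  # key 10
    ri = _ring_info(mol)
    return sum(1 for a in mol.GetAtoms() if ri.NumAtomRings(a.GetIdx()) >= 2)


def _n_spiro_atoms(mol):  # key 11
    from rdkit.Chem import rdMolDescriptors

    return rdMolDescriptors.CalcNumSpiroAtoms(mol)


def _n_ring_branch_atoms(mol):  # key 12
    return sum(
        1
        for a in mol.GetAtoms()
        if sum(1 for b in a.GetBonds() if b.IsInRing()) >= 3
    )


def _is_het(atom):
    return atom.GetAtomicNum() not in (1, 6)


def _n_heteroatoms(mol):  # key 13
    return sum(1 for a in mol.GetAtoms() if _is_het(a))


def _n_ring_heteroatoms(mol):  # key 14
    return sum(1 for a in mol.GetAtoms() if _is_het(a) and a.IsInRing())


def _count_elem(mol, num, in_ring=None):
    out = 0
    for a in mol.GetAtoms():
        if a.GetAtomicNum() != num:
            continue
        if in_ring is None or a.IsInRing() == in_ring:
            out += 1
    return out


def _n_nitrogen(mol):  # key 15
    return _count_elem(mol, 7)


def _n_ring_nitrogen(mol):  # key 16
    return _count_elem(mol, 7, in_ring=True)


def _n_oxygen(mol):  # key 17
    return _count_elem(mol, 8)


def _n_ring_oxygen(mol):  # key 18
    return _count_elem(mol, 8, in_ring=True)


def _n_sulfur(mol):  # key 19
    return _count_elem(mol, 16)


def _n_ring_sulfur(mol):  # key 20
    return _count_elem(mol, 16, in_ring=True)


def _n_other_het(mol):  # key 21
    return sum(
        1 for a in mol.GetAtoms() if _is_het(a) and a.GetAtomicNum() not in (7, 8, 16)
    )


def _n_aromatic_atoms(mol):  # key 22
    return sum(1 for a in mol.GetAtoms() if a.GetIsAromatic())


def _n_aromatic_het(mol):  # key 23
    return sum(1 for a in mol.GetAtoms() if a.GetIsAromatic() and _is_het(a))


def _n_double_bonds(mol):  # key 24
    return sum(
        1 for b in mol.GetBonds() if b.GetBondType() == Chem.BondType.DOUBLE
    )


def _n_triple_bonds(mol):  # key 25
    return sum(
        1 for b in mol.GetBonds() if b.GetBondType() == Chem.BondType.TRIPLE
    )


def _n_exocyclic_double_atoms(mol):  # key 26
    out = 0
    for b in mol.GetBonds():
        if b.GetBondType() != Chem.BondType.DOUBLE or b.IsInRing():
            continue
        a1, a2 = b.GetBeginAtom(), b.GetEndAtom()
        if a1.IsInRing() != a2.IsInRing():
            out += 1
    return out


def _n_branch_atoms(mol):  # key 27
    return sum(1 for a in mol.GetAtoms() if a.GetDegree() >= 3)


def _n_deg4_atoms(mol):  # key 28
    return sum(1 for a in mol.GetAtoms() if a.GetDegree() >= 4)


def _ring_system_components(mol):
    """Connected components of the ring-bond graph (fused ring systems)."""
    ri = _ring_info(mol)
    rings = [set(r) for r in ri.AtomRings()]
    systems: list[set] = []
    for ring in rings:
        merged = ring
        rest = []
        for sys_ in systems:
            if sys_ & merged:
                merged = merged | sys_
            else:
                rest.append(sys_)
        systems = rest + [merged]
    return systems


def _n_ring_systems(mol):  # key 29
    return len(_ring_system_components(mol))


def _largest_ring_system(mol):  # key 30
    systems = _ring_system_components(mol)
    return max((len(s) for s in systems), default=0)


def _n_linker_heteroatoms(mol):  # key 31
    return sum(1 for a in mol.GetAtoms() if _is_het(a) and not a.IsInRing())


def _n_charged_atoms(mol):  # key 32
    return sum(1 for a in mol.GetAtoms() if a.GetFormalCharge() != 0)


#: The key registry: (name, description) -> counting function, in order of
#: decreasing significance. Key 1 dominates the ordering (scaffold size),
#: architecture keys follow, composition and electronic detail come last.
KEY_REGISTRY: list[tuple[str, str, Callable]] = [
    ("n_heavy_atoms", "heavy atoms in the scaffold", _n_heavy),
    ("n_ring_atoms", "atoms belonging to at least one ring", _n_ring_atoms),
    ("n_linker_atoms", "non-ring (linker and exocyclic) atoms", _n_linker_atoms),
    ("n_linker_bonds", "bonds not in any ring", _n_linker_bonds),
    ("n_rings", "SSSR ring count", _n_rings),
    ("largest_ring_size", "atom count of the largest SSSR ring", _largest_ring),
    ("smallest_ring_size", "atom count of the smallest SSSR ring", _smallest_ring),
    ("n_aromatic_rings", "rings whose bonds are all aromatic", _n_aromatic_rings),
    ("n_aliphatic_rings", "rings with at least one non-aromatic bond", _n_aliphatic_rings),
    ("n_fusion_atoms", "atoms shared by two or more rings", _n_fusion_atoms),
    ("n_spiro_atoms", "spiro junction atoms", _n_spiro_atoms),
    ("n_ring_branch_atoms", "atoms with three or more ring bonds", _n_ring_branch_atoms),
    ("n_heteroatoms", "non-carbon heavy atoms", _n_heteroatoms),
    ("n_ring_heteroatoms", "heteroatoms inside rings", _n_ring_heteroatoms),
    ("n_nitrogen", "nitrogen atoms", _n_nitrogen),
    ("n_ring_nitrogen", "nitrogen atoms inside rings", _n_ring_nitrogen),
    ("n_oxygen", "oxygen atoms", _n_oxygen),
    ("n_ring_oxygen", "oxygen atoms inside rings", _n_ring_oxygen),
    ("n_sulfur", "sulfur atoms", _n_sulfur),
    ("n_ring_sulfur", "sulfur atoms inside rings", _n_ring_sulfur),
    ("n_other_heteroatoms", "heteroatoms other than N, O, S", _n_other_het),
    ("n_aromatic_atoms", "aromatic atoms", _n_aromatic_atoms),
    ("n_aromatic_heteroatoms", "aromatic heteroatoms", _n_aromatic_het),
    ("n_double_bonds", "double bonds (kekulized aromatics excluded)", _n_double_bonds),
    ("n_triple_bonds", "triple bonds", _n_triple_bonds),
    ("n_exocyclic_double_atoms", "exocyclic double bonds off a ring", _n_exocyclic_double_atoms),
    ("n_branch_atoms", "atoms of degree three or more", _n_branch_atoms),
    ("n_deg4_atoms", "atoms of degree four or more", _n_deg4_atoms),
    ("n_ring_systems", "fused ring systems (components of the ring graph)", _n_ring_systems),
    ("largest_ring_system_size", "atoms in the largest fused ring system", _largest_ring_system),
    ("n_linker_heteroatoms", "heteroatoms outside rings", _n_linker_heteroatoms),
    ("n_charged_atoms", "atoms with non-zero formal charge", _n_charged_atoms),
]

assert len(KEY_REGISTRY) == N_KEYS

KEY_NAMES = [name for name, _, _ in KEY_REGISTRY]


def compute_sk(s: Scaffold) -> SKVector:
    """Compute the 32-key Scaffold-Key vector of a scaffold.

    Deterministic: the same scaffold (canonical SMILES) always yields the
    same vector. Raises :class:`SKError` when the structure cannot be
    perceived (callers flag and exclude such records).
    """
    mol = Chem.MolFromSmiles(s.smiles)
    if mol is None:
        raise SKError(f"cannot perceive scaffold {s.smiles!r}")
    if not any(a.IsInRing() for a in mol.GetAtoms()):
        raise SKError(f"scaffold {s.smiles!r} has no ring")
    keys = tuple(int(fn(mol)) for _, _, fn in KEY_REGISTRY)
    return SKVector(keys=keys, inchikey=s.inchikey)


def sk_distance(a: SKVector | Sequence[int], b: SKVector | Sequence[int]) -> float:
    """Scaffold-Key distance: sum over keys of sqrt(|diff|^3) / key index.

    Early keys (low index n) are the most significant structural features
    and carry the largest weight 1/n. Symmetric; zero iff the 32 keys are
    identical. The InChI-Key field is ignored.
    """
    ka = np.asarray(a.keys if isinstance(a, SKVector) else a, dtype=float)
    kb = np.asarray(b.keys if isinstance(b, SKVector) else b, dtype=float)
    if ka.shape != (N_KEYS,) or kb.shape != (N_KEYS,):
        raise ValueError(f"both vectors must have length {N_KEYS}")
    diff = np.abs(ka - kb)
    weights = 1.0 / np.arange(1, N_KEYS + 1)
    return float(np.sum(np.sqrt(diff**3) * weights))


def sk_distance_matrix(keys: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Distances from one query vector to each row of a key matrix."""
    diff = np.abs(keys.astype(float) - np.asarray(query, dtype=float)[None, :])
    weights = 1.0 / np.arange(1, N_KEYS + 1)
    return np.sqrt(diff**3) @ weights


def _sort_key(rec: ScaffoldRecord):
    return (rec.sk.keys, rec.scaffold.inchikey)


def sort_scaffolds(records: Sequence[ScaffoldRecord]) -> list[ScaffoldRecord]:
    """Totally order scaffolds by their SK vector and assign 1-based ranks.

    The ordering compares the 32-key tuple with key 1 most significant
    ("alphanumeric" on fixed-width key strings is equivalent); full ties
    fall back to the lexicographically smaller InChI-Key. Residual ties
    (identical structure listed twice) keep input order with a warning, so
    any permutation of distinct scaffolds yields identical ranks.
    """
    ordered = sorted(records, key=_sort_key)
    for prev, cur in zip(ordered, ordered[1:]):
        if _sort_key(prev) == _sort_key(cur):
            warnings.warn(
                f"residual ordering tie between {prev.scaffold.smiles!r} and "
                f"{cur.scaffold.smiles!r}; input order kept"
            )
    return [replace(rec, rank=i) for i, rec in enumerate(ordered, start=1)]


def dedup_by_sk(records: Sequence[ScaffoldRecord]) -> list[ScaffoldRecord]:
    """One representative per distinct 32-key vector.

    The representative is the member with the smallest InChI-Key, so the
    surviving set does not depend on input order; first-occurrence order
    of the groups is preserved.
    """
    groups: dict[tuple, ScaffoldRecord] = {}
    order: list[tuple] = []
    for rec in records:
        key = rec.sk.keys
        if key not in groups:
            groups[key] = rec
            order.append(key)
        elif rec.scaffold.inchikey < groups[key].scaffold.inchikey:
            groups[key] = rec
    return [groups[k] for k in order]
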