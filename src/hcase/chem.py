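"""Structure ingestion, standardization and Bemis-Murcko scaffold extraction.

Every molecule entering an embedding passes through the same funnel:
parse -> keep the largest fragment -> canonicalize -> extract the
Bemis-Murcko scaffold (ring systems plus linkers, side chains removed).
Acyclic molecules have no scaffold and are dropped by the callers that
build reference spaces or embed libraries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold


class StructureError(ValueError):
    """Raised when a SMILES cannot be parsed or standardized."""


@dataclass(frozen=True)
class MoleculeRecord:
    """A labelled structure: an opaque id plus a SMILES string."""

    id: str
    smiles: str
    source: Optional[str] = None


@dataclass(frozen=True)
class Scaffold:
    """A Bemis-Murcko scaffold with its canonical SMILES and InChI-Key."""

    smiles: str
    inchikey: str


def _mol_from_record(rec: MoleculeRecord) -> Chem.Mol:
    mol = Chem.MolFromSmiles(rec.smiles)
    if mol is None:
        raise StructureError(f"unparseable SMILES for id {rec.id!r}: {rec.smiles!r}")
    return mol


def standardize_structure(raw: MoleculeRecord) -> MoleculeRecord:
    """Keep only the largest fragment of a substance and canonicalize.

    "Largest" means greatest heavy-atom count; ties are broken by
    lexicographically smallest canonical SMILES so the choice is
    deterministic. Idempotent.
    """
    mol = _mol_from_record(raw)
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    best = min(frags, key=lambda f: (-f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)))
    return MoleculeRecord(id=raw.id, smiles=Chem.MolToSmiles(best), source=raw.source)


def extract_bms(mol: MoleculeRecord) -> Optional[Scaffold]:
    """Bemis-Murcko scaffold of a (standardized) molecule, or ``None``.

    The framework keeps ring systems, linkers between them and atoms
    double-bonded to either (e.g. exocyclic carbonyl oxygens); all other
    side-chain atoms are removed. Acyclic molecules return ``None``.
    """
    m = _mol_from_record(mol)
    core = MurckoScaffold.GetScaffoldForMol(m)
    if core is None or core.GetNumAtoms() == 0:
        return None
    smiles = Chem.MolToSmiles(core)
    return Scaffold(smiles=smiles, inchikey=compute_inchikey_smiles(smiles))


def compute_inchikey(s: Scaffold) -> str:
    """Standard 27-character InChI-Key of a scaffold."""
    return compute_inchikey_smiles(s.smiles)


def compute_inchikey_smiles(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"unparseable scaffold SMILES: {smiles!r}")
    key = Chem.MolToInchiKey(mol)
    if not key:
        raise StructureError(f"InChI-Key generation failed for {smiles!r}")
    return key


# Fingerprint generators are cheap to build but caching by (radius, nbits)
# keeps tight loops (knn over whole libraries) allocation-free.
_FP_GENERATORS: dict = {}


def _fp_generator(radius: int, nbits: int):
    key = (radius, nbits)
    if key not in _FP_GENERATORS:
        _FP_GENERATORS[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=nbits
        )
    return _FP_GENERATORS[key]


def morgan_fingerprint(rec: MoleculeRecord, radius: int = 3, nbits: int = 2048):
    """Binary Morgan (circular) fingerprint as an RDKit bit vector."""
    if radius < 0 or nbits < 1:
        raise ValueError("radius must be >= 0 and nbits >= 1")
    return _fp_generator(radius, nbits).GetFingerprint(_mol_from_record(rec))


def morgan_tanimoto(
    a: MoleculeRecord, b: MoleculeRecord, radius: int = 3, nbits: int = 2048
) -> float:
    """Tanimoto similarity of two binary Morgan fingerprints, in [0, 1].

    A pair of empty fingerprints (no substructure set any bit) has no
    defined overlap; it is reported as 0.0 with a warning.
    """
    fa = morgan_fingerprint(a, radius, nbits)
    fb = morgan_fingerprint(b, radius, nbits)
    if fa.GetNumOnBits() == 0 and fb.GetNumOnBits() == 0:
        warnings.warn(
            f"both fingerprints empty for ids {a.id!r}, {b.id!r}; similarity set to 0"
        )
        return 0.0
    from rdkit import DataStructs

    return DataStructs.TanimotoSimilarity(fa, fb)


def knn(
    query: MoleculeRecord,
    library: Sequence[MoleculeRecord],
    k: int = 5,
    radius: int = 3,
    nbits: int = 2048,
) -> list[tuple[str, float]]:
    """The k nearest neighbors of ``query`` in ``library`` by Tanimoto.

    The query itself (matched by id) is excluded. Results are sorted by
    decreasing similarity, ties broken by ascending id for determinism.
    """
    candidates = [m for m in library if m.id != query.id]
    if not candidates:
        raise ValueError("library holds no molecule other than the query")
    if k > len(candidates):
        raise ValueError(f"k={k} exceeds library size {len(candidates)}")
    from rdkit import DataStructs

    fq = morgan_fingerprint(query, radius, nbits)
    fps = [morgan_fingerprint(m, radius, nbits) for m in candidates]
    sims = DataStructs.BulkTanimotoSimilarity(fq, fps)
    ranked = sorted(zip(candidates, sims), key=lambda t: (-t[1], t[0].id))
    return [(m.id, float(s)) for m, s in ranked[:k]]
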