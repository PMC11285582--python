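"""Deterministic synthetic scaffold sets, compound libraries and harnesses.

Real reference spaces come from large bioactivity collections (tens of
thousands of Bemis-Murcko scaffolds) and real libraries from drug or
screening collections. The generators here emulate the features those
inputs must have for the method to be exercised end-to-end: a broad
size/complexity gradient of ring-bearing scaffolds (1-5 ring systems
assembled from aromatic and saturated carbo-/heterocycles, fused or
chain-linked), and compound libraries built by decorating those scaffolds
with small substituents so each compound has a known true parent.

Everything is driven by an explicit seed; the same spec always produces
byte-identical output. The module also hosts the experiment harnesses
built on these fixtures: the cherry-picked rank-window construction, the
convergence-with-order profile and the reduced-space robustness check.
"""

from __future__ import annotations

import contextlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem, rdBase
from rdkit.Chem import RWMol


@contextlib.contextmanager
def _quiet_rdkit():
    """Silence parse/valence errors for draws the generator rejects anyway."""
    rdBase.DisableLog("rdApp.error")
    try:
        yield
    finally:
        rdBase.EnableLog("rdApp.error")

from .chem import MoleculeRecord, Scaffold, extract_bms, standardize_structure
from .embedding import ReferenceSpace, embed_library
from .hilbert import grid_dimensions, rank_to_point
from .scaffold_keys import ScaffoldRecord, compute_sk, dedup_by_sk, sort_scaffolds

#: Ring units of the scaffold grammar. Each entry: (name, ring count,
#: closed template, open template). Templates carry {a}/{b} ring-closure
#: slots (filled with unique %nn labels per unit so nesting never
#: collides) and {x}, the attachment slot of the open form.
RING_UNITS: list[tuple[str, int, str, str]] = [
    ("benzene", 1, "c{a}ccccc{a}", "c{a}ccc({x})cc{a}"),
    ("pyridine", 1, "c{a}ccncc{a}", "c{a}ccnc({x})c{a}"),
    ("pyrimidine", 1, "c{a}cncnc{a}", "c{a}cnc({x})nc{a}"),
    ("pyrazine", 1, "c{a}cnccn{a}", "c{a}cnc({x})cn{a}"),
    ("pyrrole", 1, "c{a}cc[nH]c{a}", "c{a}ccn({x})c{a}"),
    ("furan", 1, "c{a}ccoc{a}", "c{a}cc({x})oc{a}"),
    ("thiophene", 1, "c{a}ccsc{a}", "c{a}cc({x})sc{a}"),
    ("imidazole", 1, "c{a}cnc[nH]{a}", "c{a}cncn{a}{x}"),
    ("cyclohexane", 1, "C{a}CCCCC{a}", "C{a}CCC({x})CC{a}"),
    ("piperidine", 1, "C{a}CCNCC{a}", "C{a}CCN({x})CC{a}"),
    ("tetrahydropyran", 1, "C{a}CCOCC{a}", "C{a}CC({x})OCC{a}"),
    ("piperazine", 1, "C{a}CNCCN{a}", "C{a}CN({x})CCN{a}"),
    ("morpholine", 1, "C{a}COCCN{a}", "C{a}COCCN{a}{x}"),
    ("cyclopentane", 1, "C{a}CCCC{a}", "C{a}CCC({x})C{a}"),
    ("pyrrolidine", 1, "C{a}CCNC{a}", "C{a}CCN({x})C{a}"),
    ("tetrahydrofuran", 1, "C{a}CCOC{a}", "C{a}CC({x})OC{a}"),
    ("cycloheptane", 1, "C{a}CCCCCC{a}", "C{a}CCCC({x})CC{a}"),
    ("oxetane", 1, "C{a}COC{a}", "C{a}C({x})OC{a}"),
    ("cyclohexanone", 1, "C{a}CCC(=O)CC{a}", "C{a}CC({x})C(=O)CC{a}"),
    ("pyrrolidinone", 1, "C{a}(=O)CCCN{a}", "C{a}(=O)CCCN{a}{x}"),
    ("naphthalene", 2, "c{a}ccc{b}ccccc{b}c{a}", "c{a}ccc{b}cc({x})ccc{b}c{a}"),
    ("quinoline", 2, "c{a}ccc{b}ncccc{b}c{a}", "c{a}ccc{b}ncc({x})cc{b}c{a}"),
    ("isoquinoline", 2, "c{a}ccc{b}cnccc{b}c{a}", "c{a}ccc{b}cnc({x})cc{b}c{a}"),
    ("quinazoline", 2, "c{a}ccc{b}ncncc{b}c{a}", "c{a}ccc{b}ncnc({x})c{b}c{a}"),
    ("indole", 2, "c{a}ccc{b}[nH]ccc{b}c{a}", "c{a}cc({x})c{b}[nH]ccc{b}c{a}"),
    ("benzofuran", 2, "c{a}ccc{b}occc{b}c{a}", "c{a}ccc{b}oc({x})cc{b}c{a}"),
    ("benzothiophene", 2, "c{a}ccc{b}sccc{b}c{a}", "c{a}ccc{b}sc({x})cc{b}c{a}"),
    ("decalin", 2, "C{a}CCC{b}CCCCC{b}C{a}", "C{a}CCC{b}CC({x})CCC{b}C{a}"),
    ("tetralin", 2, "C{a}CCc{b}ccccc{b}C{a}", "C{a}CC({x})c{b}ccccc{b}C{a}"),
    ("indane", 2, "C{a}Cc{b}ccccc{b}C{a}", "C{a}C({x})c{b}ccccc{b}C{a}"),
    ("dihydrobenzofuran", 2, "C{a}COc{b}ccccc{b}C{a}", "C{a}C({x})Oc{b}ccccc{b}C{a}"),
]

#: Side-chain pool for compound decoration; all acyclic, so the parent
#: scaffold is recoverable as the Bemis-Murcko scaffold of the compound.
SUBSTITUENTS: tuple[str, ...] = (
    "C", "CC", "CCC", "O", "N", "F", "Cl", "OC", "C(=O)C", "C#N",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one deterministic synthetic dataset."""

    n_scaffolds: int = 200
    n_compounds: int = 300
    seed: int = 0
    max_rings: int = 5
    max_linker_length: int = 4
    max_substituents: int = 3


class GrammarExhausted(RuntimeError):
    """Raised when the grammar cannot produce enough distinct scaffolds."""


def _assemble(unit_indices: Sequence[int], linker_lengths: Sequence[int]) -> str:
    """Chain ring units back-to-front, renumbering ring closures."""
    label = 10 + 2 * len(unit_indices)
    _, _, closed, _ = RING_UNITS[unit_indices[-1]]
    frag = closed.format(a=f"%{label}", b=f"%{label + 1}")
    for pos in range(len(unit_indices) - 2, -1, -1):
        label = 10 + 2 * pos
        _, _, _, open_tpl = RING_UNITS[unit_indices[pos]]
        x = "C" * linker_lengths[pos] + frag
        frag = open_tpl.format(a=f"%{label}", b=f"%{label + 1}", x=x)
    return frag


def generate_scaffolds(spec: FixtureSpec) -> list[MoleculeRecord]:
    """Sample ``spec.n_scaffolds`` distinct ring-bearing scaffolds.

    Each draw picks ring units until a sampled ring budget (1 to
    ``max_rings``) is filled, then chains them with alkyl linkers of
    length 0 to ``max_linker_length``. Output SMILES are canonical,
    constitutionally distinct and always carry at least one ring.
    """
    if spec.n_scaffolds < 1:
        raise ValueError("n_scaffolds must be >= 1")
    rng = np.random.default_rng(spec.seed)
    seen: set[str] = set()
    records: list[MoleculeRecord] = []
    attempts = 0
    max_attempts = 200 * spec.n_scaffolds
    while len(records) < spec.n_scaffolds:
        attempts += 1
        if attempts > max_attempts:
            raise GrammarExhausted(
                f"only {len(records)} distinct scaffolds after {attempts} draws"
            )
        budget = int(rng.integers(1, spec.max_rings + 1))
        units: list[int] = []
        while budget > 0:
            candidates = [i for i, u in enumerate(RING_UNITS) if u[1] <= budget]
            pick = int(rng.choice(candidates))
            units.append(pick)
            budget -= RING_UNITS[pick][1]
        linkers = [
            int(rng.integers(0, spec.max_linker_length + 1))
            for _ in range(len(units) - 1)
        ]
        with _quiet_rdkit():
            mol = Chem.MolFromSmiles(_assemble(units, linkers))
        if mol is None:
            continue
        smiles = Chem.MolToSmiles(mol)
        if smiles in seen:
            continue
        seen.add(smiles)
        records.append(
            MoleculeRecord(
                id=f"SYN-{len(records) + 1:05d}", smiles=smiles, source="synthetic"
            )
        )
    return records


def _decorate(scaffold_mol: Chem.Mol, substituent: str, rng: np.random.Generator):
    """Attach one acyclic substituent at a random substitutable atom."""
    sub = Chem.MolFromSmiles(substituent)
    sites = [
        a.GetIdx()
        for a in scaffold_mol.GetAtoms()
        if a.GetTotalNumHs() > 0 and a.GetAtomicNum() in (6, 7) and not (
            a.GetAtomicNum() == 7 and a.GetIsAromatic()
        )
    ]
    if not sites:
        return None
    site = int(rng.choice(sites))
    combined = RWMol(Chem.CombineMols(scaffold_mol, sub))
    combined.AddBond(site, scaffold_mol.GetNumAtoms(), Chem.BondType.SINGLE)
    with _quiet_rdkit():
        try:
            out = combined.GetMol()
            Chem.SanitizeMol(out)
        except Exception:
            return None
    return out


def generate_compounds(
    space_scaffolds: Sequence[MoleculeRecord], spec: FixtureSpec
) -> list[MoleculeRecord]:
    """Decorate scaffolds into a compound library with known parents.

    Each compound is a randomly chosen scaffold carrying 0 to
    ``max_substituents`` side chains from :data:`SUBSTITUENTS`. The true
    parent scaffold's id is recorded in the ``source`` field for oracle
    tests. Valence-breaking decorations are skipped and retried.
    """
    if not space_scaffolds:
        raise ValueError("scaffold list is empty")
    rng = np.random.default_rng(spec.seed + 1)
    out: list[MoleculeRecord] = []
    attempts = 0
    max_attempts = 50 * spec.n_compounds
    while len(out) < spec.n_compounds:
        attempts += 1
        if attempts > max_attempts:
            raise GrammarExhausted("decoration failed too often")
        parent = space_scaffolds[int(rng.integers(0, len(space_scaffolds)))]
        mol = Chem.MolFromSmiles(parent.smiles)
        n_subs = int(rng.integers(0, spec.max_substituents + 1))
        ok = True
        for _ in range(n_subs):
            sub = SUBSTITUENTS[int(rng.integers(0, len(SUBSTITUENTS)))]
            decorated = _decorate(mol, sub, rng)
            if decorated is None:
                ok = False
                break
            mol = decorated
        if not ok:
            continue
        out.append(
            MoleculeRecord(
                id=f"CPD-{len(out) + 1:05d}",
                smiles=Chem.MolToSmiles(mol),
                source=parent.id,
            )
        )
    return out


# --- cherry-picked rank windows -----------------------------------------

#: Anchor configuration of the scaffold-tracking experiment on a
#: ChEMBL-scale reference set: nine anchor ranks spread over a space of
#: 55,961 scaffolds, each taken with its 50 rank-neighbors per side.
ANCHOR_RANKS: tuple[int, ...] = (
    5000, 15000, 16000, 25000, 26000, 35000, 44000, 45000, 55000,
)
ANCHOR_SPACE_SIZE = 55961
ANCHOR_WINDOW = 50


def cherry_pick_ranks(
    seed_ranks: Sequence[int], window: int, space_size: int
) -> list[int]:
    """Ranks of the cherry-picked set: each seed plus ``window`` ranked
    neighbors on each side.

    Windows must fit inside [1, space_size] and must not overlap (the
    construction guarantees disjoint tracked neighborhoods).
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    for r in seed_ranks:
        if not (1 + window <= r <= space_size - window):
            raise ValueError(
                f"seed rank {r} with window {window} leaves the space [1, {space_size}]"
            )
    sorted_ranks = sorted(seed_ranks)
    for r1, r2 in zip(sorted_ranks, sorted_ranks[1:]):
        if r2 - r1 <= 2 * window:
            raise ValueError(f"windows of seed ranks {r1} and {r2} overlap")
    out: list[int] = []
    for r in sorted_ranks:
        out.extend(range(r - window, r + window + 1))
    return out


def cherry_pick_experiment(
    space: ReferenceSpace, seed_ranks: Sequence[int], window: int
) -> list[ScaffoldRecord]:
    """The marked scaffold set of a space for the tracking experiment."""
    ranks = cherry_pick_ranks(seed_ranks, window, space.size)
    return [space.scaffolds[r - 1] for r in ranks]


# --- experiment harnesses ------------------------------------------------

def _normalized_point(rank: int, space: ReferenceSpace, z: int) -> np.ndarray:
    p = rank_to_point(rank, space.grid(z))
    n, _ = grid_dimensions(z)
    return np.array([p.x / n, p.y / n])


def convergence_displacements(
    space: ReferenceSpace,
    compounds: Sequence[MoleculeRecord],
    z_values: Sequence[int],
) -> list[float]:
    """Mean normalized displacement of embedded compounds between
    consecutive curve orders.

    Entry i is the mean Euclidean distance between a compound's
    normalized coordinates (x/N, y/N) at ``z_values[i]`` and at
    ``z_values[i+1]``. A shrinking sequence is the stabilization property
    of pseudo-Hilbert curves of increasing order.
    """
    coords: dict[int, dict[str, np.ndarray]] = {}
    for z in z_values:
        n, _ = grid_dimensions(z)
        embedded = embed_library(compounds, space, z)
        coords[z] = {
            e.compound_id: np.array([e.point.x / n, e.point.y / n]) for e in embedded
        }
    out = []
    for z1, z2 in zip(z_values, z_values[1:]):
        common = coords[z1].keys() & coords[z2].keys()
        disp = [float(np.linalg.norm(coords[z1][c] - coords[z2][c])) for c in common]
        out.append(float(np.mean(disp)))
    return out


def reduced_space_displacement(
    scaffold_records: Sequence[ScaffoldRecord],
    z: int,
    keep_fraction: float = 0.9,
    seed: int = 0,
    tracked_seed_ranks: Optional[Sequence[int]] = None,
    window: int = 20,
) -> float:
    """Robustness of positions when the reference set shrinks by 10%.

    Builds the full space from ``scaffold_records``, marks a tracked
    window set, rebuilds the space from a random ``keep_fraction`` subset
    that retains every tracked scaffold, and returns the mean Euclidean
    displacement of the tracked scaffolds' normalized grid coordinates
    between the two spaces.
    """
    full = ReferenceSpace(
        scaffolds=sort_scaffolds(dedup_by_sk(list(scaffold_records))),
        source="synthetic-full",
    )
    if tracked_seed_ranks is None:
        step = full.size // 4
        tracked_seed_ranks = [step, 2 * step, 3 * step]
    tracked = cherry_pick_experiment(full, tracked_seed_ranks, window)
    tracked_keys = {rec.scaffold.inchikey for rec in tracked}

    rng = np.random.default_rng(seed)
    others = [r for r in full.scaffolds if r.scaffold.inchikey not in tracked_keys]
    n_keep = max(0, int(round(keep_fraction * full.size)) - len(tracked))
    kept_idx = rng.choice(len(others), size=min(n_keep, len(others)), replace=False)
    subset = [others[i] for i in sorted(kept_idx)] + list(tracked)
    reduced = ReferenceSpace(
        scaffolds=sort_scaffolds(dedup_by_sk(subset)), source="synthetic-reduced"
    )

    rank_full = {r.scaffold.inchikey: r.rank for r in full.scaffolds}
    rank_reduced = {r.scaffold.inchikey: r.rank for r in reduced.scaffolds}
    disp = []
    for key in tracked_keys:
        a = _normalized_point(rank_full[key], full, z)
        b = _normalized_point(rank_reduced[key], reduced, z)
        disp.append(float(np.linalg.norm(a - b)))
    return float(np.mean(disp))


def fixture_space(spec: FixtureSpec, source: str = "synthetic") -> ReferenceSpace:
    """Convenience: generate scaffolds and build their reference space."""
    from .embedding import build_reference_space

    return build_reference_space(generate_scaffolds(spec), source=source)
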