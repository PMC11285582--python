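"""Building reference scaffold spaces and embedding compound libraries.

The chemical space is a ranked list of reference Bemis-Murcko scaffolds:
standardize -> scaffold -> Scaffold-Key -> dedup -> sort -> rank. A
compound is embedded by extracting its own scaffold, finding the
SK-nearest reference scaffold, converting that scaffold's rank into a
curve bin and folding the bin onto the 2^z x 2^z grid. Each compound's
position therefore depends only on itself and the reference space, never
on the other compounds in the batch.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .chem import (
    MoleculeRecord,
    Scaffold,
    StructureError,
    extract_bms,
    standardize_structure,
)
from .hilbert import GridPoint, PHCGrid, bin_index, hilbert_coords
from .scaffold_keys import (
    N_KEYS,
    SKError,
    SKVector,
    ScaffoldRecord,
    compute_sk,
    dedup_by_sk,
    sk_distance_matrix,
    sort_scaffolds,
)

SPACE_FORMAT_VERSION = "1"


@dataclass
class ReferenceSpace:
    """A deduplicated, SK-sorted, ranked reference scaffold set."""

    scaffolds: list[ScaffoldRecord]
    source: str = "unknown"
    dedup_policy: str = "sk"
    n_dropped: int = 0
    _sk_matrix: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self):
        ranks = [r.rank for r in self.scaffolds]
        if ranks != list(range(1, len(self.scaffolds) + 1)):
            raise ValueError("scaffold ranks must be contiguous 1..|S|")

    @property
    def size(self) -> int:
        return len(self.scaffolds)

    @property
    def sk_matrix(self) -> np.ndarray:
        if self._sk_matrix is None:
            self._sk_matrix = np.array(
                [rec.sk.keys for rec in self.scaffolds], dtype=np.int64
            )
        return self._sk_matrix

    def checksum(self) -> str:
        """Digest of ranks, SMILES and keys; identifies the space in files."""
        h = hashlib.sha256()
        for rec in self.scaffolds:
            h.update(
                f"{rec.rank}\t{rec.scaffold.smiles}\t{rec.scaffold.inchikey}\t"
                f"{','.join(map(str, rec.sk.keys))}\n".encode()
            )
        return h.hexdigest()[:16]

    def grid(self, z: int) -> PHCGrid:
        return PHCGrid(z=z, space_size=self.size)

    def save(self, path: str | Path) -> None:
        """Write the space file: sidecar header plus one row per scaffold."""
        with open(path, "w") as fh:
            fh.write(f"# format_version={SPACE_FORMAT_VERSION}\n")
            fh.write(f"# source={self.source}\n")
            fh.write(f"# dedup_policy={self.dedup_policy}\n")
            fh.write(f"# n_dropped={self.n_dropped}\n")
            fh.write(f"# checksum={self.checksum()}\n")
            fh.write("rank\tsmiles\tinchikey\t" + "\t".join(f"k{i}" for i in range(1, N_KEYS + 1)) + "\n")
            for rec in self.scaffolds:
                keys = "\t".join(str(k) for k in rec.sk.keys)
                fh.write(f"{rec.rank}\t{rec.scaffold.smiles}\t{rec.scaffold.inchikey}\t{keys}\n")

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceSpace":
        meta = {}
        records = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    k, _, v = line[1:].strip().partition("=")
                    meta[k] = v
                    continue
                if line.startswith("rank\t") or not line:
                    continue
                parts = line.split("\t")
                rank, smiles, inchikey = int(parts[0]), parts[1], parts[2]
                keys = tuple(int(x) for x in parts[3 : 3 + N_KEYS])
                scaffold = Scaffold(smiles=smiles, inchikey=inchikey)
                records.append(
                    ScaffoldRecord(
                        scaffold=scaffold,
                        sk=SKVector(keys=keys, inchikey=inchikey),
                        rank=rank,
                    )
                )
        records.sort(key=lambda r: r.rank)
        return cls(
            scaffolds=records,
            source=meta.get("source", "unknown"),
            dedup_policy=meta.get("dedup_policy", "sk"),
            n_dropped=int(meta.get("n_dropped", 0)),
        )


@dataclass(frozen=True)
class EmbeddedCompound:
    """One library member's position in an embedded space."""

    compound_id: str
    bms_smiles: str
    nearest_rank: int
    d_sk_nearest: float
    b: int
    point: GridPoint
    z: int
    space_checksum: str = ""


@dataclass
class SkipReport:
    """Compounds excluded from a pipeline stage, with reasons."""

    skipped: list[tuple[str, str]] = field(default_factory=list)

    def add(self, compound_id: str, reason: str) -> None:
        self.skipped.append((compound_id, reason))

    def __len__(self) -> int:
        return len(self.skipped)


def scaffold_record(scaffold: Scaffold) -> ScaffoldRecord:
    return ScaffoldRecord(scaffold=scaffold, sk=compute_sk(scaffold))


def build_reference_space(
    scaffold_inputs: Sequence[MoleculeRecord],
    source: str = "unknown",
    report: Optional[SkipReport] = None,
) -> ReferenceSpace:
    """Build a ranked reference space from raw structures.

    Pipeline: standardize -> Bemis-Murcko scaffold -> Scaffold-Key ->
    dedup by SK -> sort -> rank. Structures without a valid scaffold
    (acyclic or unparseable) are dropped and counted, never fatal.
    """
    if not scaffold_inputs:
        raise ValueError("no input structures")
    report = report if report is not None else SkipReport()
    records = []
    for rec in scaffold_inputs:
        try:
            std = standardize_structure(rec)
            scaffold = extract_bms(std)
        except StructureError as exc:
            report.add(rec.id, f"parse/standardize failure: {exc}")
            continue
        if scaffold is None:
            report.add(rec.id, "no Bemis-Murcko scaffold (acyclic)")
            continue
        try:
            records.append(scaffold_record(scaffold))
        except SKError as exc:
            report.add(rec.id, f"Scaffold-Key failure: {exc}")
    if not records:
        raise ValueError("no input structure yielded a valid scaffold")
    ranked = sort_scaffolds(dedup_by_sk(records))
    return ReferenceSpace(
        scaffolds=ranked, source=source, dedup_policy="sk", n_dropped=len(report)
    )


def nearest_reference(
    s: Scaffold | SKVector, space: ReferenceSpace
) -> tuple[int, float]:
    """Rank of the SK-nearest reference scaffold and the distance to it.

    Ties are broken toward the lowest rank (the "simpler" scaffold under
    the SK ordering), which argmin over the rank-sorted matrix gives for
    free.
    """
    if space.size == 0:
        raise ValueError("empty reference space")
    sk = compute_sk(s) if isinstance(s, Scaffold) else s
    dists = sk_distance_matrix(space.sk_matrix, np.asarray(sk.keys))
    idx = int(np.argmin(dists))
    return space.scaffolds[idx].rank, float(dists[idx])


def embed_library(
    compounds: Sequence[MoleculeRecord],
    space: ReferenceSpace,
    z: int,
    report: Optional[SkipReport] = None,
) -> list[EmbeddedCompound]:
    """Embed a compound library onto the space's order-z PHC grid.

    Per compound: scaffold -> SK -> nearest reference -> bin -> grid
    cell. Compounds without a scaffold are skipped and reported. A grid
    finer than the reference set (|D| > |S| + 1) is allowed but noted:
    beyond that point extra resolution cannot separate scaffolds further.
    """
    grid = space.grid(z)
    if grid.d_count > space.size + 1:
        warnings.warn(
            f"grid of {grid.d_count} cells exceeds the resolution limit of the "
            f"{space.size}-scaffold reference set; positions remain valid but "
            "no further separation is gained"
        )
    report = report if report is not None else SkipReport()
    checksum = space.checksum()
    out = []
    for rec in compounds:
        try:
            std = standardize_structure(rec)
            scaffold = extract_bms(std)
        except StructureError as exc:
            report.add(rec.id, f"parse/standardize failure: {exc}")
            continue
        if scaffold is None:
            report.add(rec.id, "no Bemis-Murcko scaffold (acyclic)")
            continue
        try:
            rank, d_sk = nearest_reference(scaffold, space)
        except SKError as exc:
            report.add(rec.id, f"Scaffold-Key failure: {exc}")
            continue
        b = bin_index(rank, grid.l)
        out.append(
            EmbeddedCompound(
                compound_id=rec.id,
                bms_smiles=scaffold.smiles,
                nearest_rank=rank,
                d_sk_nearest=d_sk,
                b=b,
                point=hilbert_coords(b, z),
                z=z,
                space_checksum=checksum,
            )
        )
    return out


def write_embedding(
    embedded: Sequence[EmbeddedCompound], space: ReferenceSpace, path: str | Path
) -> None:
    """Write an embedding file with a reproducibility header block."""
    if embedded:
        z = embedded[0].z
    else:
        raise ValueError("nothing to write: empty embedding")
    grid = space.grid(z)
    with open(path, "w") as fh:
        fh.write(f"# z={z}\n# N={grid.n}\n# D={grid.d_count}\n")
        fh.write(f"# l={grid.l!r}\n# S={space.size}\n")
        fh.write(f"# space_checksum={space.checksum()}\n")
        fh.write("compound_id\tbms_smiles\tnearest_rank\td_sk\tbin\tx\ty\n")
        for e in embedded:
            fh.write(
                f"{e.compound_id}\t{e.bms_smiles}\t{e.nearest_rank}\t"
                f"{e.d_sk_nearest:.6f}\t{e.b}\t{e.point.x}\t{e.point.y}\n"
            )


def read_embedding(path: str | Path) -> tuple[list[EmbeddedCompound], dict]:
    """Read an embedding file back; returns records and the header dict."""
    meta: dict = {}
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                k, _, v = line[1:].strip().partition("=")
                meta[k] = v
                continue
            if line.startswith("compound_id") or not line:
                continue
            cid, bms, rank, d_sk, b, x, y = line.split("\t")
            records.append(
                EmbeddedCompound(
                    compound_id=cid,
                    bms_smiles=bms,
                    nearest_rank=int(rank),
                    d_sk_nearest=float(d_sk),
                    b=int(b),
                    point=GridPoint(x=int(x), y=int(y)),
                    z=int(meta["z"]),
                    space_checksum=meta.get("space_checksum", ""),
                )
            )
    return records, meta
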