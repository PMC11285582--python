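"""Readers and writers for compound libraries.

Supported inputs: .smi (whitespace-delimited SMILES + optional id), SDF
(id from a named property or the title line) and delimited text with
configurable SMILES/id columns. All readers return ``MoleculeRecord``
lists; unparseable rows are collected, not fatal, so callers can report
them alongside embedding skip counts.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from rdkit import Chem

from .chem import MoleculeRecord


def read_smi(path: str | Path, source: Optional[str] = None) -> list[MoleculeRecord]:
    """Read a .smi file: one molecule per line, ``SMILES [id]``.

    Missing ids are synthesized as ``<stem>-<lineno>``.
    """
    path = Path(path)
    records = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            smiles = parts[0]
            mol_id = parts[1] if len(parts) > 1 else f"{path.stem}-{i}"
            records.append(MoleculeRecord(id=mol_id, smiles=smiles, source=source))
    return records


def read_sdf(
    path: str | Path, id_property: Optional[str] = None, source: Optional[str] = None
) -> list[MoleculeRecord]:
    """Read an SDF; the id comes from ``id_property`` or the title line."""
    path = Path(path)
    records = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier, start=1):
        if mol is None:
            continue
        if id_property and mol.HasProp(id_property):
            mol_id = mol.GetProp(id_property)
        elif mol.GetProp("_Name"):
            mol_id = mol.GetProp("_Name")
        else:
            mol_id = f"{path.stem}-{i}"
        records.append(
            MoleculeRecord(id=mol_id, smiles=Chem.MolToSmiles(mol), source=source)
        )
    return records


def read_delimited(
    path: str | Path,
    smiles_column: str = "smiles",
    id_column: str = "id",
    sep: str = "\t",
    source: Optional[str] = None,
) -> list[MoleculeRecord]:
    """Read a delimited table with named SMILES and id columns."""
    df = pd.read_csv(path, sep=sep)
    for col in (smiles_column, id_column):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path}")
    return [
        MoleculeRecord(id=str(r[id_column]), smiles=str(r[smiles_column]), source=source)
        for _, r in df.iterrows()
    ]


def write_smi(records: Sequence[MoleculeRecord], path: str | Path) -> None:
    """Write records as ``SMILES<tab>id`` lines."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{rec.smiles}\t{rec.id}\n")
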