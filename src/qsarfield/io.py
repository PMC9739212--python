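"""Structure and activity file I/O.

SDF (V2000) files are read and written through RDKit.  MOL2 (TRIPOS) files
are parsed directly so that the partial charges in the ninth ATOM column are
preserved — those charges, when present, take precedence over any internal
charge assignment.  Activity tables are CSV/TSV with columns
``id,ic50_uM,pic50,role`` (either activity column may be empty; role is
``training``/``test``/empty).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit import RDLogger

from .dataset import Atom, CompoundRecord, Molecule

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "read_sdf",
    "write_sdf",
    "read_mol2",
    "read_activities",
    "write_activities",
    "read_structures",
    "read_dataset",
]


def read_sdf(path) -> list[Molecule]:
    """Read a multi-record V2000 SDF into point-cloud molecules."""
    try:
        supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    except OSError as exc:
        raise ValueError(f"{path}: unreadable SDF: {exc}") from exc
    mols = []
    for i, rdmol in enumerate(supplier):
        if rdmol is None:
            raise ValueError(f"{path}: unparsable SDF record #{i + 1}")
        name = rdmol.GetProp("_Name").strip() if rdmol.HasProp("_Name") else ""
        conf = rdmol.GetConformer()
        atoms = [
            Atom(a.GetSymbol(), np.array(conf.GetAtomPosition(a.GetIdx())))
            for a in rdmol.GetAtoms()
        ]
        mols.append(Molecule(name or f"mol{i + 1}", atoms))
    if not mols:
        raise ValueError(f"{path}: no molecules found")
    return mols


def write_sdf(mols: list[Molecule], path) -> None:
    writer = Chem.SDWriter(str(path))
    try:
        for mol in mols:
            rw = Chem.RWMol()
            for a in mol.atoms:
                rw.AddAtom(Chem.Atom(a.element))
            conf = Chem.Conformer(len(mol.atoms))
            for i, a in enumerate(mol.atoms):
                conf.SetAtomPosition(i, a.coords.tolist())
            rw.AddConformer(conf)
            out = rw.GetMol()
            out.SetProp("_Name", mol.id)
            writer.write(out)
    finally:
        writer.close()


def read_mol2(path) -> list[Molecule]:
    """Parse TRIPOS MOL2, keeping per-atom partial charges when present."""
    text = Path(path).read_text()
    blocks = text.split("@<TRIPOS>MOLECULE")
    mols = []
    for block in blocks[1:]:
        lines = block.splitlines()
        name = lines[1].strip() if len(lines) > 1 else ""
        try:
            atom_at = next(i for i, l in enumerate(lines) if l.strip() == "@<TRIPOS>ATOM")
        except StopIteration:
            raise ValueError(f"{path}: MOL2 record without ATOM section") from None
        atoms = []
        for line in lines[atom_at + 1:]:
            if line.startswith("@<TRIPOS>") or not line.strip():
                break
            parts = line.split()
            if len(parts) < 6:
                raise ValueError(f"{path}: malformed ATOM line: {line!r}")
            x, y, z = map(float, parts[2:5])
            element = parts[5].split(".")[0]
            charge = float(parts[8]) if len(parts) >= 9 else 0.0
            atoms.append(Atom(element, np.array([x, y, z]), charge))
        mols.append(Molecule(name or f"mol{len(mols) + 1}", atoms))
    if not mols:
        raise ValueError(f"{path}: no molecules found")
    return mols


def read_structures(path) -> list[Molecule]:
    path = Path(path)
    if path.suffix.lower() == ".mol2":
        return read_mol2(path)
    return read_sdf(path)


def _opt(value) -> float | None:
    return None if pd.isna(value) else float(value)


def read_activities(path) -> list[CompoundRecord]:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"id": str})
    if "id" not in df.columns:
        raise ValueError(f"{path}: activity table needs an 'id' column")
    if "ic50_uM" not in df.columns and "pic50" not in df.columns:
        raise ValueError(f"{path}: need an 'ic50_uM' and/or 'pic50' column")
    if df["id"].duplicated().any():
        dups = sorted(df.loc[df["id"].duplicated(), "id"])
        raise ValueError(f"{path}: duplicate compound ids {dups}")
    records = []
    for _, row in df.iterrows():
        role = row.get("role")
        role = "training" if (role is None or pd.isna(role) or role == "") else str(role)
        records.append(
            CompoundRecord(
                id=str(row["id"]),
                ic50_uM=_opt(row["ic50_uM"]) if "ic50_uM" in df.columns else None,
                pic50=_opt(row["pic50"]) if "pic50" in df.columns else None,
                role=role,
            )
        )
    return records


def write_activities(records: list[CompoundRecord], path) -> None:
    pd.DataFrame(
        {
            "id": [r.id for r in records],
            "ic50_uM": [r.ic50_uM for r in records],
            "pic50": [r.pic50 for r in records],
            "role": [r.role for r in records],
        }
    ).to_csv(path, index=False)


def read_dataset(structure_path, activity_table_path) -> tuple[list[Molecule], list[CompoundRecord]]:
    """Read structures and activities and match them by compound id."""
    mols = read_structures(structure_path)
    records = read_activities(activity_table_path)
    mol_ids = [m.id for m in mols]
    if len(set(mol_ids)) != len(mol_ids):
        raise ValueError("duplicate molecule ids in structure file")
    mol_by_id = {m.id: m for m in mols}
    missing = [r.id for r in records if r.id not in mol_by_id]
    if missing:
        raise ValueError(f"activity rows without a matching structure: {missing}")
    extra = sorted(set(mol_ids) - {r.id for r in records})
    if extra:
        raise ValueError(f"structures without an activity row: {extra}")
    ordered = [mol_by_id[r.id] for r in records]
    return ordered, records
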