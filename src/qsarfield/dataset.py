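"""Compound records, activity transforms, atom property typing and splitting.

A 3D-QSAR study starts from a congeneric series of inhibitors with measured
half-maximal inhibitory concentrations (IC50).  Concentrations are converted
to the log scale (pIC50 = -log10 of the molar IC50) before any regression, and
the series is divided into a training and a test set such that the test-set
activity range is nested inside the training range — a model should only be
asked to interpolate.

Molecules here are lightweight point clouds: each atom carries coordinates,
a partial charge and three dimensionless property weights (hydrophobicity,
H-bond donor, H-bond acceptor) that feed the similarity fields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "Atom",
    "Molecule",
    "CompoundRecord",
    "SplitSpec",
    "ic50_to_pic50",
    "pic50_to_ic50",
    "assign_property_weights",
    "split_train_test",
    "HYDROPHOBIC_WEIGHTS",
]


@dataclass
class Atom:
    """One atom: element symbol, Cartesian coordinates (Å) and field weights."""

    element: str
    coords: np.ndarray
    partial_charge: float = 0.0
    hydrophobic_w: float = 0.0
    donor_w: float = 0.0
    acceptor_w: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError(f"coords must be a 3-vector, got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("atom coordinates must be finite")


@dataclass
class Molecule:
    """An aligned small molecule as an ordered atom list.

    ``skeleton_indices`` point at the atoms of the common scaffold shared by
    the whole congeneric series; they define the correspondence used for
    rigid-body alignment.  ``formal_charge`` (total, in e) is optional — when
    set, partial charges are checked to sum to it.
    """

    id: str
    atoms: list[Atom]
    skeleton_indices: list[int] | None = None
    formal_charge: float | None = None

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"molecule {self.id!r} has no atoms")
        if self.skeleton_indices is not None:
            idx = list(self.skeleton_indices)
            if len(set(idx)) != len(idx):
                raise ValueError(f"molecule {self.id!r}: duplicate skeleton indices")
            if idx and (min(idx) < 0 or max(idx) >= len(self.atoms)):
                raise ValueError(f"molecule {self.id!r}: skeleton index out of range")
        if self.formal_charge is not None:
            total = float(sum(a.partial_charge for a in self.atoms))
            if abs(total - self.formal_charge) > 1e-4:
                raise ValueError(
                    f"molecule {self.id!r}: partial charges sum to {total:.6f}, "
                    f"expected {self.formal_charge}"
                )

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def property_weights(self, kind: str) -> np.ndarray:
        """Per-atom weights for one field kind.

        steric uses the cube of the van der Waals radius (volume surrogate),
        electrostatic the partial charge; the rest are the typed weights.
        """
        from .fields import VDW_RADII  # local import avoids a cycle

        if kind == "steric":
            return np.array([VDW_RADII[a.element] ** 3 for a in self.atoms])
        if kind == "electrostatic":
            return self.charges
        if kind == "hydrophobic":
            return np.array([a.hydrophobic_w for a in self.atoms])
        if kind == "donor":
            return np.array([a.donor_w for a in self.atoms])
        if kind == "acceptor":
            return np.array([a.acceptor_w for a in self.atoms])
        raise KeyError(f"unknown field kind {kind!r}")

    def with_coords(self, coords: np.ndarray) -> "Molecule":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [replace(a, coords=c.copy()) for a, c in zip(self.atoms, coords)]
        return Molecule(self.id, atoms, self.skeleton_indices, self.formal_charge)


@dataclass
class CompoundRecord:
    """Activity record: IC50 in μM, pIC50, and the train/test role."""

    id: str
    ic50_uM: float | None = None
    pic50: float | None = None
    role: str = "training"

    def __post_init__(self) -> None:
        if self.role not in ("training", "test"):
            raise ValueError(f"record {self.id!r}: role must be training|test")
        if self.ic50_uM is None and self.pic50 is None:
            raise ValueError(f"record {self.id!r}: need IC50 or pIC50")
        if self.ic50_uM is not None:
            if not (math.isfinite(self.ic50_uM) and self.ic50_uM > 0):
                raise ValueError(f"record {self.id!r}: IC50 must be positive")
            computed = ic50_to_pic50(self.ic50_uM)
            if self.pic50 is None:
                self.pic50 = computed
            elif abs(self.pic50 - computed) > 1e-4:
                raise ValueError(
                    f"record {self.id!r}: pIC50 {self.pic50} inconsistent with "
                    f"IC50 {self.ic50_uM} μM (expected {computed:.5f})"
                )


@dataclass
class SplitSpec:
    """Training/test split request.

    Either a random split at ``training_fraction`` (re-drawn until the
    test-set activity range nests inside the training range) or an explicit
    list of test ids, which bypasses randomisation but is still checked.
    """

    training_fraction: float = 0.75
    explicit_test_ids: list[str] | None = None
    seed: int = 0
    max_attempts: int = 500

    def __post_init__(self) -> None:
        if not 0.0 < self.training_fraction < 1.0:
            raise ValueError("training_fraction must lie in (0, 1)")


def ic50_to_pic50(ic50_uM, ndigits: int | None = None):
    """pIC50 from an IC50 given in μM: ``-log10(ic50 * 1e-6) = 6 - log10(ic50)``.

    Accepts scalars or arrays; ``ndigits`` rounds for report parity with
    printed activity tables.
    """
    arr = np.asarray(ic50_uM, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("IC50 values must be finite and positive")
    out = 6.0 - np.log10(arr)
    if ndigits is not None:
        out = np.round(out, ndigits)
    return float(out) if np.isscalar(ic50_uM) or arr.ndim == 0 else out


def pic50_to_ic50(pic50):
    """Inverse transform: IC50 in μM from pIC50."""
    arr = np.asarray(pic50, dtype=float)
    out = np.power(10.0, 6.0 - arr)
    return float(out) if np.isscalar(pic50) or arr.ndim == 0 else out


# Per-element hydrophobicity weights: a coarse atomic-lipophilicity lookup in
# the spirit of atomic logP contribution schemes, collapsed to one
# dimensionless weight per element.  Halogens and sulfur lipophilic, the
# H-bonding heteroatoms not.
HYDROPHOBIC_WEIGHTS: dict[str, float] = {
    "H": 0.1,
    "C": 0.6,
    "N": 0.0,
    "O": 0.0,
    "F": 0.3,
    "P": 0.2,
    "S": 0.5,
    "Cl": 0.6,
    "Br": 0.7,
    "I": 0.8,
}


def assign_property_weights(
    mol: Molecule,
    rule_table: dict[str, float] | None = None,
    bonds: list[tuple[int, int]] | None = None,
) -> Molecule:
    """Type atoms for the hydrophobic / donor / acceptor similarity fields.

    Rules: every N or O is an H-bond acceptor (weight 1); an N or O bearing at
    least one covalently bound hydrogen is additionally a donor (weight 1,
    placed on the heavy atom); hydrophobic weights come from a per-element
    lookup.  Connectivity is taken from ``bonds`` or inferred from covalent
    radii.
    """
    from .charges import infer_bonds

    table = HYDROPHOBIC_WEIGHTS if rule_table is None else rule_table
    for a in mol.atoms:
        if a.element not in table:
            raise KeyError(
                f"molecule {mol.id!r}: element {a.element!r} not covered by the "
                "hydrophobicity rule table"
            )
    if bonds is None:
        bonds = infer_bonds(mol)
    neighbours: dict[int, list[int]] = {i: [] for i in range(len(mol.atoms))}
    for i, j in bonds:
        neighbours[i].append(j)
        neighbours[j].append(i)

    atoms = []
    for i, a in enumerate(mol.atoms):
        hyd = table[a.element]
        donor = 0.0
        acceptor = 0.0
        if a.element in ("N", "O"):
            acceptor = 1.0
            if any(mol.atoms[j].element == "H" for j in neighbours[i]):
                donor = 1.0
        atoms.append(replace(a, hydrophobic_w=hyd, donor_w=donor, acceptor_w=acceptor))
    return Molecule(mol.id, atoms, mol.skeleton_indices, mol.formal_charge)


def _range_nested(test_y: np.ndarray, train_y: np.ndarray) -> bool:
    return (test_y.max() <= train_y.max()) and (test_y.min() >= train_y.min())


def split_train_test(
    records: list[CompoundRecord], spec: SplitSpec
) -> tuple[list[str], list[str]]:
    """Partition compounds into training and test ids.

    The test-set pIC50 range must nest inside the training range so the model
    never extrapolates on the hold-out compounds.  Random splits are re-drawn
    (incrementing a sub-seed) until that holds; an explicit test-id list skips
    the randomisation but is validated against the same condition.
    """
    if len(records) < 5:
        raise ValueError("need at least 5 records to split")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate compound ids")
    y = np.array([r.pic50 for r in records], dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError("pIC50 missing or non-finite for some records")

    if spec.explicit_test_ids is not None:
        test_ids = list(spec.explicit_test_ids)
        unknown = set(test_ids) - set(ids)
        if unknown:
            raise ValueError(f"explicit test ids not in dataset: {sorted(unknown)}")
        mask = np.array([i in set(test_ids) for i in ids])
        if mask.all() or not mask.any():
            raise ValueError("explicit test set must be a proper subset")
        if not _range_nested(y[mask], y[~mask]):
            raise ValueError(
                "explicit test set violates range nesting: test activities "
                "must lie within the training activity range"
            )
        train_ids = [i for i in ids if i not in set(test_ids)]
        return train_ids, test_ids

    n = len(records)
    n_train = int(round(spec.training_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    for attempt in range(spec.max_attempts):
        rng = np.random.default_rng(spec.seed + attempt)
        perm = rng.permutation(n)
        train_idx, test_idx = perm[:n_train], perm[n_train:]
        if _range_nested(y[test_idx], y[train_idx]):
            return [ids[i] for i in sorted(train_idx)], [ids[i] for i in sorted(test_idx)]
    raise RuntimeError(
        f"no admissible split found in {spec.max_attempts} attempts; the "
        "nesting condition may be unsatisfiable for this activity profile"
    )
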