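"""Iterative partial equalization of orbital electronegativities (PEOE).

The classic Gasteiger scheme: each element gets a quadratic electronegativity
function chi(q) = a + b*q + c*q^2; at every iteration charge flows across each
bond from the less to the more electronegative atom, scaled by the damping
factor 0.5**k, so transfers shrink geometrically and the charges converge.
Transfers are applied synchronously (computed from the charges at the start of
the iteration), which makes the result independent of atom ordering.

Parameters are per element (sigma framework, sp3-like values); no aromatic
pi correction is applied.
"""

from __future__ import annotations

import numpy as np

from .dataset import Atom, Molecule

__all__ = ["assign_peoe_charges", "infer_bonds", "PEOE_PARAMS", "COVALENT_RADII"]

# chi(q) = a + b q + c q^2  [eV-like units]; classic sp3 parameter sets.
PEOE_PARAMS: dict[str, tuple[float, float, float]] = {
    "H": (7.17, 6.24, -0.56),
    "C": (7.98, 9.18, 1.88),
    "N": (11.54, 10.82, 1.36),
    "O": (14.18, 12.92, 1.39),
    "F": (14.66, 13.85, 2.31),
    "Cl": (11.00, 9.69, 1.35),
    "Br": (10.08, 8.47, 1.16),
    "I": (9.90, 7.96, 0.96),
    "S": (10.14, 9.13, 1.38),
    "P": (8.90, 8.24, 0.96),
}

# Cation electronegativity chi(+1) = a + b + c, except hydrogen where the
# conventional value 20.02 is used.
_CHI_PLUS = {el: (20.02 if el == "H" else a + b + c) for el, (a, b, c) in PEOE_PARAMS.items()}

COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "P": 1.07, "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39,
}


def infer_bonds(mol: Molecule, tolerance: float = 1.3) -> list[tuple[int, int]]:
    """Distance-based connectivity: i-j bonded when closer than
    ``tolerance * (r_cov_i + r_cov_j)``."""
    coords = mol.coords
    bonds = []
    for i in range(len(mol.atoms)):
        ri = COVALENT_RADII.get(mol.atoms[i].element)
        if ri is None:
            raise KeyError(f"no covalent radius for element {mol.atoms[i].element!r}")
        for j in range(i + 1, len(mol.atoms)):
            rj = COVALENT_RADII[mol.atoms[j].element]
            d = float(np.linalg.norm(coords[i] - coords[j]))
            if 1e-6 < d < tolerance * (ri + rj):
                bonds.append((i, j))
    return bonds


def assign_peoe_charges(
    mol: Molecule,
    n_iter: int = 6,
    bonds: list[tuple[int, int]] | None = None,
    damping: float = 0.5,
) -> Molecule:
    """Return a copy of ``mol`` with PEOE partial charges.

    Charges start from zero (neutral molecule); because every transfer moves
    charge pairwise, the total is conserved exactly, so the molecule stays
    neutral to machine precision.
    """
    for a in mol.atoms:
        if a.element not in PEOE_PARAMS:
            raise KeyError(f"no PEOE parameters for element {a.element!r}")
    if bonds is None:
        bonds = infer_bonds(mol)
    n = len(mol.atoms)
    abc = np.array([PEOE_PARAMS[a.element] for a in mol.atoms])
    chi_plus = np.array([_CHI_PLUS[a.element] for a in mol.atoms])
    q = np.zeros(n)
    for k in range(1, n_iter + 1):
        chi = abc[:, 0] + abc[:, 1] * q + abc[:, 2] * q * q
        dq = np.zeros(n)
        f = damping**k
        for i, j in bonds:
            if chi[j] > chi[i]:
                # charge flows from i (less electronegative, becomes +) to j
                t = (chi[j] - chi[i]) / chi_plus[i] * f
                dq[i] += t
                dq[j] -= t
            elif chi[i] > chi[j]:
                t = (chi[i] - chi[j]) / chi_plus[j] * f
                dq[j] += t
                dq[i] -= t
        q += dq
    atoms = [
        Atom(a.element, a.coords.copy(), float(qi), a.hydrophobic_w, a.donor_w, a.acceptor_w)
        for a, qi in zip(mol.atoms, q)
    ]
    return Molecule(mol.id, atoms, mol.skeleton_indices, 0.0)
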