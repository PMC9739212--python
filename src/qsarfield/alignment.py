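"""Rigid-body superposition of the congeneric series onto a template.

Each molecule's common-skeleton atoms are least-squares fitted onto the
corresponding atoms of the template (conventionally the most active
compound), and the resulting rigid transform is applied to the whole
molecule.  The rotation is the Kabsch solution — the proper rotation
minimising the RMSD over the mapped atom pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import Molecule

__all__ = ["AlignmentResult", "kabsch_superpose", "align_set"]


@dataclass
class AlignmentResult:
    rotation: np.ndarray  # 3x3 proper rotation, det = +1
    translation: np.ndarray  # applied after rotation, Å
    skeleton_rmsd: float  # post-fit RMSD over mapped atoms, Å

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(
    mobile_coords: np.ndarray,
    ref_coords: np.ndarray,
    atom_map: list[tuple[int, int]] | None = None,
) -> AlignmentResult:
    """RMSD-minimising proper rotation + translation mapping mobile onto ref.

    ``atom_map`` pairs (mobile_index, ref_index); by default positions are
    matched in order.  Requires at least three non-collinear pairs; mirror
    images are handled by the determinant correction so the returned rotation
    is always proper.
    """
    mobile_coords = np.asarray(mobile_coords, dtype=float)
    ref_coords = np.asarray(ref_coords, dtype=float)
    if atom_map is None:
        if mobile_coords.shape != ref_coords.shape:
            raise ValueError("coordinate sets differ in shape and no atom_map given")
        m, r = mobile_coords, ref_coords
    else:
        mi = [p[0] for p in atom_map]
        ri = [p[1] for p in atom_map]
        m, r = mobile_coords[mi], ref_coords[ri]
    if len(m) < 3:
        raise ValueError("need at least 3 mapped atom pairs")

    mc, rc = m.mean(axis=0), r.mean(axis=0)
    m0, r0 = m - mc, r - rc
    h = m0.T @ r0
    u, s, vt = np.linalg.svd(h)
    scale = float(np.linalg.norm(m0)) * float(np.linalg.norm(r0))
    if scale > 0 and s[1] / np.sqrt(scale + 1e-300) < 1e-8:
        raise ValueError("mapped atoms are collinear or degenerate")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = rc - rot @ mc
    fitted = m @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - r) ** 2, axis=1))))
    return AlignmentResult(rotation=rot, translation=trans, skeleton_rmsd=rmsd)


def align_set(
    molecules: list[Molecule],
    template_id: str,
    skeleton_maps: dict[str, list[tuple[int, int]]] | None = None,
) -> tuple[list[Molecule], dict[str, AlignmentResult]]:
    """Superpose every molecule's skeleton onto the template's skeleton.

    Correspondence comes from ``skeleton_maps`` (mol atom index -> template
    atom index) or, by default, from positional pairing of each molecule's
    ``skeleton_indices`` with the template's.  The template itself is
    returned unchanged.
    """
    by_id = {m.id: m for m in molecules}
    if template_id not in by_id:
        raise KeyError(f"template molecule {template_id!r} not in set")
    template = by_id[template_id]
    if template.skeleton_indices is None:
        raise ValueError(f"template {template_id!r} lacks skeleton_indices")
    t_coords = template.coords

    aligned = []
    results: dict[str, AlignmentResult] = {}
    for mol in molecules:
        if mol.id == template_id:
            aligned.append(mol)
            results[mol.id] = AlignmentResult(np.eye(3), np.zeros(3), 0.0)
            continue
        if skeleton_maps is not None and mol.id in skeleton_maps:
            pairs = skeleton_maps[mol.id]
            mob_idx = [p[0] for p in pairs]
            ref_idx = [p[1] for p in pairs]
        else:
            if mol.skeleton_indices is None:
                raise ValueError(f"molecule {mol.id!r} lacks skeleton_indices")
            if len(mol.skeleton_indices) != len(template.skeleton_indices):
                raise ValueError(
                    f"molecule {mol.id!r}: skeleton length "
                    f"{len(mol.skeleton_indices)} != template "
                    f"{len(template.skeleton_indices)}"
                )
            mob_idx = list(mol.skeleton_indices)
            ref_idx = list(template.skeleton_indices)
        res = kabsch_superpose(mol.coords, t_coords, list(zip(mob_idx, ref_idx)))
        aligned.append(mol.with_coords(res.apply(mol.coords)))
        results[mol.id] = res
    return aligned, results
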