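"""Grid-based molecular interaction fields and the descriptor block.

Two families of descriptors are computed on a rectangular lattice enclosing
the aligned series:

* probe-energy fields — a Lennard-Jones steric energy and a Coulomb
  electrostatic energy (distance-dependent dielectric eps(r) = r) between an
  sp3-carbon probe of charge +1 e and the molecule, truncated at
  +/-30 kcal/mol.  At lattice nodes inside the molecular volume (steric
  energy at the truncation cap) the electrostatic value carries no
  information and is replaced by its column mean across the series.
* similarity fields — Gaussian-attenuated similarity indices
  ``A_k(node) = -sum_i w_probe * w_ik * exp(-alpha * r_iq^2)`` for the five
  physicochemical kinds (steric via r_vdw^3 volume weights, electrostatic via
  partial charges, hydrophobic / donor / acceptor via typed weights).  The
  smooth Gaussian avoids the singularities of the energy forms.

Columns that barely vary across compounds carry noise, not signal: columns
with standard deviation below a minimum-sigma threshold are dropped, and the
surviving per-kind sub-blocks are scaled to equal total variance so no single
field dominates the regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import Molecule

__all__ = [
    "GridSpec",
    "ProbeSpec",
    "FieldBlock",
    "make_grid",
    "comfa_fields",
    "comsia_fields",
    "build_block",
    "apply_block",
    "VDW_RADII",
    "WELL_DEPTHS",
    "COULOMB_CONSTANT",
    "ENERGY_CAP",
    "FIELD_KINDS",
]

FIELD_KINDS = ("steric", "electrostatic", "hydrophobic", "donor", "acceptor")

# van der Waals radii (Å) and Lennard-Jones well depths (kcal/mol),
# Tripos-style parameters for the elements of a typical medicinal series.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98,
}
WELL_DEPTHS: dict[str, float] = {
    "H": 0.042, "C": 0.107, "N": 0.095, "O": 0.116, "F": 0.109,
    "P": 0.314, "S": 0.314, "Cl": 0.314, "Br": 0.434, "I": 0.623,
}

COULOMB_CONSTANT = 332.0637  # kcal Å mol^-1 e^-2
ENERGY_CAP = 30.0  # kcal/mol truncation for both energy fields


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned lattice: nodes at ``origin + k * spacing``, k in [0, dims).

    Nodes are linearised x-fastest: flat index = ix + nx*(iy + ny*iz).
    """

    origin: tuple[float, float, float]
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if any(d < 1 for d in self.dims):
            raise ValueError("grid dims must be positive")

    @property
    def n_nodes(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def nodes(self) -> np.ndarray:
        """All node coordinates, shape (n_nodes, 3), x-fastest order."""
        nx, ny, nz = self.dims
        ax = [np.asarray(self.origin)[i] + self.spacing * np.arange(self.dims[i]) for i in range(3)]
        zz, yy, xx = np.meshgrid(ax[2], ax[1], ax[0], indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])

    def nearest_node(self, point) -> int:
        """Flat index of the lattice node closest to a Cartesian point."""
        p = np.asarray(point, dtype=float)
        idx = np.rint((p - np.asarray(self.origin)) / self.spacing).astype(int)
        idx = np.clip(idx, 0, np.asarray(self.dims) - 1)
        nx, ny, _ = self.dims
        return int(idx[0] + nx * (idx[1] + ny * idx[2]))


@dataclass(frozen=True)
class ProbeSpec:
    """Probe parameters: sp3 carbon of charge +1 e by default, with unit
    weights for the similarity kinds and Gaussian attenuation alpha (Å^-2)."""

    vdw_radius: float = 1.70
    well_depth: float = 0.107
    charge: float = 1.0
    hydrophobic_w: float = 1.0
    donor_w: float = 1.0
    acceptor_w: float = 1.0
    attenuation_alpha: float = 0.3

    def similarity_weight(self, kind: str) -> float:
        if kind == "steric":
            return 1.0  # unit probe weight; atoms carry the r_vdw^3 volume term
        if kind == "electrostatic":
            return self.charge
        return {"hydrophobic": self.hydrophobic_w, "donor": self.donor_w,
                "acceptor": self.acceptor_w}[kind]


def make_grid(molecules: list[Molecule], spacing: float = 2.0, margin: float = 4.0) -> GridSpec:
    """Bounding box of the aligned set, extended by ``margin`` on every side
    and discretised at ``spacing``."""
    if not molecules:
        raise ValueError("empty molecule set")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if margin < 0:
        raise ValueError("margin must be non-negative")
    all_coords = np.vstack([m.coords for m in molecules])
    lo = all_coords.min(axis=0) - margin
    hi = all_coords.max(axis=0) + margin
    dims = tuple(int(np.ceil((hi[i] - lo[i]) / spacing)) + 1 for i in range(3))
    return GridSpec(origin=tuple(float(v) for v in lo), spacing=float(spacing), dims=dims)


def _distances(mol: Molecule, grid: GridSpec) -> np.ndarray:
    """(n_nodes, n_atoms) distance matrix, floored at 1e-10 Å."""
    diff = grid.nodes()[:, None, :] - mol.coords[None, :, :]
    return np.maximum(np.sqrt(np.sum(diff * diff, axis=2)), 1e-10)


def comfa_fields(
    mol: Molecule, grid: GridSpec, probe: ProbeSpec | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Lennard-Jones steric and Coulomb electrostatic probe energies.

    Returns ``(steric, electrostatic)`` vectors over the grid, kcal/mol.
    Steric is capped at +30; electrostatic is clamped to [-30, +30] and set
    to NaN where the steric energy sits at the cap (inside the molecule) —
    ``build_block`` later substitutes the column mean there.
    """
    probe = probe or ProbeSpec()
    r = _distances(mol, grid)
    r_m = probe.vdw_radius + np.array([VDW_RADII[e] for e in mol.elements])
    eps = np.sqrt(probe.well_depth * np.array([WELL_DEPTHS[e] for e in mol.elements]))
    frac6 = (r_m[None, :] / r) ** 6
    steric = np.sum(eps[None, :] * (frac6 * frac6 - 2.0 * frac6), axis=1)
    clashed = steric >= ENERGY_CAP
    steric = np.minimum(steric, ENERGY_CAP)

    # eps(r) = r  =>  E = k q_i q_p / r^2
    elec = COULOMB_CONSTANT * probe.charge * np.sum(mol.charges[None, :] / (r * r), axis=1)
    elec = np.clip(elec, -ENERGY_CAP, ENERGY_CAP)
    elec[clashed] = np.nan
    return steric, elec


def comsia_fields(
    mol: Molecule,
    grid: GridSpec,
    probe: ProbeSpec | None = None,
    kinds: tuple[str, ...] = FIELD_KINDS,
) -> dict[str, np.ndarray]:
    """Gaussian similarity indices, one vector per requested kind."""
    probe = probe or ProbeSpec()
    r = _distances(mol, grid)
    g = np.exp(-probe.attenuation_alpha * r * r)
    out = {}
    for kind in kinds:
        if kind not in FIELD_KINDS:
            raise KeyError(f"unknown field kind {kind!r}")
        w = mol.property_weights(kind)
        out[kind] = -probe.similarity_weight(kind) * (g @ w)
    return out


@dataclass
class FieldBlock:
    """Compounds x descriptor-columns matrix with per-column provenance.

    ``matrix`` holds the kept, scaled columns; ``column_kinds``/
    ``column_nodes`` give each kept column's field kind and flat grid node;
    ``kept_mask`` records the filter verdict for every original column (per
    kind, grid order); ``scale_factors`` the per-kind variance-equalising
    factor; ``column_sd`` the post-scaling standard deviation of each kept
    column.
    """

    matrix: np.ndarray
    column_kinds: np.ndarray
    column_nodes: np.ndarray
    kept_mask: dict[str, np.ndarray]
    scale_factors: dict[str, float]
    grid: GridSpec
    kinds: tuple[str, ...]
    column_fill: dict[str, np.ndarray] | None = None  # NaN substitution means

    @property
    def n_compounds(self) -> int:
        return self.matrix.shape[0]

    @property
    def column_sd(self) -> np.ndarray:
        return self.matrix.std(axis=0, ddof=1)

    def columns_of(self, kind: str) -> np.ndarray:
        if kind not in self.kinds:
            raise KeyError(f"field kind {kind!r} not in block")
        return np.flatnonzero(self.column_kinds == kind)


def build_block(
    field_vectors: dict[str, np.ndarray],
    grid: GridSpec,
    filter_sigma: float = 2.0,
    scaling: str = "comfa_std",
) -> FieldBlock:
    """Assemble per-kind (n_compounds, n_nodes) arrays into one descriptor block.

    Filtering and scaling: NaN entries (sterically clashed electrostatics)
    are replaced by their column mean; columns with standard deviation below
    ``filter_sigma`` (in raw field units) are dropped; with
    ``scaling='comfa_std'`` each kind's kept sub-block is multiplied by one
    factor so every kind contributes the same total variance.
    """
    if scaling not in ("comfa_std", "none"):
        raise ValueError("scaling must be 'comfa_std' or 'none'")
    kinds = tuple(field_vectors)
    n_rows = {k: np.asarray(v).shape[0] for k, v in field_vectors.items()}
    if len(set(n_rows.values())) != 1:
        raise ValueError(f"inconsistent compound counts across kinds: {n_rows}")

    kept_mask: dict[str, np.ndarray] = {}
    scale_factors: dict[str, float] = {}
    column_fill: dict[str, np.ndarray] = {}
    sub_blocks, col_kinds, col_nodes = [], [], []
    for kind in kinds:
        x = np.array(field_vectors[kind], dtype=float)
        if x.shape[1] != grid.n_nodes:
            raise ValueError(
                f"kind {kind!r}: {x.shape[1]} columns != {grid.n_nodes} grid nodes"
            )
        # clashed-node substitution: column mean of the informative entries
        nan_mask = np.isnan(x)
        counts = (~nan_mask).sum(axis=0)
        sums = np.where(nan_mask, 0.0, x).sum(axis=0)
        col_mean = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
        column_fill[kind] = col_mean
        if nan_mask.any():
            x = np.where(nan_mask, col_mean[None, :], x)
        sd = x.std(axis=0, ddof=1)
        kept = sd >= filter_sigma
        kept_mask[kind] = kept
        if not kept.any():
            scale_factors[kind] = 1.0
            continue
        sub = x[:, kept]
        if scaling == "comfa_std":
            total_var = float(np.sum(sub.var(axis=0, ddof=1)))
            factor = 1.0 / np.sqrt(total_var) if total_var > 0 else 1.0
        else:
            factor = 1.0
        scale_factors[kind] = factor
        sub_blocks.append(sub * factor)
        col_kinds.append(np.full(int(kept.sum()), kind, dtype=object))
        col_nodes.append(np.flatnonzero(kept))
    if not sub_blocks:
        raise ValueError(
            f"every column filtered out at minimum sigma {filter_sigma}; "
            "lower the threshold or check the field computation"
        )
    return FieldBlock(
        matrix=np.hstack(sub_blocks),
        column_kinds=np.concatenate(col_kinds),
        column_nodes=np.concatenate(col_nodes),
        kept_mask=kept_mask,
        scale_factors=scale_factors,
        grid=grid,
        # kinds lists only the field kinds that survived the filter;
        # kept_mask/scale_factors keep the record for all inputs
        kinds=tuple(k for k in kinds if kept_mask[k].any()),
        column_fill=column_fill,
    )


def apply_block(field_vectors: dict[str, np.ndarray], block: FieldBlock) -> np.ndarray:
    """Transform new compounds' raw field vectors into the column space of an
    existing block: NaNs are filled with the block's stored column means, the
    same columns are kept and the same scale factors applied."""
    parts = []
    for kind in block.kinds:
        if kind not in field_vectors:
            raise KeyError(f"field kind {kind!r} missing from input vectors")
        x = np.atleast_2d(np.array(field_vectors[kind], dtype=float))
        if x.shape[1] != block.grid.n_nodes:
            raise ValueError(f"kind {kind!r}: column count mismatch with block grid")
        nan_mask = np.isnan(x)
        if nan_mask.any():
            fill = block.column_fill[kind] if block.column_fill else np.zeros(x.shape[1])
            x = np.where(nan_mask, fill[None, :], x)
        kept = block.kept_mask[kind]
        if kept.any():
            parts.append(x[:, kept] * block.scale_factors[kind])
    return np.hstack(parts)
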