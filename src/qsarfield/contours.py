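"""StDev x Coeff contour volumes and OpenDX export.

A fitted PLS model is interpreted spatially by mapping, for every kept grid
column of one field kind, the product of that column's standard deviation
and its regression coefficient back onto the lattice.  Because column
scaling multiplies the standard deviation and divides the coefficient by the
same factor, the product is independent of block scaling and is expressed in
activity units.  Positive nodes mark regions where more of the field
property favours activity; negative nodes disfavour it.

Contour levels follow the cumulative-contribution convention: the favored
isosurface at fraction f encloses the positive nodes carrying the top
(1 - f) share of the total positive |StDev x Coeff| mass (f = 0.8 by
default), and symmetrically for the disfavored level on the negative side
(fraction 0.2 by default, i.e. the top 20% of negative mass).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .fields import FieldBlock, GridSpec
from .pls import PLSModel

__all__ = [
    "VolumeMap",
    "ContourLevels",
    "stdev_coeff_volume",
    "contour_levels",
    "write_volume",
    "read_volume",
]


@dataclass
class VolumeMap:
    grid: GridSpec
    values: np.ndarray  # one scalar per node, x-fastest order; activity units
    field_kind: str
    mask: np.ndarray  # True where a kept column provided a value

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_nodes,):
            raise ValueError("values length must equal grid node count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume values must be finite")


@dataclass
class ContourLevels:
    favored_level: float
    disfavored_level: float
    favored_fraction: float
    disfavored_fraction: float


def stdev_coeff_volume(model: PLSModel, block: FieldBlock, field_kind: str) -> VolumeMap:
    """Map sd_j x coef_j of one field kind onto the grid.

    Filtered (dropped) columns contribute 0 and are excluded from the mask.
    The scaled sd and scaled coefficient multiply to the scale-invariant
    product, so the volume is already in original field x activity units.
    """
    idx = block.columns_of(field_kind)
    sd = block.column_sd[idx]
    coef = model.coefficients[idx]
    values = np.zeros(block.grid.n_nodes)
    mask = np.zeros(block.grid.n_nodes, dtype=bool)
    nodes = block.column_nodes[idx]
    values[nodes] = sd * coef
    mask[nodes] = True
    return VolumeMap(grid=block.grid, values=values, field_kind=field_kind, mask=mask)


def _mass_level(values: np.ndarray, fraction: float) -> float:
    """Smallest value v such that nodes with value >= v carry at most
    (1 - fraction) of the total mass of ``values`` (all positive)."""
    order = np.argsort(values)[::-1]
    sorted_vals = values[order]
    cum = np.cumsum(sorted_vals)
    budget = (1.0 - fraction) * cum[-1]
    within = np.flatnonzero(cum <= budget + 1e-12)
    if within.size == 0:
        return float(sorted_vals[0])
    return float(sorted_vals[within[-1]])


def contour_levels(
    volume: VolumeMap,
    favored_fraction: float = 0.8,
    disfavored_fraction: float = 0.2,
) -> ContourLevels:
    """Isosurface levels from cumulative |StDev x Coeff| mass."""
    for f in (favored_fraction, disfavored_fraction):
        if not 0.0 < f < 1.0:
            raise ValueError("contour fractions must lie in (0, 1)")
    v = volume.values
    if not np.any(v != 0.0):
        raise ValueError("all-zero volume has no contour levels")
    pos = v[v > 0]
    neg = -v[v < 0]
    favored = _mass_level(pos, favored_fraction) if pos.size else 0.0
    # symmetric rule on the mirrored negatives; a disfavored fraction of 0.2
    # encloses the top 20% of negative mass
    disfavored = -_mass_level(neg, 1.0 - disfavored_fraction) if neg.size else 0.0
    return ContourLevels(
        favored_level=float(favored),
        disfavored_level=float(disfavored),
        favored_fraction=favored_fraction,
        disfavored_fraction=disfavored_fraction,
    )


def write_volume(volume: VolumeMap, path) -> None:
    """Write an OpenDX scalar field.

    In-memory node order is x-fastest; the DX data stream follows the format's
    own convention (last index, z, fastest), so values are re-ordered on the
    way out and back on the way in.
    """
    nx, ny, nz = volume.grid.dims
    sp = volume.grid.spacing
    ox, oy, oz = volume.grid.origin
    # x-fastest -> z-fastest
    vals = volume.values.reshape(nz, ny, nx).transpose(2, 1, 0).ravel()
    lines = [
        f"# qsarfield StDev*Coeff volume, field kind: {volume.field_kind}",
        "# in-memory linearization is x-fastest; this data stream is z-fastest per DX convention",
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {ox:.6f} {oy:.6f} {oz:.6f}",
        f"delta {sp:.6f} 0.000000 0.000000",
        f"delta 0.000000 {sp:.6f} 0.000000",
        f"delta 0.000000 0.000000 {sp:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {vals.size} data follows",
    ]
    for i in range(0, vals.size, 3):
        lines.append(" ".join(f"{v:.6e}" for v in vals[i : i + 3]))
    lines += [
        'attribute "dep" string "positions"',
        'object "regular positions regular connections" class field',
        'component "positions" value 1',
        'component "connections" value 2',
        'component "data" value 3',
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_volume(path, field_kind: str = "") -> VolumeMap:
    """Read a scalar field written by :func:`write_volume`."""
    dims = origin = spacing = None
    data: list[float] = []
    in_data = False
    n_items = 0
    for line in Path(path).read_text().splitlines():
        s = line.strip()
        if s.startswith("#") or not s:
            continue
        if s.startswith("object 1"):
            dims = tuple(int(t) for t in s.split("counts")[1].split())
        elif s.startswith("origin"):
            origin = tuple(float(t) for t in s.split()[1:4])
        elif s.startswith("delta"):
            d = [float(t) for t in s.split()[1:4]]
            if spacing is None and max(d) > 0:
                spacing = max(d)
        elif "data follows" in s:
            n_items = int(s.split("items")[1].split()[0])
            in_data = True
        elif in_data and len(data) < n_items:
            data.extend(float(t) for t in s.split())
        elif s.startswith("attribute"):
            in_data = False
    if dims is None or origin is None or spacing is None:
        raise ValueError(f"{path}: not a grid scalar field")
    nx, ny, nz = dims
    vals = np.array(data[: nx * ny * nz])
    # z-fastest -> x-fastest
    vals = vals.reshape(nx, ny, nz).transpose(2, 1, 0).ravel()
    grid = GridSpec(origin=origin, spacing=spacing, dims=dims)
    return VolumeMap(grid=grid, values=vals, field_kind=field_kind, mask=vals != 0)
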