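"""StDev*Coeff contour fields for visualizing a fitted grid-field model.

For one field type, the scalar value at grid point j is
``sd(X_j over the training set) * b_j`` — the classic display quantity for
favored/disfavored regions. Columns removed by the minimum-sigma filter
carry a neutral 0. Contour levels are percentile-based: the favored level
is an upper percentile of the positive contributions and the disfavored
level a lower percentile of the negative ones (default 80/20,
linear-interpolation percentile definition).

Grids export as OpenDX scalar fields, the plain-text format molecular
viewers load for isosurface display.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .fields import GridSpec
from .qsar import PLSModel

logger = logging.getLogger("fieldsar.contours")

__all__ = [
    "ContourSet", "stdev_coeff_grid", "extract_contours",
    "write_opendx", "read_opendx", "export_contour_set",
]


@dataclass
class ContourSet:
    """Percentile-thresholded favored/disfavored regions of one scalar grid."""

    grid: GridSpec | None
    values: np.ndarray             # flat (n_points,)
    favored_level: float | None    # threshold on positive contributions
    disfavored_level: float | None
    percentiles: tuple[float, float]
    favored_mask: np.ndarray       # flat bool
    disfavored_mask: np.ndarray

    def __post_init__(self):
        if (self.favored_level is not None and self.disfavored_level is not None
                and self.favored_level < self.disfavored_level):
            raise ValueError("favored level below disfavored level")


def stdev_coeff_grid(model: PLSModel, X: np.ndarray,
                     column_map: list[tuple[str, int]], field_type: str,
                     n_points: int) -> np.ndarray:
    """Full-grid StDev*Coeff values for one field type; dropped columns 0."""
    types = {f for f, _ in column_map}
    if field_type not in types:
        raise ValueError(f"field type {field_type!r} absent from model (has {sorted(types)})")
    X = np.asarray(X, dtype=float)
    # accept either the training design matrix or a precomputed column-sd vector
    sd = X if X.ndim == 1 else X.std(axis=0, ddof=1)
    out = np.zeros(n_points)
    for (ftype, gidx), s, b in zip(column_map, sd, model.coef_):
        if ftype == field_type:
            out[gidx] = s * b
    return out


def extract_contours(values: np.ndarray, percentiles: tuple[float, float] = (80.0, 20.0),
                     grid: GridSpec | None = None) -> ContourSet:
    """Threshold a StDev*Coeff grid at percentile contour levels.

    The favored level is the upper percentile of the strictly positive
    values, the disfavored level the lower percentile of the strictly
    negative ones; cells at or beyond a level belong to the respective set.
    A degenerate all-equal grid yields an empty contour set with a warning.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("contour grid contains non-finite values")
    upper, lower = percentiles
    pos = values[values > 0]
    neg = values[values < 0]
    if np.ptp(values) == 0:
        warnings.warn("degenerate all-equal contour grid; empty contour set")
        empty = np.zeros(values.shape, dtype=bool)
        return ContourSet(grid, values, None, None, percentiles, empty, empty)
    fav_level = float(np.percentile(pos, upper)) if pos.size else None
    dis_level = float(np.percentile(neg, lower)) if neg.size else None
    fav = values >= fav_level if fav_level is not None else np.zeros(values.shape, bool)
    dis = values <= dis_level if dis_level is not None else np.zeros(values.shape, bool)
    return ContourSet(grid, values, fav_level, dis_level, percentiles, fav, dis)


def write_opendx(path: str | Path, values: np.ndarray, grid: GridSpec) -> None:
    """Write a scalar grid as an OpenDX regular-positions field."""
    nx, ny, nz = grid.dims
    v = np.asarray(values, dtype=float).reshape(nx, ny, nz)
    lines = [
        "# OpenDX scalar field written by fieldsar",
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        "origin {:.6f} {:.6f} {:.6f}".format(*grid.origin),
        f"delta {grid.spacing:.6f} 0.000000 0.000000",
        f"delta 0.000000 {grid.spacing:.6f} 0.000000",
        f"delta 0.000000 0.000000 {grid.spacing:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {v.size} data follows",
    ]
    flat = v.ravel()  # C order == z fastest, the OpenDX convention
    for i in range(0, flat.size, 3):
        lines.append(" ".join(f"{x:.9e}" for x in flat[i:i + 3]))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "density" class field')
    lines.append('component "positions" value 1')
    lines.append('component "connections" value 2')
    lines.append('component "data" value 3')
    Path(path).write_text("\n".join(lines) + "\n")


def read_opendx(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    """Read a scalar grid written by :func:`write_opendx`."""
    dims = origin = None
    spacing = []
    data: list[float] = []
    n_items = None
    in_data = False
    for line in Path(path).read_text().splitlines():
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        if in_data:
            if s.startswith("attribute") or s.startswith("object"):
                in_data = False
            else:
                data.extend(float(x) for x in s.split())
                if n_items is not None and len(data) >= n_items:
                    in_data = False
            continue
        if s.startswith("object 1"):
            dims = tuple(int(x) for x in s.split()[-3:])
        elif s.startswith("origin"):
            origin = tuple(float(x) for x in s.split()[1:4])
        elif s.startswith("delta"):
            spacing.append(max(float(x) for x in s.split()[1:4]))
        elif "data follows" in s:
            n_items = int(s.split()[-3])
            in_data = True
    if dims is None or origin is None or not spacing:
        raise ValueError(f"not a fieldsar OpenDX grid: {path}")
    grid = GridSpec(origin=origin, spacing=spacing[0], dims=dims)
    return np.array(data).reshape(dims).ravel(), grid


def export_contour_set(cs: ContourSet, out_dir: str | Path, field_type: str) -> list[Path]:
    """Export a contour set as OpenDX grids: the raw StDev*Coeff field plus
    masked favored/disfavored grids (one file per sign)."""
    if cs.grid is None:
        raise ValueError("contour set has no grid; cannot export")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    spec = [
        (f"{field_type}_stdevcoeff.dx", cs.values),
        (f"{field_type}_favored.dx", np.where(cs.favored_mask, cs.values, 0.0)),
        (f"{field_type}_disfavored.dx", np.where(cs.disfavored_mask, cs.values, 0.0)),
    ]
    for name, vals in spec:
        p = out_dir / name
        write_opendx(p, vals, cs.grid)
        paths.append(p)
    return paths
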