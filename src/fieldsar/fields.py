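"""Grid-field descriptors for aligned molecule sets.

Two descriptor families are computed on a shared rectilinear lattice
(default 2.0 Å spacing):

* CoMFA: probe-atom interaction energies, steric via a 12-6 Lennard-Jones
  potential and electrostatic via a Coulomb potential with a
  distance-dependent dielectric, both capped at ±30 kcal/mol. Electrostatic
  values at lattice points buried inside the steric-capped envelope of a
  molecule are replaced by the training-set column mean (the classic
  within-cap masking convention).
* CoMSIA: Gaussian-attenuated similarity indices,
  ``A_k(j) = -sum_i w_probe,k * w_ik * exp(-alpha * r_ij^2)``, for five
  properties: steric (w ∝ r_vdW³), electrostatic (w = partial charge),
  hydrophobic, H-bond donor and H-bond acceptor (w from simple atom-type
  rules). The Gaussian never diverges, so no caps are needed.

The design-matrix assembly drops low-variance columns (minimum-sigma
filtering) and block-scales each field to equal total variance, with all
statistics fitted on the training set only and frozen for test/query
molecules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np

from .chemio import MoleculeRecord

logger = logging.getLogger("fieldsar.fields")

__all__ = [
    "KE", "GridSpec", "ProbeSpec", "SP3_CARBON_PROBE", "FieldBlock", "FieldSet",
    "build_grid", "comfa_fields", "comsia_fields",
    "compute_comfa_set", "compute_comsia_set",
    "DesignAssembler", "assemble_design_matrix",
]

#: Coulomb constant in kcal·Å/(mol·e²)
KE = 332.0636

#: default CoMFA/CoMSIA energy cap, kcal/mol
DEFAULT_CAP = 30.0

#: default CoMSIA Gaussian attenuation, Å^-2
DEFAULT_ALPHA = 0.3


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned rectilinear lattice. Points are ordered C-style with the
    z index fastest: ``flat = ix*ny*nz + iy*nz + iz``."""

    origin: tuple[float, float, float]
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("grid spacing must be > 0")
        if any(d < 1 for d in self.dims):
            raise ValueError("grid dims must be >= 1")

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def points(self) -> np.ndarray:
        """(n_points, 3) lattice coordinates in Å."""
        axes = [np.asarray(self.origin)[k] + self.spacing * np.arange(self.dims[k])
                for k in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


@dataclass(frozen=True)
class ProbeSpec:
    """The probe atom placed at every lattice point: by default an sp³
    carbon with charge +1.0 e."""

    charge: float = 1.0            # e
    rstar: float = 1.70            # Å
    eps: float = 0.107             # kcal/mol
    element: str = "C.3"

    def __post_init__(self):
        if self.rstar <= 0:
            raise ValueError("probe radius must be > 0")
        if self.eps < 0:
            raise ValueError("probe well depth must be >= 0")


SP3_CARBON_PROBE = ProbeSpec()


@dataclass
class FieldBlock:
    """Molecules × grid-points descriptor matrix for one field type."""

    field_type: str                 # S, E, H, D, A
    model_family: str               # CoMFA | CoMSIA
    values: np.ndarray              # (n_molecules, n_points)
    cap: float | None = None        # kcal/mol, CoMFA only
    capped_count: int = 0
    kept_columns: np.ndarray | None = None


@dataclass
class FieldSet:
    """All field blocks of one model family for one molecule set."""

    model_family: str
    blocks: dict[str, np.ndarray]
    grid: GridSpec
    cap_mask: np.ndarray | None = None   # (n_mol, n_points) steric-cap envelope
    ids: list[str] = dc_field(default_factory=list)

    @property
    def field_types(self) -> list[str]:
        return list(self.blocks)

    @property
    def n_molecules(self) -> int:
        return next(iter(self.blocks.values())).shape[0]

    def subset(self, rows) -> "FieldSet":
        rows = np.asarray(rows)
        return FieldSet(
            model_family=self.model_family,
            blocks={k: v[rows] for k, v in self.blocks.items()},
            grid=self.grid,
            cap_mask=None if self.cap_mask is None else self.cap_mask[rows],
            ids=[self.ids[i] for i in rows] if self.ids else [],
        )


def build_grid(records: list[MoleculeRecord], spacing: float = 2.0,
               padding: float = 4.0) -> GridSpec:
    """Minimal lattice covering every atom of every record plus ``padding``
    Å on all sides, centred on the padded bounding box."""
    if not records:
        raise ValueError("cannot build a grid from an empty record list")
    allc = np.vstack([r.coords for r in records])
    lo = allc.min(axis=0) - padding
    hi = allc.max(axis=0) + padding
    span = hi - lo
    dims = tuple(int(np.ceil(s / spacing)) + 1 for s in span)
    center = (lo + hi) / 2.0
    origin = tuple(center[k] - (dims[k] - 1) * spacing / 2.0 for k in range(3))
    return GridSpec(origin=origin, spacing=spacing, dims=dims)


def comfa_fields(record: MoleculeRecord, grid: GridSpec,
                 probe: ProbeSpec = SP3_CARBON_PROBE, cap: float = DEFAULT_CAP,
                 dielectric: str = "distance",
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """CoMFA steric (LJ 12-6) and electrostatic (Coulomb) probe energies.

    Combining rules: ``R_ij = R*_probe + R*_i``, ``eps_ij =
    sqrt(eps_probe * eps_i)``. The electrostatic term uses a
    distance-dependent dielectric ``eps(r) = r`` by default
    (``dielectric="constant"`` selects vacuum permittivity 1).

    Returns ``(steric, electrostatic, cap_mask)`` where ``cap_mask`` marks
    points whose *steric* energy hit the positive cap (probe inside the
    molecule); electrostatic values there are later replaced by training
    column means during assembly.
    """
    if record.charges is None:
        raise ValueError(f"molecule {record.id}: assign partial charges first")
    pts = grid.points()
    # r: (n_atoms, n_points)
    diff = record.coords[:, None, :] - pts[None, :, :]
    r = np.sqrt(np.einsum("apk,apk->ap", diff, diff))

    rij = probe.rstar + record.rstar
    eij = np.sqrt(probe.eps * record.eps)
    r_safe = np.maximum(r, 1e-12)  # atom exactly on a lattice point
    with np.errstate(over="ignore", invalid="ignore"):
        x = (rij[:, None] / r_safe) ** 6
        lj = eij[:, None] * (x * x - 2.0 * x)
        # overflow at tiny r means unbounded repulsion
        lj = np.where(np.isfinite(lj), lj, np.inf)
        steric = lj.sum(axis=0)
        denom = r_safe * r_safe if dielectric == "distance" else r_safe
        elec = (KE * probe.charge * record.charges[:, None] / denom).sum(axis=0)
    cap_mask = steric >= cap
    steric = np.clip(np.nan_to_num(steric, nan=cap, posinf=cap, neginf=-cap), -cap, cap)
    elec = np.clip(np.nan_to_num(elec, nan=cap, posinf=cap, neginf=-cap), -cap, cap)
    return steric, elec, cap_mask


#: probe property weight per CoMSIA field type
COMSIA_PROBE_WEIGHTS = {"S": 1.0, "E": 1.0, "H": 1.0, "D": 1.0, "A": 1.0}


def comsia_fields(record: MoleculeRecord, grid: GridSpec,
                  alpha: float = DEFAULT_ALPHA,
                  probe_weights: dict[str, float] = COMSIA_PROBE_WEIGHTS,
                  ) -> dict[str, np.ndarray]:
    """Gaussian similarity indices for the five CoMSIA properties.

    ``A_k(j) = -sum_i w_probe,k * w_ik * exp(-alpha * r_ij^2)`` with atom
    properties: steric r_vdW³, electrostatic partial charge, hydrophobic /
    donor / acceptor from the chemio flag rules.
    """
    if alpha <= 0:
        raise ValueError("CoMSIA attenuation alpha must be > 0")
    if record.charges is None:
        raise ValueError(f"molecule {record.id}: assign partial charges first")
    pts = grid.points()
    diff = record.coords[:, None, :] - pts[None, :, :]
    r2 = np.einsum("apk,apk->ap", diff, diff)
    g = np.exp(-alpha * r2)           # (n_atoms, n_points)
    props = {
        "S": record.rstar ** 3,
        "E": record.charges,
        "H": record.hydrophobe,
        "D": record.donor.astype(float),
        "A": record.acceptor.astype(float),
    }
    return {k: -probe_weights[k] * (props[k][:, None] * g).sum(axis=0) for k in props}


def compute_comfa_set(records: list[MoleculeRecord], grid: GridSpec,
                      probe: ProbeSpec = SP3_CARBON_PROBE,
                      cap: float = DEFAULT_CAP,
                      dielectric: str = "distance") -> FieldSet:
    S, E, M = [], [], []
    for rec in records:
        s, e, m = comfa_fields(rec, grid, probe, cap, dielectric)
        S.append(s); E.append(e); M.append(m)
    return FieldSet("CoMFA", {"S": np.array(S), "E": np.array(E)}, grid,
                    cap_mask=np.array(M), ids=[r.id for r in records])


def compute_comsia_set(records: list[MoleculeRecord], grid: GridSpec,
                       alpha: float = DEFAULT_ALPHA) -> FieldSet:
    rows: dict[str, list[np.ndarray]] = {k: [] for k in "SEHDA"}
    for rec in records:
        vals = comsia_fields(rec, grid, alpha)
        for k in rows:
            rows[k].append(vals[k])
    return FieldSet("CoMSIA", {k: np.array(v) for k, v in rows.items()}, grid,
                    ids=[r.id for r in records])


class DesignAssembler:
    """Fits masking/filtering/scaling statistics on a training field set and
    applies them, frozen, to any other set on the same grid.

    Steps, in order:

    1. CoMFA electrostatic masking: entries inside a molecule's steric-cap
       envelope are replaced by the training column mean over unmasked
       entries (0 where a column is masked for every training molecule).
    2. Minimum-sigma filtering: columns with training standard deviation
       (ddof=1) below ``sigma_min`` are dropped.
    3. Block scaling: each field block is scaled so its kept columns have
       unit total variance, giving every field equal a-priori weight.
    """

    def __init__(self, sigma_min: float = 2.0, block_scale: bool = True):
        self.sigma_min = sigma_min
        self.block_scale = block_scale
        self.fitted = False

    def fit(self, fs: FieldSet) -> "DesignAssembler":
        self.field_types_ = fs.field_types
        self.e_col_means_ = None
        blocks = {k: v.copy() for k, v in fs.blocks.items()}
        if fs.cap_mask is not None and "E" in blocks:
            E = blocks["E"]
            mask = fs.cap_mask
            with np.errstate(invalid="ignore"):
                col_sum = np.where(mask, 0.0, E).sum(axis=0)
                col_n = (~mask).sum(axis=0)
                means = np.where(col_n > 0, col_sum / np.maximum(col_n, 1), 0.0)
            self.e_col_means_ = means
            blocks["E"] = np.where(mask, means[None, :], E)

        sds, keeps = {}, {}
        for k, v in blocks.items():
            sd = v.std(axis=0, ddof=1)
            sds[k] = sd
            keeps[k] = sd >= self.sigma_min if self.sigma_min > 0 else np.ones(v.shape[1], bool)
        n_kept = sum(int(k.sum()) for k in keeps.values())
        if n_kept == 0:
            raise ValueError(
                f"minimum-sigma filter ({self.sigma_min}) removed every column; "
                "use a smaller sigma_min")
        self.kept_ = keeps
        self.scales_ = {}
        for k in blocks:
            if self.block_scale:
                tot_var = float((sds[k][keeps[k]] ** 2).sum())
                self.scales_[k] = 1.0 / np.sqrt(tot_var) if tot_var > 0 else 1.0
            else:
                self.scales_[k] = 1.0
        self.column_map_ = [(k, int(j)) for k in blocks for j in np.flatnonzero(keeps[k])]
        self.fitted = True
        return self

    def transform(self, fs: FieldSet) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("DesignAssembler.transform before fit")
        if fs.field_types != self.field_types_:
            raise ValueError("field set does not match fitted assembler")
        cols = []
        for k in self.field_types_:
            v = fs.blocks[k]
            if k == "E" and self.e_col_means_ is not None and fs.cap_mask is not None:
                v = np.where(fs.cap_mask, self.e_col_means_[None, :], v)
            cols.append(v[:, self.kept_[k]] * self.scales_[k])
        return np.hstack(cols)

    def fit_transform(self, fs: FieldSet) -> np.ndarray:
        return self.fit(fs).transform(fs)


def assemble_design_matrix(fs: FieldSet, sigma_min: float = 2.0,
                           block_scale: bool = True,
                           ) -> tuple[np.ndarray, list[tuple[str, int]], DesignAssembler]:
    """Fit-and-transform convenience wrapper around :class:`DesignAssembler`.

    Returns ``(X, column_map, assembler)``; the column map pairs each kept
    design column with its (field_type, grid flat index) for contouring.
    """
    asm = DesignAssembler(sigma_min=sigma_min, block_scale=block_scale)
    X = asm.fit_transform(fs)
    return X, asm.column_map_, asm
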