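"""Essential dynamics: Cartesian covariance analysis of a trajectory.

The covariance matrix over the selected atoms (Cα by default) is
``C_ij = <(x_i - <x_i>)(x_j - <x_j>)>`` with the brackets averaging over
frames after rigid superposition onto the mean structure. Its symmetric
eigendecomposition yields the principal components: eigenvalues (Å²) are
motion amplitudes, eigenvectors the directions, and projections of the
centered coordinates onto the eigenvectors give the per-frame essential
coordinates.

Derived analyses:

* DCCM — per-residue normalized cross-correlations
  ``<Δr_i·Δr_j> / sqrt(<|Δr_i|²><|Δr_j|²>)`` in [-1, 1]; +1 correlated,
  -1 anticorrelated motion.
* Free-energy landscape — 2D frame-occupancy histogram over (PC1, PC2)
  mapped through ``ΔG = -kT ln(P / P_max)`` so the most occupied bin sits
  at 0; local minima are metastable conformational states.
* Porcupine vectors — per-atom displacement arrows for one principal
  component, scaled by the projection range between the two extreme frames.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import kabsch, apply_rigid
from .trajio import Trajectory

logger = logging.getLogger("fieldsar.essdyn")

__all__ = [
    "CovarianceModel", "FELGrid",
    "covariance_and_pca", "dccm", "free_energy_landscape", "porcupine_vectors",
    "write_porcupine_pdb",
]

#: Boltzmann constant, kcal/(mol·K)
KB = 0.0019872041


@dataclass
class CovarianceModel:
    """Covariance matrix, eigensystem and projections of one selection."""

    selection: np.ndarray          # atom indices into the trajectory
    resids: np.ndarray             # per selected atom
    mean: np.ndarray               # (n_sel, 3) mean structure, Å
    covariance: np.ndarray         # (3n, 3n) Å²
    eigenvalues: np.ndarray        # (3n,) Å², descending
    eigenvectors: np.ndarray       # (3n, 3n), columns, orthonormal
    projections: np.ndarray        # (n_frames, 3n) Å
    centered: np.ndarray           # (n_frames, 3n) superposed centered coords


def covariance_and_pca(traj: Trajectory, selection: np.ndarray | None = None,
                       superpose_iterations: int = 2) -> CovarianceModel:
    """Covariance matrix and PCA of the selected atoms (default Cα).

    Frames are superposed onto the mean structure (iterated) before the
    covariance is formed, so rigid-body motion does not masquerade as an
    internal mode. Eigenvector signs follow a fixed convention: the
    largest-magnitude element of each is made positive.
    """
    if traj.n_frames < 2:
        raise ValueError("covariance analysis needs at least 2 frames")
    sel = traj.select_ca() if selection is None else np.asarray(selection)
    if sel.size == 0:
        raise ValueError("empty selection")
    coords = traj.coords[:, sel, :].copy()
    static = np.allclose(coords, coords[0], atol=1e-12)
    if not static:
        for _ in range(superpose_iterations):
            mean = coords.mean(axis=0)
            for f in range(coords.shape[0]):
                R, t, _ = kabsch(coords[f], mean)
                coords[f] = apply_rigid(coords[f], R, t)
    mean = coords.mean(axis=0)
    Xc = (coords - mean).reshape(traj.n_frames, -1)
    C = Xc.T @ Xc / traj.n_frames
    C = (C + C.T) / 2.0
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # deterministic sign: largest-|component| positive
    for k in range(evecs.shape[1]):
        j = int(np.argmax(np.abs(evecs[:, k])))
        if evecs[j, k] < 0:
            evecs[:, k] = -evecs[:, k]
    proj = Xc @ evecs
    return CovarianceModel(selection=sel, resids=traj.top.resid[sel].copy(),
                           mean=mean, covariance=C, eigenvalues=evals,
                           eigenvectors=evecs, projections=proj, centered=Xc)


def dccm(model: CovarianceModel) -> pd.DataFrame:
    """Dynamic cross-correlation matrix over the selected residues.

    Entry (i, j) is ``<Δr_i·Δr_j> / sqrt(<|Δr_i|²><|Δr_j|²>)``, where Δr is
    the 3D displacement vector of the residue's selected atom(s)' centroid.
    Zero-variance residues yield masked (NaN) entries with a warning.
    """
    resids = model.resids
    unique = pd.unique(resids)
    n_frames = model.centered.shape[0]
    disp = np.empty((n_frames, len(unique), 3))
    cent3 = model.centered.reshape(n_frames, -1, 3)
    for k, rid in enumerate(unique):
        m = resids == rid
        disp[:, k, :] = cent3[:, m, :].mean(axis=1)
    inner = np.einsum("fik,fjk->ij", disp, disp) / n_frames
    var = np.diag(inner).copy()
    zero = var <= 0
    if zero.any():
        warnings.warn(f"zero-variance residues masked in DCCM: {unique[zero].tolist()}")
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt(np.outer(var, var))
        M = np.where(denom > 0, inner / np.where(denom > 0, denom, 1.0), np.nan)
    M = np.where(np.isfinite(M), np.clip(M, -1.0, 1.0), np.nan)
    return pd.DataFrame(M, index=unique, columns=unique)


@dataclass
class FELGrid:
    """Free-energy landscape over the first two essential coordinates."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    free_energy: np.ndarray        # (bins, bins) kT; NaN where unoccupied
    minima: list                   # [(ix, iy, depth kT, occupancy), ...]
    temperature: float             # K
    counts: np.ndarray

    def in_kcal(self) -> np.ndarray:
        return self.free_energy * KB * self.temperature


def free_energy_landscape(projections: np.ndarray, bins: int = 32,
                          temperature: float = 300.0,
                          components: tuple[int, int] = (0, 1)) -> FELGrid:
    """2D occupancy histogram over (PC1, PC2) mapped through
    ``ΔG(bin) = -kT ln(P(bin)/P_max)``; occupied bins are >= 0 with the
    modal bin at exactly 0, unoccupied bins are masked (NaN). Minima are
    8-neighbourhood local minima among occupied bins, ranked by depth then
    occupancy."""
    if bins <= 0:
        raise ValueError("bins must be positive")
    proj = np.asarray(projections, dtype=float)
    pc1 = proj[:, components[0]]
    pc2 = proj[:, components[1]]
    counts, xe, ye = np.histogram2d(pc1, pc2, bins=bins)
    pmax = counts.max()
    with np.errstate(divide="ignore"):
        fel = np.where(counts > 0, -np.log(counts / pmax), np.nan)
    minima = []
    nx, ny = fel.shape
    for i in range(nx):
        for j in range(ny):
            if not np.isfinite(fel[i, j]):
                continue
            nb = fel[max(0, i - 1):i + 2, max(0, j - 1):j + 2]
            finite_nb = nb[np.isfinite(nb)]
            if fel[i, j] <= finite_nb.min():
                minima.append((i, j, float(fel[i, j]), int(counts[i, j])))
    minima.sort(key=lambda m: (m[2], -m[3]))
    return FELGrid(x_edges=xe, y_edges=ye, free_energy=fel, minima=minima,
                   temperature=temperature, counts=counts)


def porcupine_vectors(model: CovarianceModel, component: int = 0) -> np.ndarray:
    """Per-atom displacement arrows for one principal component.

    Each selected atom's vector is its eigenvector segment scaled by the
    signed projection change between the two extreme frames along that
    component (chronological order: the later extreme minus the earlier
    one), so arrow lengths reflect the actual motion amplitude in Å and
    reversing the frame order flips only the arrow signs.
    """
    v = model.eigenvectors[:, component].reshape(-1, 3)
    proj = model.projections[:, component]
    i_lo, i_hi = int(np.argmin(proj)), int(np.argmax(proj))
    t1, t2 = min(i_lo, i_hi), max(i_lo, i_hi)
    span = float(proj[t2] - proj[t1])
    return v * span


def write_porcupine_pdb(model: CovarianceModel, path: str | Path,
                        component: int = 0, tsv_path: str | Path | None = None) -> None:
    """Export porcupine arrows as pairs of pseudo-atoms (base at the mean
    structure, tip displaced by the mode vector), plus an optional TSV."""
    vecs = porcupine_vectors(model, component)
    base = model.mean
    tip = base + vecs
    lines = []
    serial = 1
    for k in range(base.shape[0]):
        for tag, xyz in (("BAS", base[k]), ("TIP", tip[k])):
            lines.append(
                f"HETATM{serial:>5} {tag:<4} VEC A{k + 1:>4}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
            )
            serial += 1
        lines.append(f"CONECT{serial - 2:>5}{serial - 1:>5}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
    if tsv_path is not None:
        df = pd.DataFrame({
            "resid": model.resids,
            "bx": base[:, 0], "by": base[:, 1], "bz": base[:, 2],
            "vx": vecs[:, 0], "vy": vecs[:, 1], "vz": vecs[:, 2],
            "length": np.linalg.norm(vecs, axis=1),
        })
        df.to_csv(tsv_path, sep="\t", index=False)
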