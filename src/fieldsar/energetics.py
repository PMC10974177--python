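"""Binding free-energy estimation in the MM-PB(GB)SA spirit.

Per frame of a complex trajectory, under the single-trajectory
approximation (the complex geometry is reused for the unbound protein and
ligand, so intra-partition terms cancel):

* ``ΔG_bind = ΔE_gas + ΔG_sol - TΔS`` with the entropy term kept as an
  explicit slot, fixed at 0 ("neglected"),
* ``ΔE_gas = ΔE_vdw + ΔE_ele`` — protein–ligand cross Lennard-Jones 12-6
  (``R_ij = R*_i + R*_j``, ``eps_ij = sqrt(eps_i eps_j)``) and Coulomb
  (constant dielectric 1, k_e = 332.0636 kcal·Å/(mol·e²)) interactions,
* ``ΔG_sol = ΔG_pol + ΔG_SA`` where ``ΔG_SA = γ·ΔSASA`` (Shrake–Rupley
  surface areas, γ default 0.00542 kcal/(mol·Å²), no offset) and the polar
  term is a pairwise generalized-Born-style screening model
  (``polar_model="gb_like"``; a finite-difference Poisson–Boltzmann solver
  is deliberately not implemented — ``polar_model="off"`` disables the
  term).

The per-residue decomposition assigns each cross pair's MM + polar energy
half to each partner's residue and each atom's γ·ΔSASA to its own residue,
so the residue contributions sum exactly to the decomposable total.
Residues contributing ≤ -1 kcal/mol are flagged as hot spots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .fields import KE
from .trajio import Trajectory, Topology

logger = logging.getLogger("fieldsar.energetics")

__all__ = [
    "EnergyReport", "ResidueDecomposition",
    "interaction_energy_mm", "sasa", "solvation_terms",
    "binding_free_energy", "per_residue_decomposition",
]

#: water relative permittivity for the GB-like screening term
EPS_WATER = 78.5

#: default surface-tension coefficient, kcal/(mol·Å²)
DEFAULT_GAMMA = 0.00542


def _check_params(top: Topology) -> None:
    bad = np.flatnonzero(~np.isfinite(top.charge) | ~np.isfinite(top.rstar)
                         | ~np.isfinite(top.eps))
    if bad.size:
        raise ValueError(f"missing charge/LJ parameters for atoms {bad.tolist()}")


def _cross_distances(c: np.ndarray, p_idx: np.ndarray, l_idx: np.ndarray) -> np.ndarray:
    d = c[p_idx][:, None, :] - c[l_idx][None, :, :]
    return np.sqrt(np.einsum("ijk,ijk->ij", d, d))


def interaction_energy_mm(frame_coords: np.ndarray, top: Topology,
                          ligand_mask: np.ndarray) -> tuple[float, float]:
    """Protein–ligand cross MM interaction energies (kcal/mol): LJ 12-6 and
    Coulomb with dielectric 1. Intra-partition terms are omitted — they
    cancel in the single-trajectory binding difference."""
    _check_params(top)
    lig = np.asarray(ligand_mask, dtype=bool)
    p_idx = np.flatnonzero(~lig)
    l_idx = np.flatnonzero(lig)
    c = np.asarray(frame_coords, dtype=float)
    r = _cross_distances(c, p_idx, l_idx)
    rij = top.rstar[p_idx][:, None] + top.rstar[l_idx][None, :]
    eij = np.sqrt(top.eps[p_idx][:, None] * top.eps[l_idx][None, :])
    x = (rij / r) ** 6
    e_vdw = float((eij * (x * x - 2.0 * x)).sum())
    e_ele = float((KE * top.charge[p_idx][:, None] * top.charge[l_idx][None, :] / r).sum())
    return e_vdw, e_ele


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (Fibonacci lattice)."""
    k = np.arange(n) + 0.5
    cos_phi = 1.0 - 2.0 * k / n
    sin_phi = np.sqrt(1.0 - cos_phi ** 2)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack([sin_phi * np.cos(theta), sin_phi * np.sin(theta), cos_phi])


def sasa(frame_coords: np.ndarray, radii: np.ndarray,
         selection: np.ndarray | None = None,
         probe: float = 1.4, n_points: int = 960) -> np.ndarray:
    """Shrake–Rupley solvent-accessible surface area, per atom (Å²).

    Each atom is expanded by the probe radius and sampled with a
    deterministic Fibonacci point set; a point is accessible when outside
    every other expanded sphere. Only atoms in ``selection`` occlude and
    are reported (default: all)."""
    c = np.asarray(frame_coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    sel = np.arange(c.shape[0]) if selection is None else np.asarray(selection)
    cs = c[sel]
    rs = radii[sel] + probe
    sphere = _fibonacci_sphere(n_points)
    out = np.zeros(len(sel))
    for a in range(len(sel)):
        pts = cs[a] + rs[a] * sphere
        nb = np.flatnonzero(
            (np.linalg.norm(cs - cs[a], axis=1) < rs + rs[a]))
        nb = nb[nb != a]
        accessible = np.ones(n_points, dtype=bool)
        for b in nb:
            d = np.linalg.norm(pts - cs[b], axis=1)
            accessible &= d >= rs[b]
            if not accessible.any():
                break
        out[a] = 4.0 * np.pi * rs[a] ** 2 * accessible.mean()
    return out


def _gb_pair_matrix(r: np.ndarray, born_p: np.ndarray, born_l: np.ndarray,
                    q_p: np.ndarray, q_l: np.ndarray) -> np.ndarray:
    """Pairwise GB-style screened cross interaction (kcal/mol per pair)."""
    RiRj = born_p[:, None] * born_l[None, :]
    f_gb = np.sqrt(r * r + RiRj * np.exp(-r * r / (4.0 * RiRj)))
    return -KE * (1.0 - 1.0 / EPS_WATER) * q_p[:, None] * q_l[None, :] / f_gb


def solvation_terms(frame_coords: np.ndarray, top: Topology,
                    ligand_mask: np.ndarray, gamma: float = DEFAULT_GAMMA,
                    polar_model: str = "gb_like",
                    sasa_points: int = 960) -> tuple[float, float]:
    """Solvation change on binding: ``(ΔG_pol, ΔG_SA)`` in kcal/mol.

    ``ΔG_SA = γ·(SASA_complex - SASA_protein - SASA_ligand)`` with each
    partition's SASA computed on its own atoms (single-trajectory
    geometry). The polar term, with fixed Born radii, reduces to the
    screened cross-pair sum."""
    if gamma < 0:
        raise ValueError("surface-tension coefficient gamma must be >= 0")
    lig = np.asarray(ligand_mask, dtype=bool)
    p_idx = np.flatnonzero(~lig)
    l_idx = np.flatnonzero(lig)
    c = np.asarray(frame_coords, dtype=float)

    if gamma == 0.0:
        dg_sa = 0.0
    else:
        sasa_c = sasa(c, top.rstar, n_points=sasa_points).sum()
        sasa_p = sasa(c, top.rstar, selection=p_idx, n_points=sasa_points).sum()
        sasa_l = sasa(c, top.rstar, selection=l_idx, n_points=sasa_points).sum()
        dg_sa = float(gamma * (sasa_c - sasa_p - sasa_l))

    if polar_model == "off":
        dg_pol = 0.0
    elif polar_model == "gb_like":
        r = _cross_distances(c, p_idx, l_idx)
        dg_pol = float(_gb_pair_matrix(r, top.rstar[p_idx], top.rstar[l_idx],
                                       top.charge[p_idx], top.charge[l_idx]).sum())
    else:
        raise ValueError(f"unknown polar model {polar_model!r}")
    return dg_pol, dg_sa


@dataclass
class EnergyReport:
    """Per-frame and averaged binding-energy terms (kcal/mol)."""

    frames: np.ndarray                      # frame indices of the window
    per_frame: pd.DataFrame                 # columns: the term names below
    mean: dict = dc_field(default_factory=dict)
    sd: dict = dc_field(default_factory=dict)
    gamma: float = DEFAULT_GAMMA
    tds: float = 0.0                        # entropy term, kept and neglected
    polar_model: str = "gb_like"

    TERMS = ("E_ele", "E_vdw", "E_gas", "G_pol", "G_SA", "G_sol", "G_bind")


def binding_free_energy(traj: Trajectory, ligand_mask: np.ndarray,
                        window: float = 0.1, gamma: float = DEFAULT_GAMMA,
                        polar_model: str = "gb_like",
                        sasa_points: int = 960) -> EnergyReport:
    """Binding free energy over the final ``window`` fraction of frames
    (default 10%, mirroring the convention of averaging the last segment of
    a production run). Reports per-frame terms and mean ± SD.

    The additive identities (gas = vdw + ele; sol = pol + SA;
    bind = gas + sol - TΔS) are asserted per frame.
    """
    if not 0 < window <= 1:
        raise ValueError("window must be a fraction in (0, 1]")
    n = traj.n_frames
    n_win = max(1, int(np.ceil(window * n)))
    frames = np.arange(n - n_win, n)
    rows = []
    for f in frames:
        c = traj.coords[f]
        e_vdw, e_ele = interaction_energy_mm(c, traj.top, ligand_mask)
        g_pol, g_sa = solvation_terms(c, traj.top, ligand_mask, gamma,
                                      polar_model, sasa_points)
        e_gas = e_vdw + e_ele
        g_sol = g_pol + g_sa
        g_bind = e_gas + g_sol - 0.0
        assert abs(e_gas - (e_vdw + e_ele)) < 1e-9
        assert abs(g_sol - (g_pol + g_sa)) < 1e-9
        assert abs(g_bind - (e_gas + g_sol)) < 1e-9
        rows.append({"frame": f, "E_ele": e_ele, "E_vdw": e_vdw, "E_gas": e_gas,
                     "G_pol": g_pol, "G_SA": g_sa, "G_sol": g_sol, "G_bind": g_bind})
    df = pd.DataFrame(rows)
    mean = {k: float(df[k].mean()) for k in EnergyReport.TERMS}
    sd = {k: float(df[k].std(ddof=0)) for k in EnergyReport.TERMS}
    return EnergyReport(frames=frames, per_frame=df, mean=mean, sd=sd,
                        gamma=gamma, tds=0.0, polar_model=polar_model)


@dataclass
class ResidueDecomposition:
    """Per-residue share of the decomposable binding energy."""

    table: pd.DataFrame        # resid, resname, is_ligand, contribution, hot_spot
    total: float               # kcal/mol; equals the sum of contributions
    hotspot_cutoff: float = -1.0


def per_residue_decomposition(traj: Trajectory, ligand_mask: np.ndarray,
                              window: float = 0.1, gamma: float = DEFAULT_GAMMA,
                              polar_model: str = "gb_like",
                              sasa_points: int = 960,
                              hotspot_cutoff: float = -1.0) -> ResidueDecomposition:
    """Decompose the window-averaged binding energy over residues.

    Cross-pair MM and polar energies split half/half between the two
    partner residues; each atom's γ·ΔSASA goes to its own residue. The
    ligand appears as its own residue row. Hot spots are residues at or
    below ``hotspot_cutoff`` (default -1 kcal/mol)."""
    _check_params(traj.top)
    top = traj.top
    lig = np.asarray(ligand_mask, dtype=bool)
    p_idx = np.flatnonzero(~lig)
    l_idx = np.flatnonzero(lig)
    n = traj.n_frames
    n_win = max(1, int(np.ceil(window * n)))
    frames = np.arange(n - n_win, n)

    contrib: dict[int, float] = {}

    def add(resid: int, value: float):
        contrib[resid] = contrib.get(resid, 0.0) + value

    total = 0.0
    for f in frames:
        c = traj.coords[f]
        r = _cross_distances(c, p_idx, l_idx)
        rij = top.rstar[p_idx][:, None] + top.rstar[l_idx][None, :]
        eij = np.sqrt(top.eps[p_idx][:, None] * top.eps[l_idx][None, :])
        x = (rij / r) ** 6
        pair = eij * (x * x - 2.0 * x)
        pair = pair + KE * top.charge[p_idx][:, None] * top.charge[l_idx][None, :] / r
        if polar_model == "gb_like":
            pair = pair + _gb_pair_matrix(r, top.rstar[p_idx], top.rstar[l_idx],
                                          top.charge[p_idx], top.charge[l_idx])
        half_p = pair.sum(axis=1) / 2.0
        half_l = pair.sum(axis=0) / 2.0
        for i, e in zip(p_idx, half_p):
            add(int(top.resid[i]), float(e) / n_win)
        for j, e in zip(l_idx, half_l):
            add(int(top.resid[j]), float(e) / n_win)
        total += float(pair.sum()) / n_win

        if gamma > 0:
            sasa_c = sasa(c, top.rstar, n_points=sasa_points)
            sasa_p = sasa(c, top.rstar, selection=p_idx, n_points=sasa_points)
            sasa_l = sasa(c, top.rstar, selection=l_idx, n_points=sasa_points)
            d_atom = np.zeros(traj.n_atoms)
            d_atom[p_idx] = sasa_c[p_idx] - sasa_p
            d_atom[l_idx] = sasa_c[l_idx] - sasa_l
            for i in range(traj.n_atoms):
                add(int(top.resid[i]), float(gamma * d_atom[i]) / n_win)
            total += float(gamma * d_atom.sum()) / n_win

    rows = []
    resid_to_name = {int(r): str(nm) for r, nm in zip(top.resid, top.resname)}
    lig_resids = {int(r) for r in top.resid[l_idx]}
    for rid in sorted(contrib):
        val = contrib[rid]
        rows.append({"resid": rid, "resname": resid_to_name.get(rid, "?"),
                     "is_ligand": rid in lig_resids, "contribution": val,
                     "hot_spot": val <= hotspot_cutoff})
    table = pd.DataFrame(rows)
    if abs(table["contribution"].sum() - total) > 1e-6:
        raise AssertionError("per-residue contributions do not sum to the total")
    return ResidueDecomposition(table=table, total=total,
                                hotspot_cutoff=hotspot_cutoff)
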