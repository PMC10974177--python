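"""Synthetic inputs with known ground truth.

Three generators cover the pipeline end to end:

* :func:`gen_qsar_set` — a congeneric series of isoxazole-phenyl molecules
  sharing an *exact* common scaffold geometry, decorated at four ring
  positions from a small substituent menu. The activity is planted as a
  linear function of actual computed steric grid-field columns plus
  Gaussian noise, scaled into the 6–10 pEC50 range, so the whole
  alignment -> fields -> PLS chain is exercised against a known coefficient
  vector.
* :func:`gen_trajectory` — a helical pseudo-protein with planted harmonic
  modes (correlated / anticorrelated residue pairs), optional thermal
  jitter, and a static interaction scene (hydrogen bond, salt bridge,
  hydrophobic contact, plus matched negative decoys) with geometries that
  satisfy or violate the detection criteria by construction.
* :func:`gen_complex` — a protein–ligand scene with charges and LJ
  parameters, together with an independent brute-force energy sheet
  (plain Python pair loops) for oracle testing of the energetics module.

Every generator is deterministic under a fixed seed and emits its ground
truth; emitted coordinates are rounded (1e-4 Å for SDF molecules, 1e-3 Å
for PDB-bound trajectories, 1e-6 Å for complex scenes) so that written
files re-read losslessly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from rdkit import Chem
from rdkit.Geometry import Point3D

from . import fields as flds
from .chemio import MoleculeRecord, assign_partial_charges, record_from_mol
from .trajio import ATOMIC_MASSES, Topology, Trajectory

logger = logging.getLogger("fieldsar.synthgen")

__all__ = [
    "SCAFFOLD_SMARTS", "QsarPlantSpec", "TrajPlantSpec",
    "gen_qsar_set", "gen_trajectory", "gen_complex",
]

#: common scaffold of every generated molecule: isoxazole + phenyl
SCAFFOLD_SMARTS = "c1cc(no1)-c1ccccc1"

# ------------------------------------------------------------- QSAR series

#: substituent menu for the four decorated ring positions; geometries are
#: built by :func:`_substituent_atoms`
SUBSTITUENTS = ("H", "F", "Cl", "CH3", "OH", "NH2")


@dataclass(frozen=True)
class QsarPlantSpec:
    """Study conditions for the planted QSAR set (defaults mirror a
    245-compound series with a 203/42 split and activities in 6–10)."""

    n_molecules: int = 245
    n_train: int = 203
    n_test: int = 42
    sigma: float = 0.2             # activity noise, pEC50 units
    activity_range: tuple[float, float] = (6.0, 10.0)
    n_planted_columns: int = 16
    seed: int = 1
    randomize_pose: bool = True
    grid_spacing: float = 2.0
    grid_padding: float = 4.0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("activity noise sigma must be >= 0")
        if self.n_train + self.n_test != self.n_molecules:
            raise ValueError("split sizes must sum to n_molecules")


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _ring_geometry() -> dict:
    """Fixed 3D geometry of the scaffold: isoxazole pentagon in the xy
    plane, phenyl attached at C3 and tilted 30° out of plane (so the
    molecule is genuinely 3D)."""
    pent_r = 1.17
    penta = {}
    for k, name in enumerate(["C3", "C4", "C5", "O1", "N2"]):
        ang = math.radians(72 * k)
        penta[name] = np.array([pent_r * math.cos(ang), pent_r * math.sin(ang), 0.0])
    c3 = penta["C3"]
    u = _unit(c3)                      # exocyclic direction at C3 (+x)
    ipso = c3 + 1.47 * u
    tilt = math.radians(30.0)
    e1 = u
    e2 = np.array([0.0, math.cos(tilt), math.sin(tilt)])
    center = ipso + 1.39 * e1
    hexa = []
    for k in range(6):
        ang = math.radians(180.0 + 60.0 * k)
        hexa.append(center + 1.39 * (math.cos(ang) * e1 + math.sin(ang) * e2))
    normal = _unit(np.cross(e1, e2))
    return {"penta": penta, "hexa": hexa, "hex_center": center, "normal": normal}


def _substituent_atoms(kind: str, site: np.ndarray, u: np.ndarray,
                       p1: np.ndarray) -> list[tuple[str, np.ndarray]]:
    """Atoms of one substituent: (element, position). ``u`` is the
    exocyclic unit direction at the ring carbon, ``p1`` a perpendicular."""
    p2 = _unit(np.cross(u, p1))
    if kind == "H":
        return [("H", site + 1.08 * u)]
    if kind == "F":
        return [("F", site + 1.35 * u)]
    if kind == "Cl":
        return [("Cl", site + 1.74 * u)]
    if kind == "CH3":
        c = site + 1.50 * u
        out = [("C", c)]
        for j in range(3):
            ang = math.radians(120.0 * j)
            d = (1.0 / 3.0) * u + (2.0 * math.sqrt(2.0) / 3.0) * (
                math.cos(ang) * p1 + math.sin(ang) * p2)
            out.append(("H", c + 1.09 * _unit(d)))
        return out
    if kind == "OH":
        o = site + 1.36 * u
        d = math.cos(math.radians(75.5)) * u + math.sin(math.radians(75.5)) * p1
        return [("O", o), ("H", o + 0.96 * _unit(d))]
    if kind == "NH2":
        nat = site + 1.40 * u
        out = [("N", nat)]
        for s in (+1.0, -1.0):
            d = math.cos(math.radians(60.0)) * u + s * math.sin(math.radians(60.0)) * p1
            out.append(("H", nat + 1.01 * _unit(d)))
        return out
    raise ValueError(f"unknown substituent {kind!r}")


def build_scaffold_molecule(subs: tuple[str, str, str, str]) -> Chem.Mol:
    """Construct one decorated scaffold molecule with exact coordinates.

    ``subs`` assigns the menu substituents to the phenyl ortho, meta, para
    and second-meta positions; the remaining phenyl position and the free
    isoxazole carbons carry hydrogens.
    """
    geo = _ring_geometry()
    penta, hexa = geo["penta"], geo["hexa"]
    normal = geo["normal"]
    mol = Chem.RWMol()
    pos: list[np.ndarray] = []

    def add(symbol: str, xyz: np.ndarray) -> int:
        a = Chem.Atom(symbol)
        a.SetNoImplicit(True)
        idx = mol.AddAtom(a)
        pos.append(np.asarray(xyz, dtype=float))
        return idx

    i_c3 = add("C", penta["C3"])
    i_c4 = add("C", penta["C4"])
    i_c5 = add("C", penta["C5"])
    i_o1 = add("O", penta["O1"])
    i_n2 = add("N", penta["N2"])
    mol.AddBond(i_c3, i_c4, Chem.BondType.SINGLE)
    mol.AddBond(i_c4, i_c5, Chem.BondType.DOUBLE)
    mol.AddBond(i_c5, i_o1, Chem.BondType.SINGLE)
    mol.AddBond(i_o1, i_n2, Chem.BondType.SINGLE)
    mol.AddBond(i_n2, i_c3, Chem.BondType.DOUBLE)

    hex_idx = [add("C", p) for p in hexa]
    for k in range(6):
        bt = Chem.BondType.DOUBLE if k % 2 == 0 else Chem.BondType.SINGLE
        mol.AddBond(hex_idx[k], hex_idx[(k + 1) % 6], bt)
    mol.AddBond(i_c3, hex_idx[0], Chem.BondType.SINGLE)

    # ring hydrogens on the free isoxazole carbons
    for i_ring, name in ((i_c4, "C4"), (i_c5, "C5")):
        u = _unit(penta[name])
        h = add("H", penta[name] + 1.08 * u)
        mol.AddBond(i_ring, h, Chem.BondType.SINGLE)

    # phenyl decorations: positions 1..4 get the menu substituents,
    # position 5 a hydrogen
    center = geo["hex_center"]
    for k, kind in zip((1, 2, 3, 4), subs):
        site = hexa[k]
        u = _unit(site - center)
        for el, xyz in _substituent_atoms(kind, site, u, normal):
            j = add(el, xyz)
            if el != "H" or kind == "H":
                mol.AddBond(hex_idx[k], j, Chem.BondType.SINGLE)
                anchor = j
            else:
                mol.AddBond(anchor, j, Chem.BondType.SINGLE)
    u5 = _unit(hexa[5] - center)
    h5 = add("H", hexa[5] + 1.08 * u5)
    mol.AddBond(hex_idx[5], h5, Chem.BondType.SINGLE)

    m = mol.GetMol()
    Chem.SanitizeMol(m)
    conf = Chem.Conformer(m.GetNumAtoms())
    for i, xyz in enumerate(pos):
        conf.SetAtomPosition(i, Point3D(*(round(float(c), 4) for c in xyz)))
    m.AddConformer(conf, assignId=True)
    return m


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation from a normalized quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def gen_qsar_set(spec: QsarPlantSpec = QsarPlantSpec(),
                 ) -> tuple[list[MoleculeRecord], dict]:
    """Generate the planted QSAR molecule set.

    Returns ``(records, truth)``. Records carry Gasteiger charges and a
    noisy activity; all except the template (``mol_000``, the bare
    scaffold, always first) are emitted in random rigid poses when
    ``randomize_pose`` is on. The truth dict holds the planted coefficient
    vector (over steric columns of the canonical-pose reference grid), the
    noise draws, and the exact noiseless activities.
    """
    rng = np.random.default_rng(spec.seed)
    n_sites = 4
    menu = SUBSTITUENTS
    all_combos_needed = spec.n_molecules - 1
    if all_combos_needed > len(menu) ** n_sites - 1:
        raise ValueError("substituent menu too small for the requested set size")

    combos = {("H",) * n_sites}
    while len(combos) < spec.n_molecules:
        combos.add(tuple(menu[i] for i in rng.integers(0, len(menu), size=n_sites)))
    combo_list = [("H",) * n_sites] + sorted(c for c in combos if c != ("H",) * n_sites)

    canonical: list[MoleculeRecord] = []
    for k, subs in enumerate(combo_list):
        mol = build_scaffold_molecule(subs)
        rec = record_from_mol(mol, f"mol_{k:03d}",
                              activity=1.0,  # placeholder, replaced below
                              role="train" if k else "template")
        canonical.append(assign_partial_charges(rec))

    # plant the activity through actual computed steric field columns
    grid = flds.build_grid(canonical, spec.grid_spacing, spec.grid_padding)
    fs = flds.compute_comfa_set(canonical, grid)
    S = fs.blocks["S"]
    sd = S.std(axis=0, ddof=1)
    planted_cols = np.argsort(sd)[::-1][: spec.n_planted_columns]
    planted_cols = np.sort(planted_cols)
    beta0 = rng.normal(size=spec.n_planted_columns)
    raw = S[:, planted_cols] @ beta0
    lo, hi = spec.activity_range
    span = raw.max() - raw.min()
    scale = (hi - lo) / span
    offset = lo - raw.min() * scale
    beta = beta0 * scale
    y_true = offset + S[:, planted_cols] @ beta
    noise = rng.normal(0.0, spec.sigma, size=len(canonical)) if spec.sigma > 0 \
        else np.zeros(len(canonical))
    y = y_true + noise
    assert np.all((y > 5.0) & (y < 11.0)), "planted activities left the sanity band"

    records: list[MoleculeRecord] = []
    for k, rec in enumerate(canonical):
        coords = rec.coords
        if spec.randomize_pose and k > 0:
            R = _random_rotation(rng)
            t = rng.uniform(-5.0, 5.0, size=3)
            coords = np.round(coords @ R.T + t, 4)
        rec = MoleculeRecord(
            id=rec.id, mol=rec.mol, coords=coords, elements=rec.elements,
            charges=rec.charges, rstar=rec.rstar, eps=rec.eps,
            hydrophobe=rec.hydrophobe, donor=rec.donor, acceptor=rec.acceptor,
            activity=float(y[k]), role=rec.role,
        )
        records.append(rec)

    truth = {
        "template_id": "mol_000",
        "scaffold_smarts": SCAFFOLD_SMARTS,
        "substituents": {r.id: c for r, c in zip(records, combo_list)},
        "grid": {"origin": grid.origin, "spacing": grid.spacing, "dims": grid.dims},
        "planted_field": "S",
        "planted_columns": planted_cols.tolist(),
        "beta": beta.tolist(),
        "offset": float(offset),
        "sigma": spec.sigma,
        "true_activity": {r.id: float(v) for r, v in zip(records, y_true)},
        "activity": {r.id: float(v) for r, v in zip(records, y)},
        "noise": {r.id: float(v) for r, v in zip(records, noise)},
    }
    return records, truth


# ------------------------------------------------------- trajectories

@dataclass(frozen=True)
class PlantedMode:
    """One harmonic mode: residues move along ``direction`` with the given
    per-residue signs, amplitude (Å) and period (frames)."""

    residues: tuple[int, ...]
    signs: tuple[int, ...]
    direction: tuple[float, float, float]
    amplitude: float = 1.5
    period: float = 100.0
    phase: float = 0.0


@dataclass(frozen=True)
class TrajPlantSpec:
    """Study conditions for the synthetic trajectory (test-scale defaults;
    full-scale runs use 2000 frames for a 100 ns / 50 ps-per-frame run)."""

    n_residues: int = 40
    n_frames: int = 500
    dt_ps: float = 50.0
    modes: tuple[PlantedMode, ...] | None = None
    correlated_pair: tuple[int, int] = (5, 15)
    anticorrelated_pair: tuple[int, int] = (10, 25)
    jitter: float = 0.0            # Å per axis
    include_scene: bool = True
    seed: int = 0


def _helix_backbone(n_residues: int) -> tuple[np.ndarray, Topology]:
    """Idealized α-helix-like backbone: N, CA, C, O per residue."""
    names, elements, resids, resnames, coords = [], [], [], [], []
    rise, radius, turn = 1.5, 2.3, math.radians(100.0)
    offsets = {"N": np.array([-0.8, -1.0, -0.4]),
               "CA": np.zeros(3),
               "C": np.array([0.9, 0.8, 0.5]),
               "O": np.array([1.0, 1.9, 0.6])}
    for i in range(n_residues):
        ang = turn * i
        ca = np.array([radius * math.cos(ang), radius * math.sin(ang), rise * i])
        rot = np.array([[math.cos(ang), -math.sin(ang), 0],
                        [math.sin(ang), math.cos(ang), 0], [0, 0, 1]])
        for nm in ("N", "CA", "C", "O"):
            names.append(nm)
            elements.append(nm[0])
            resids.append(i + 1)
            resnames.append("ALA")
            coords.append(ca + rot @ offsets[nm])
    top = Topology.guess(names=names, resids=resids, resnames=resnames,
                         elements=elements)
    return np.array(coords), top


def _append_scene(mean: np.ndarray, top: Topology, n_residues: int,
                  ) -> tuple[np.ndarray, Topology, dict]:
    """Static interaction scene far from the helix: a pocket pseudo-residue
    (protein side) and a LIG residue with one planted hydrogen bond, salt
    bridge and hydrophobic contact, plus negative decoys that violate one
    criterion each."""
    base = np.array([25.0, 0.0, 0.0])
    pk_resid = n_residues + 1
    lig_resid = n_residues + 2
    atoms = []   # (name, element, resid, resname, xyz, flags dict)

    def A(name, element, resid, resname, xyz, **flags):
        atoms.append((name, element, resid, resname, np.asarray(xyz, float), flags))

    u = np.array([1.0, 0.0, 0.0])
    p = np.array([0.0, 1.0, 0.0])

    # --- planted H-bond: N-H ... O, d(N..O)=2.9, angle at H = 165 deg
    nd = base
    A("ND", "N", pk_resid, "PCK", nd)
    h = nd + 1.0 * u
    A("HD", "H", pk_resid, "PCK", h, donor_h=True, heavy="ND")
    v = math.cos(math.radians(165.0)) * (-u) + math.sin(math.radians(165.0)) * p
    # place O along v from H so that |N - O| = 2.9 exactly
    b = 2.0 * float((h - nd) @ v)
    cterm = float((h - nd) @ (h - nd)) - 2.9 ** 2
    t = (-b + math.sqrt(b * b - 4 * cterm)) / 2.0
    o = h + t * v
    A("OA", "O", lig_resid, "LIG", o, acceptor=True)

    # --- decoy 1: distance fails (d = 3.6, angle 180)
    nd2 = base + np.array([0.0, 8.0, 0.0])
    A("ND2", "N", pk_resid, "PCK", nd2)
    h2 = nd2 + 1.0 * u
    A("HD2", "H", pk_resid, "PCK", h2, donor_h=True, heavy="ND2")
    A("OA2", "O", lig_resid, "LIG", nd2 + 3.6 * u, acceptor=True)

    # --- decoy 2: angle fails (d = 2.9, angle 120)
    nd3 = base + np.array([0.0, -8.0, 0.0])
    A("ND3", "N", pk_resid, "PCK", nd3)
    h3 = nd3 + 1.0 * u
    A("HD3", "H", pk_resid, "PCK", h3, donor_h=True, heavy="ND3")
    v3 = math.cos(math.radians(120.0)) * (-u) + math.sin(math.radians(120.0)) * p
    b3 = 2.0 * float((h3 - nd3) @ v3)
    c3 = float((h3 - nd3) @ (h3 - nd3)) - 2.9 ** 2
    t3 = (-b3 + math.sqrt(b3 * b3 - 4 * c3)) / 2.0
    A("OA3", "O", lig_resid, "LIG", h3 + t3 * v3, acceptor=True)

    # --- salt bridge: guanidinium-like (+) vs carboxylate-like (-), 4.0 Å
    gp = base + np.array([0.0, 0.0, 10.0])
    for k, d in enumerate([np.zeros(3), 1.3 * p, -1.3 * p]):
        A(f"NG{k}", "N" if k else "C", pk_resid, "PCK", gp + d,
          group=1, sign=+1)
    cp = gp + np.array([4.0, 0.0, 0.0])
    for k, d in enumerate([np.zeros(3), 1.25 * p, -1.25 * p]):
        A(f"OC{k}", "O" if k else "C", lig_resid, "LIG", cp + d,
          group=2, sign=-1)
    # decoy: opposite-sign pair at 7.0 Å -> no event
    gp2 = base + np.array([0.0, 10.0, 10.0])
    A("NG9", "N", pk_resid, "PCK", gp2, group=3, sign=+1)
    A("OC9", "O", lig_resid, "LIG", gp2 + np.array([7.0, 0.0, 0.0]),
      group=4, sign=-1)

    # --- hydrophobic: apolar C pair at 3.5 Å; decoy at 4.5 Å
    hp = base + np.array([0.0, 0.0, -10.0])
    A("CH1", "C", pk_resid, "PCK", hp, apolar=True)
    A("CL1", "C", lig_resid, "LIG", hp + 3.5 * u, apolar=True)
    hp2 = base + np.array([0.0, 6.0, -10.0])
    A("CH2", "C", pk_resid, "PCK", hp2, apolar=True)
    A("CL2", "C", lig_resid, "LIG", hp2 + 4.5 * u, apolar=True)

    n0 = top.n_atoms
    name_to_idx = {}
    for k, (nm, el, rid, rn, xyz, fl) in enumerate(atoms):
        name_to_idx[nm] = n0 + k

    def cat(a, vals):
        return np.concatenate([a, np.asarray(vals, dtype=a.dtype)])

    new_top = Topology(
        name=cat(top.name, [a[0] for a in atoms]),
        element=cat(top.element, [a[1] for a in atoms]),
        mass=cat(top.mass, [ATOMIC_MASSES[a[1]] for a in atoms]),
        resid=cat(top.resid, [a[2] for a in atoms]),
        resname=cat(top.resname, [a[3] for a in atoms]),
        chain=cat(top.chain, ["A"] * len(atoms)),
        charge=cat(top.charge, [0.0] * len(atoms)),
        rstar=cat(top.rstar, [1.7] * len(atoms)),
        eps=cat(top.eps, [0.107] * len(atoms)),
        is_donor_h=cat(top.is_donor_h, [bool(a[5].get("donor_h")) for a in atoms]),
        donor_heavy=cat(top.donor_heavy,
                        [name_to_idx[a[5]["heavy"]] if "heavy" in a[5] else -1
                         for a in atoms]),
        is_acceptor=cat(top.is_acceptor, [bool(a[5].get("acceptor")) for a in atoms]),
        is_apolar=cat(top.is_apolar, [bool(a[5].get("apolar")) for a in atoms]),
        charge_group=cat(top.charge_group, [a[5].get("group", -1) for a in atoms]),
        group_sign=cat(top.group_sign, [a[5].get("sign", 0) for a in atoms]),
    )
    new_mean = np.vstack([mean, np.array([a[4] for a in atoms])])
    truth = {
        "lig_resid": lig_resid,
        "pocket_resid": pk_resid,
        "hbonds": [{"donor_atom": "ND", "acceptor_atom": "OA",
                    "distance": 2.9, "angle": 165.0}],
        "salt_bridges": [{"groups": (1, 2), "distance": 4.0}],
        "hydrophobic": [{"atoms": ("CH1", "CL1"), "distance": 3.5}],
    }
    return new_mean, new_top, truth


def gen_trajectory(spec: TrajPlantSpec = TrajPlantSpec(),
                   ) -> tuple[Trajectory, dict]:
    """Synthetic trajectory with planted modes and interaction scenes.

    Coordinates are ``mean + sum_k sign * A_k sin(2π f / period + phase) *
    direction + jitter``; the correlated pair shares a mode with equal
    signs, the anticorrelated pair with opposite signs. Scene atoms are
    static. Coordinates are rounded to 1e-3 Å (PDB precision).
    """
    rng = np.random.default_rng(spec.seed)
    mean, top = _helix_backbone(spec.n_residues)
    scene_truth = {}
    if spec.include_scene:
        mean, top, scene_truth = _append_scene(mean, top, spec.n_residues)

    modes = spec.modes
    if modes is None:
        ci, cj = spec.correlated_pair
        ai, aj = spec.anticorrelated_pair
        modes = (
            PlantedMode(residues=(ci, cj), signs=(1, 1),
                        direction=(1.0, 0.0, 0.0), amplitude=1.5, period=97.0),
            PlantedMode(residues=(ai, aj), signs=(1, -1),
                        direction=(0.0, 1.0, 0.0), amplitude=1.2, period=61.0,
                        phase=0.7),
        )

    n_atoms = top.n_atoms
    n_scene = n_atoms - 4 * spec.n_residues
    coords = np.broadcast_to(mean, (spec.n_frames, n_atoms, 3)).copy()
    tgrid = np.arange(spec.n_frames)
    for mode in modes:
        d = _unit(mode.direction)
        wave = mode.amplitude * np.sin(2 * np.pi * tgrid / mode.period + mode.phase)
        for rid, sign in zip(mode.residues, mode.signs):
            idx = np.flatnonzero(top.resid == rid)
            coords[:, idx, :] += sign * wave[:, None, None] * d
    if spec.jitter > 0:
        jit = rng.normal(0.0, spec.jitter,
                         size=(spec.n_frames, 4 * spec.n_residues, 3))
        coords[:, : 4 * spec.n_residues, :] += jit
    coords = np.round(coords, 3)

    truth = {
        "modes": [
            {"residues": m.residues, "signs": m.signs,
             "direction": list(_unit(m.direction)), "amplitude": m.amplitude,
             "period": m.period} for m in modes
        ],
        "correlated_pair": spec.correlated_pair,
        "anticorrelated_pair": spec.anticorrelated_pair,
        "jitter": spec.jitter,
        "n_scene_atoms": n_scene,
        **scene_truth,
    }
    return Trajectory(coords=coords, top=top, dt_ps=spec.dt_ps), truth


# ------------------------------------------------------- energetics scenes

def _brute_force_sheet(coords: np.ndarray, top: Topology,
                       ligand_mask: np.ndarray) -> dict:
    """Reference cross energies by plain Python double loops (the oracle
    the vectorized energetics implementation is tested against)."""
    ke = 332.0636
    eps_w = 78.5
    p_idx = [i for i in range(top.n_atoms) if not ligand_mask[i]]
    l_idx = [i for i in range(top.n_atoms) if ligand_mask[i]]
    sheets = []
    for f in range(coords.shape[0]):
        e_vdw = e_ele = g_pol = 0.0
        for i in p_idx:
            for j in l_idx:
                dx = coords[f, i] - coords[f, j]
                r = math.sqrt(float(dx @ dx))
                rij = top.rstar[i] + top.rstar[j]
                eij = math.sqrt(top.eps[i] * top.eps[j])
                x = (rij / r) ** 6
                e_vdw += eij * (x * x - 2.0 * x)
                e_ele += ke * top.charge[i] * top.charge[j] / r
                rr = top.rstar[i] * top.rstar[j]
                f_gb = math.sqrt(r * r + rr * math.exp(-r * r / (4.0 * rr)))
                g_pol += -ke * (1.0 - 1.0 / eps_w) * top.charge[i] * top.charge[j] / f_gb
        sheets.append({"E_vdw": e_vdw, "E_ele": e_ele, "G_pol": g_pol,
                       "E_gas": e_vdw + e_ele})
    return {"per_frame": sheets}


def gen_complex(n_protein_atoms: int = 50, n_ligand_atoms: int = 10,
                charge_plan: str = "random", seed: int = 3,
                n_frames: int = 3) -> tuple[Trajectory, np.ndarray, dict]:
    """Protein–ligand scene with an analytic/brute-force energy sheet.

    Plans: ``random`` (clustered random atoms with Gaussian charges),
    ``lj_dimer`` (two neutral atoms at the LJ minimum distance — cross
    energy exactly -eps_ij), ``two_charges`` (+1/-1 e at 3.320636 Å with no
    LJ term — Coulomb exactly -100.0 kcal/mol).

    Returns ``(trajectory, ligand_mask, sheet)``.
    """
    rng = np.random.default_rng(seed)
    if charge_plan == "lj_dimer":
        eps = 0.2
        rstar = np.array([1.7, 1.7])
        xyz = np.array([[0.0, 0.0, 0.0], [3.4, 0.0, 0.0]])
        names = ["P1", "L1"]
        elements = ["C", "C"]
        resids = [1, 2]
        resnames = ["PRO", "LIG"]
        charges = np.zeros(2)
        epsv = np.array([eps, eps])
    elif charge_plan == "two_charges":
        rstar = np.array([1.7, 1.7])
        xyz = np.array([[0.0, 0.0, 0.0], [3.320636, 0.0, 0.0]])
        names = ["P1", "L1"]
        elements = ["N", "O"]
        resids = [1, 2]
        resnames = ["PRO", "LIG"]
        charges = np.array([1.0, -1.0])
        epsv = np.zeros(2)
    elif charge_plan == "random":
        n = n_protein_atoms + n_ligand_atoms
        prot = rng.normal(0.0, 3.0, size=(n_protein_atoms, 3))
        # ligand atoms keep a realistic contact distance from the protein
        lig_list: list[np.ndarray] = []
        while len(lig_list) < n_ligand_atoms:
            cand = np.array([8.0, 0.0, 0.0]) + rng.normal(0.0, 1.5, size=3)
            if np.min(np.linalg.norm(prot - cand, axis=1)) >= 3.0:
                lig_list.append(cand)
        lig = np.array(lig_list)
        xyz = np.vstack([prot, lig])
        charges = rng.normal(0.0, 0.2, size=n)
        charges -= charges.mean()  # keep the scene roughly neutral
        rstar = rng.uniform(1.4, 1.9, size=n)
        epsv = rng.uniform(0.05, 0.3, size=n)
        names = [f"P{i}" for i in range(n_protein_atoms)] + \
                [f"L{i}" for i in range(n_ligand_atoms)]
        elements = ["C"] * n
        resids = [1 + i // 5 for i in range(n_protein_atoms)] + \
                 [1000] * n_ligand_atoms
        resnames = ["PRO"] * n_protein_atoms + ["LIG"] * n_ligand_atoms
    else:
        raise ValueError(f"unknown charge plan {charge_plan!r}")

    top = Topology.guess(names=names, resids=resids, resnames=resnames,
                         elements=elements)
    top.charge = np.asarray(charges, dtype=float)
    top.rstar = np.asarray(rstar, dtype=float)
    top.eps = np.asarray(epsv, dtype=float)
    ligand_mask = np.array([rn == "LIG" for rn in resnames])

    frames = []
    for f in range(n_frames):
        c = xyz.copy()
        c[ligand_mask] += np.array([0.1 * f, 0.0, 0.0])  # slow drift
        frames.append(c)
    coords = np.round(np.array(frames), 6)
    traj = Trajectory(coords=coords, top=top, dt_ps=1.0)
    sheet = _brute_force_sheet(coords, top, ligand_mask)
    sheet["plan"] = charge_plan
    return traj, ligand_mask, sheet
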