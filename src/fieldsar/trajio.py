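"""Trajectory I/O and per-frame structural metrics.

A :class:`Trajectory` is a (frames, atoms, 3) coordinate array in Å plus a
:class:`Topology` table (names, elements, masses, residues, partial charges,
LJ parameters, and interaction flags). Multi-model PDB files are read and
written through MDAnalysis; a full-precision XYZ reader/writer is provided
natively so synthetic trajectories round-trip losslessly.

Metrics follow the standard MD-analysis conventions:

* RMSD: per-frame Kabsch superposition onto a reference over a selection
  (default protein backbone N, CA, C, O), then root-mean-square deviation
  over that selection.
* RMSF: frames superposed onto the time-average structure; per-atom
  ``sqrt(<|x_i - <x_i>|^2>)``, aggregated per residue as a mass-weighted
  mean.
* Rg: mass-weighted radius of gyration.
* Hydrogen bond: heavy-donor–acceptor distance < 3.5 Å AND the angle at
  the hydrogen (donor-H ... acceptor) > 135°, both strict.
* Salt bridge: oppositely charged group centroids within 5.5 Å; hydrophobic
  contact: apolar-carbon pair across the protein/ligand partition within
  4.0 Å (both cutoffs the PLIP defaults, configurable).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import kabsch, apply_rigid, rmsd

logger = logging.getLogger("fieldsar.trajio")

__all__ = [
    "ATOMIC_MASSES", "Topology", "Trajectory", "InteractionEvent",
    "read_topology", "write_topology", "read_xyz", "write_xyz",
    "read_pdb", "write_pdb", "read_trajectory",
    "superpose_kabsch", "rmsd_series", "rmsf_profile", "gyration_series",
    "detect_hbonds", "detect_contacts", "hbond_series", "events_to_dataframe",
]

ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "P": 30.974, "S": 32.06, "Cl": 35.45, "Br": 79.904, "I": 126.904,
    "Na": 22.990, "K": 39.098, "Mg": 24.305, "Ca": 40.078, "Zn": 65.38,
}

BACKBONE_NAMES = ("N", "CA", "C", "O")


@dataclass
class Topology:
    """Per-atom static properties of a trajectory."""

    name: np.ndarray
    element: np.ndarray
    mass: np.ndarray               # amu
    resid: np.ndarray              # int
    resname: np.ndarray
    chain: np.ndarray
    charge: np.ndarray             # e
    rstar: np.ndarray              # Å
    eps: np.ndarray                # kcal/mol
    is_donor_h: np.ndarray         # bool: polar hydrogen
    donor_heavy: np.ndarray        # int index of the bonded heavy atom, -1
    is_acceptor: np.ndarray        # bool
    is_apolar: np.ndarray          # bool: apolar carbon
    charge_group: np.ndarray       # int group id, -1 = none
    group_sign: np.ndarray         # int in {-1, 0, +1}

    @property
    def n_atoms(self) -> int:
        return len(self.name)

    def validate(self) -> None:
        n = self.n_atoms
        for f in ("element", "mass", "resid", "resname", "chain", "charge",
                  "rstar", "eps", "is_donor_h", "donor_heavy", "is_acceptor",
                  "is_apolar", "charge_group", "group_sign"):
            if len(getattr(self, f)) != n:
                raise ValueError(f"topology field {f} length mismatch")
        if np.any(self.mass <= 0):
            raise ValueError("topology masses must be > 0")
        bad = np.flatnonzero(self.is_donor_h & (self.donor_heavy < 0))
        if bad.size:
            raise ValueError(f"donor hydrogens without a bonded heavy atom: {bad.tolist()}")

    @classmethod
    def guess(cls, names, resids, resnames, chains=None, elements=None) -> "Topology":
        """Minimal topology from atom names alone: element from the name's
        leading letters, mass from the element table, everything else
        neutral/off. Enough for RMSD/RMSF/Rg and the essential-dynamics
        analyses; energetics and interaction detection need a full table."""
        names = np.asarray(names, dtype=object)
        n = len(names)
        if elements is None:
            elements = []
            for nm in names:
                nm = str(nm)
                el = nm[:2].capitalize() if nm[:2].capitalize() in ATOMIC_MASSES else nm[0].upper()
                elements.append(el if el in ATOMIC_MASSES else "C")
        elements = np.asarray(elements, dtype=object)
        mass = np.array([ATOMIC_MASSES.get(e, 12.011) for e in elements])
        z = np.zeros(n)
        return cls(
            name=names, element=elements, mass=mass,
            resid=np.asarray(resids, dtype=int), resname=np.asarray(resnames, dtype=object),
            chain=np.asarray(chains, dtype=object) if chains is not None
                  else np.array(["A"] * n, dtype=object),
            charge=z.copy(), rstar=np.full(n, 1.7), eps=np.full(n, 0.107),
            is_donor_h=np.zeros(n, bool), donor_heavy=np.full(n, -1, dtype=int),
            is_acceptor=np.zeros(n, bool), is_apolar=np.zeros(n, bool),
            charge_group=np.full(n, -1, dtype=int), group_sign=np.zeros(n, dtype=int),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "name": self.name, "element": self.element, "mass": self.mass,
            "resid": self.resid, "resname": self.resname, "chain": self.chain,
            "charge": self.charge, "rstar": self.rstar, "eps": self.eps,
            "is_donor_h": self.is_donor_h.astype(int),
            "donor_heavy": self.donor_heavy,
            "is_acceptor": self.is_acceptor.astype(int),
            "is_apolar": self.is_apolar.astype(int),
            "charge_group": self.charge_group, "group_sign": self.group_sign,
        })

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Topology":
        top = cls(
            name=df["name"].to_numpy(dtype=object),
            element=df["element"].to_numpy(dtype=object),
            mass=df["mass"].to_numpy(dtype=float),
            resid=df["resid"].to_numpy(dtype=int),
            resname=df["resname"].to_numpy(dtype=object),
            chain=df["chain"].to_numpy(dtype=object),
            charge=df["charge"].to_numpy(dtype=float),
            rstar=df["rstar"].to_numpy(dtype=float),
            eps=df["eps"].to_numpy(dtype=float),
            is_donor_h=df["is_donor_h"].to_numpy().astype(bool),
            donor_heavy=df["donor_heavy"].to_numpy(dtype=int),
            is_acceptor=df["is_acceptor"].to_numpy().astype(bool),
            is_apolar=df["is_apolar"].to_numpy().astype(bool),
            charge_group=df["charge_group"].to_numpy(dtype=int),
            group_sign=df["group_sign"].to_numpy(dtype=int),
        )
        top.validate()
        return top


def write_topology(top: Topology, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(top.to_dataframe().to_dict(orient="list")))
    else:
        top.to_dataframe().to_csv(path, sep="\t", index=False)


def read_topology(path: str | Path) -> Topology:
    path = Path(path)
    if path.suffix == ".json":
        df = pd.DataFrame(json.loads(path.read_text()))
    else:
        df = pd.read_csv(path, sep="\t")
    return Topology.from_dataframe(df)


@dataclass
class Trajectory:
    """Time-ordered coordinates (Å) plus topology."""

    coords: np.ndarray             # (n_frames, n_atoms, 3)
    top: Topology
    dt_ps: float = 1.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("trajectory coordinates must be (frames, atoms, 3)")
        if self.coords.shape[1] != self.top.n_atoms:
            raise ValueError("coordinate/topology atom count mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite trajectory coordinates")
        self.top.validate()

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def select_backbone(self) -> np.ndarray:
        return np.flatnonzero(np.isin(self.top.name, BACKBONE_NAMES))

    def select_ca(self) -> np.ndarray:
        return np.flatnonzero(self.top.name == "CA")

    def check_unwrapped(self, bond_limit: float = 5.0) -> bool:
        """Warn when consecutive atoms of a residue are further apart than a
        plausible bond — the signature of wrapped periodic images."""
        c0 = self.coords[0]
        same_res = self.top.resid[1:] == self.top.resid[:-1]
        d = np.linalg.norm(c0[1:] - c0[:-1], axis=1)
        if np.any(same_res & (d > bond_limit)):
            warnings.warn("trajectory looks wrapped (intra-residue distance > "
                          f"{bond_limit} Å); analyses assume whole molecules")
            return False
        return True


# ---------------------------------------------------------------- file I/O

def write_xyz(traj: Trajectory, path: str | Path, decimals: int = 9) -> None:
    """Multi-frame XYZ with full-precision coordinates."""
    lines = []
    for f in range(traj.n_frames):
        lines.append(str(traj.n_atoms))
        lines.append(f"frame {f} t= {f * traj.dt_ps:.6f} ps")
        for el, (x, y, z) in zip(traj.top.element, traj.coords[f]):
            lines.append(f"{el} {x:.{decimals}f} {y:.{decimals}f} {z:.{decimals}f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz(path: str | Path, topology: Topology | None = None,
             dt_ps: float = 1.0) -> Trajectory:
    """Read a (multi-frame) XYZ file at float64 precision."""
    lines = Path(path).read_text().splitlines()
    frames = []
    elements = None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        block = lines[i + 2: i + 2 + n]
        if len(block) < n:
            raise ValueError(f"truncated XYZ frame in {path}")
        els, xyz = [], []
        for ln in block:
            parts = ln.split()
            els.append(parts[0])
            xyz.append([float(parts[1]), float(parts[2]), float(parts[3])])
        if elements is None:
            elements = els
        frames.append(xyz)
        i += 2 + n
    coords = np.array(frames, dtype=float)
    if topology is None:
        n = coords.shape[1]
        topology = Topology.guess(names=elements, resids=np.arange(n),
                                  resnames=["UNK"] * n, elements=elements)
    return Trajectory(coords=coords, top=topology, dt_ps=dt_ps)


def write_pdb(traj: Trajectory, path: str | Path) -> None:
    """Multi-model PDB via MDAnalysis (3-decimal fixed-point coordinates)."""
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    top = traj.top
    resid = top.resid
    _, res_index = np.unique(resid, return_inverse=True)
    # preserve first-appearance residue order
    order = {}
    res_index = np.array([order.setdefault(int(r), len(order)) for r in resid])
    n_res = res_index.max() + 1
    u = mda.Universe.empty(traj.n_atoms, n_residues=n_res,
                           atom_resindex=res_index,
                           residue_segindex=np.zeros(n_res, dtype=int),
                           trajectory=True)
    u.add_TopologyAttr("names", [str(x) for x in top.name])
    u.add_TopologyAttr("elements", [str(x) for x in top.element])
    first = [np.flatnonzero(res_index == k)[0] for k in range(n_res)]
    u.add_TopologyAttr("resids", [int(resid[i]) for i in first])
    u.add_TopologyAttr("resnames", [str(top.resname[i]) for i in first])
    u.load_new(traj.coords.astype(np.float32), format=MemoryReader,
               dt=traj.dt_ps)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), multiframe=True) as w:
            for _ in u.trajectory:
                w.write(u.atoms)


def read_pdb(path: str | Path, topology: Topology | None = None,
             dt_ps: float = 1.0) -> Trajectory:
    """Read a multi-model PDB via MDAnalysis. Without an explicit topology
    table, a minimal one is guessed from the atom records."""
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        coords = np.array([u.atoms.positions.copy() for _ in u.trajectory],
                          dtype=float)
        if topology is None:
            elements = None
            if hasattr(u.atoms, "elements"):
                elements = [str(e).capitalize() for e in u.atoms.elements]
            topology = Topology.guess(
                names=[str(n) for n in u.atoms.names],
                resids=u.atoms.resids, resnames=[str(r) for r in u.atoms.resnames],
                elements=elements,
            )
    return Trajectory(coords=coords, top=topology, dt_ps=dt_ps)


def read_trajectory(path: str | Path, topology: Topology | None = None,
                    dt_ps: float = 1.0) -> Trajectory:
    """Dispatch on extension: ``.xyz`` native reader, ``.pdb`` MDAnalysis."""
    suffix = Path(path).suffix.lower()
    if suffix == ".xyz":
        return read_xyz(path, topology, dt_ps)
    return read_pdb(path, topology, dt_ps)


# ---------------------------------------------------------------- metrics

def superpose_kabsch(mobile: np.ndarray, reference: np.ndarray,
                     selection: np.ndarray | None = None,
                     ) -> tuple[tuple[np.ndarray, np.ndarray], float]:
    """Optimal rigid superposition of one frame onto another over a
    selection. Returns ``((R, t), rmsd)``; the rotation is proper."""
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    sel = np.arange(mobile.shape[0]) if selection is None else np.asarray(selection)
    R, t, r = kabsch(mobile[sel], reference[sel])
    return (R, t), r


def rmsd_series(traj: Trajectory, reference: int | np.ndarray = 0,
                selection: np.ndarray | None = None,
                units: str = "A", superpose: bool = True) -> np.ndarray:
    """Per-frame RMSD to a reference after superposition on the selection
    (default: backbone atoms). ``units="nm"`` divides by 10;
    ``superpose=False`` gives the raw coordinate RMSD."""
    ref = traj.coords[reference] if isinstance(reference, (int, np.integer)) else np.asarray(reference)
    sel = traj.select_backbone() if selection is None else np.asarray(selection)
    if sel.size == 0:
        raise ValueError("empty RMSD selection")
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        if superpose:
            _, out[f] = superpose_kabsch(traj.coords[f], ref, sel)
        else:
            out[f] = rmsd(traj.coords[f][sel], ref[sel])
    if units == "nm":
        out = out / 10.0
    return out


def _superpose_to_mean(coords: np.ndarray, sel: np.ndarray,
                       n_iter: int = 2) -> np.ndarray:
    """Superpose every frame onto the running time-average structure
    (iterated, which converges in a couple of passes)."""
    fitted = coords.copy()
    for _ in range(n_iter):
        mean = fitted.mean(axis=0)
        for f in range(fitted.shape[0]):
            R, t, _ = kabsch(fitted[f][sel], mean[sel])
            fitted[f] = apply_rigid(fitted[f], R, t)
    return fitted


def rmsf_profile(traj: Trajectory, selection: np.ndarray | None = None,
                 grouping: str = "residue") -> pd.DataFrame:
    """Per-residue RMSF (Å): frames are superposed onto the time-average
    structure, per-atom fluctuations are computed, and residues aggregate
    their selected atoms by a mass-weighted mean.

    ``grouping="atom"`` returns the per-atom profile instead.
    """
    sel = traj.select_backbone() if selection is None else np.asarray(selection)
    if sel.size == 0:
        raise ValueError("empty RMSF selection")
    fitted = _superpose_to_mean(traj.coords, sel)
    mean = fitted.mean(axis=0)
    fluct2 = ((fitted - mean) ** 2).sum(axis=2).mean(axis=0)  # per atom
    rmsf_atom = np.sqrt(fluct2)
    if grouping == "atom":
        return pd.DataFrame({"atom": sel, "rmsf": rmsf_atom[sel]})
    resids = traj.top.resid[sel]
    masses = traj.top.mass[sel]
    vals = rmsf_atom[sel]
    rows = []
    for rid in pd.unique(resids):
        m = resids == rid
        rows.append({"resid": int(rid),
                     "rmsf": float(np.average(vals[m], weights=masses[m]))})
    return pd.DataFrame(rows)


def gyration_series(traj: Trajectory, selection: np.ndarray | None = None,
                    units: str = "A") -> np.ndarray:
    """Per-frame mass-weighted radius of gyration."""
    sel = np.arange(traj.n_atoms) if selection is None else np.asarray(selection)
    m = traj.top.mass[sel]
    c = traj.coords[:, sel, :]
    com = np.einsum("fak,a->fk", c, m) / m.sum()
    d2 = ((c - com[:, None, :]) ** 2).sum(axis=2)
    rg = np.sqrt(np.einsum("fa,a->f", d2, m) / m.sum())
    return rg / 10.0 if units == "nm" else rg


# ----------------------------------------------------- interaction events

@dataclass(frozen=True)
class InteractionEvent:
    """One detected protein–ligand (or intramolecular) interaction."""

    frame: int
    kind: str                      # hbond | salt_bridge | hydrophobic
    donor: tuple | None            # (resid, resname, atom name)
    acceptor: tuple | None
    distance: float                # Å (heavy-donor..acceptor or pair/centroid)
    angle: float = float("nan")    # degrees at the hydrogen, hbond only


def _atom_tag(top: Topology, i: int) -> tuple:
    return (int(top.resid[i]), str(top.resname[i]), str(top.name[i]))


def detect_hbonds(frame_coords: np.ndarray, top: Topology,
                  d_max: float = 3.5, angle_min: float = 135.0,
                  frame: int = 0) -> list[InteractionEvent]:
    """Geometric hydrogen bonds: heavy-donor–acceptor distance < ``d_max``
    AND donor-H...acceptor angle at the hydrogen > ``angle_min``; both
    criteria strict, ties at the cutoff are non-events."""
    c = np.asarray(frame_coords, dtype=float)
    donors_h = np.flatnonzero(top.is_donor_h)
    acceptors = np.flatnonzero(top.is_acceptor)
    events = []
    for h in donors_h:
        heavy = int(top.donor_heavy[h])
        if heavy < 0:
            raise ValueError(f"donor hydrogen {h} has no bonded heavy atom")
        for a in acceptors:
            if a == heavy:
                continue
            d = float(np.linalg.norm(c[heavy] - c[a]))
            if not d < d_max:
                continue
            v1 = c[heavy] - c[h]
            v2 = c[a] - c[h]
            cosang = float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
            ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if ang > angle_min:
                events.append(InteractionEvent(
                    frame=frame, kind="hbond",
                    donor=_atom_tag(top, heavy), acceptor=_atom_tag(top, a),
                    distance=d, angle=ang))
    return events


def detect_contacts(frame_coords: np.ndarray, top: Topology,
                    ligand_mask: np.ndarray,
                    hydrophobic_cutoff: float = 4.0,
                    saltbridge_cutoff: float = 5.5,
                    frame: int = 0) -> list[InteractionEvent]:
    """Hydrophobic contacts and salt bridges across the protein/ligand
    partition. Hydrophobic: apolar-carbon pairs within the cutoff; salt
    bridge: oppositely signed charged-group centroids within the cutoff."""
    c = np.asarray(frame_coords, dtype=float)
    lig = np.asarray(ligand_mask, dtype=bool)
    events = []

    apolar_l = np.flatnonzero(top.is_apolar & lig)
    apolar_p = np.flatnonzero(top.is_apolar & ~lig)
    if apolar_l.size and apolar_p.size:
        d = np.linalg.norm(c[apolar_l][:, None, :] - c[apolar_p][None, :, :], axis=2)
        for il, ip in zip(*np.nonzero(d < hydrophobic_cutoff)):
            events.append(InteractionEvent(
                frame=frame, kind="hydrophobic",
                donor=_atom_tag(top, apolar_l[il]),
                acceptor=_atom_tag(top, apolar_p[ip]),
                distance=float(d[il, ip])))

    groups = {}
    for gid in np.unique(top.charge_group):
        if gid < 0:
            continue
        m = top.charge_group == gid
        groups[int(gid)] = {
            "centroid": c[m].mean(axis=0),
            "sign": int(np.sign(top.group_sign[m].sum())),
            "ligand": bool(lig[m].any()),
            "first": int(np.flatnonzero(m)[0]),
        }
    gids = sorted(groups)
    for i, gi in enumerate(gids):
        for gj in gids[i + 1:]:
            a, b = groups[gi], groups[gj]
            if a["ligand"] == b["ligand"]:
                continue
            if a["sign"] * b["sign"] >= 0:
                continue
            d = float(np.linalg.norm(a["centroid"] - b["centroid"]))
            if d < saltbridge_cutoff:
                la, pa = (a, b) if a["ligand"] else (b, a)
                events.append(InteractionEvent(
                    frame=frame, kind="salt_bridge",
                    donor=_atom_tag(top, la["first"]),
                    acceptor=_atom_tag(top, pa["first"]),
                    distance=d))
    return events


def hbond_series(traj: Trajectory, d_max: float = 3.5,
                 angle_min: float = 135.0) -> list[InteractionEvent]:
    """Hydrogen-bond events over every frame of a trajectory."""
    events = []
    for f in range(traj.n_frames):
        events.extend(detect_hbonds(traj.coords[f], traj.top, d_max, angle_min, frame=f))
    return events


def events_to_dataframe(events: list[InteractionEvent]) -> pd.DataFrame:
    rows = []
    for e in events:
        rows.append({
            "frame": e.frame, "kind": e.kind,
            "donor_resid": e.donor[0] if e.donor else None,
            "donor_resname": e.donor[1] if e.donor else None,
            "donor_atom": e.donor[2] if e.donor else None,
            "acceptor_resid": e.acceptor[0] if e.acceptor else None,
            "acceptor_resname": e.acceptor[1] if e.acceptor else None,
            "acceptor_atom": e.acceptor[2] if e.acceptor else None,
            "distance": e.distance, "angle": e.angle,
        })
    return pd.DataFrame(rows)
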