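"""Molecule-set I/O, partial charges, scaffold alignment, and train/test
splitting for the grid-field QSAR pipeline.

The observation unit is a :class:`MoleculeRecord`: one aligned 3D molecule
carrying per-atom parameters (partial charge, van der Waals radius and LJ
well depth, and the similarity-field property flags) together with its
activity label, a pEC50 = -log10(EC50 / M).

RDKit does the heavy lifting for file formats, substructure matching and
Gasteiger charges; the rigid scaffold superposition is the Kabsch fit from
:mod:`fieldsar.geometry`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Geometry import Point3D

from .geometry import kabsch, apply_rigid

logger = logging.getLogger("fieldsar.chemio")

__all__ = [
    "VDW_PARAMS",
    "MoleculeRecord",
    "SplitSpec",
    "read_molecule_set",
    "read_activity_table",
    "record_from_mol",
    "assign_partial_charges",
    "align_to_template",
    "split_train_test",
    "write_molecule_set",
]

# Element -> (R* in Å, epsilon in kcal/mol). Tripos-style 12-6 parameters;
# R* is the single-atom minimum-distance radius, combined additively with the
# probe's R*. Elements outside this table fall back to the carbon entry with
# a logged warning.
VDW_PARAMS: dict[str, tuple[float, float]] = {
    "H": (1.50, 0.042),
    "C": (1.70, 0.107),
    "N": (1.55, 0.095),
    "O": (1.52, 0.116),
    "F": (1.47, 0.109),
    "P": (1.80, 0.314),
    "S": (1.80, 0.314),
    "Cl": (1.75, 0.314),
    "Br": (1.85, 0.434),
    "I": (1.98, 0.623),
}

_HALOGENS = {"F", "Cl", "Br", "I"}


@dataclass
class MoleculeRecord:
    """One 3D molecule with per-atom parameters and an activity label."""

    id: str
    mol: Chem.Mol
    coords: np.ndarray                 # (n_atoms, 3) Å
    elements: np.ndarray               # (n_atoms,) str
    charges: np.ndarray | None = None  # (n_atoms,) e, set by assign_partial_charges
    rstar: np.ndarray = None           # (n_atoms,) Å
    eps: np.ndarray = None             # (n_atoms,) kcal/mol
    hydrophobe: np.ndarray = None      # (n_atoms,) float in {-1, 0, +1}
    donor: np.ndarray = None           # (n_atoms,) bool  (H on N/O)
    acceptor: np.ndarray = None        # (n_atoms,) bool  (N/O, no + charge)
    activity: float | None = None      # pEC50
    role: str = "query"                # train | test | template | query
    scaffold_match: list[int] = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        return int(self.coords.shape[0])

    def validate(self) -> None:
        if self.n_atoms < 1:
            raise ValueError(f"molecule {self.id}: no atoms")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"molecule {self.id}: non-finite coordinates")
        if self.charges is not None and not np.all(np.isfinite(self.charges)):
            raise ValueError(f"molecule {self.id}: non-finite charges")
        if np.any(self.rstar <= 0):
            raise ValueError(f"molecule {self.id}: non-positive vdW radius")
        if self.role in ("train", "test", "template"):
            if self.activity is None:
                raise ValueError(f"molecule {self.id}: {self.role} role needs a pEC50")
            if not (0.0 < self.activity < 15.0):
                raise ValueError(
                    f"molecule {self.id}: pEC50 {self.activity} outside sanity bound (0, 15)"
                )


@dataclass(frozen=True)
class SplitSpec:
    """Random train/test partition; the alignment template always trains."""

    n_total: int
    n_train: int
    n_test: int
    seed: int
    template_id: str

    def __post_init__(self):
        if self.n_train + self.n_test != self.n_total:
            raise ValueError(
                f"split counts inconsistent: {self.n_train}+{self.n_test} != {self.n_total}"
            )


def _vdw_arrays(elements: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    rstar = np.empty(len(elements))
    eps = np.empty(len(elements))
    for i, el in enumerate(elements):
        if el not in VDW_PARAMS:
            logger.warning("element %s not in vdW table; using carbon parameters", el)
        rstar[i], eps[i] = VDW_PARAMS.get(el, VDW_PARAMS["C"])
    return rstar, eps


def _comsia_flags(mol: Chem.Mol) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Similarity-field atom properties from simple connectivity rules.

    hydrophobe: +1 for carbons/halogens with no N/O neighbour, -1 for polar
    atoms (N, O, S, P, and H bonded to N/O), 0 otherwise.
    donor: hydrogens bonded to N or O.
    acceptor: N or O without positive formal charge and with a lone pair
    (tetra-coordinated nitrogen excluded).
    """
    n = mol.GetNumAtoms()
    hydro = np.zeros(n)
    don = np.zeros(n, dtype=bool)
    acc = np.zeros(n, dtype=bool)
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        sym = atom.GetSymbol()
        nbr_syms = {nb.GetSymbol() for nb in atom.GetNeighbors()}
        polar_nbr = bool(nbr_syms & {"N", "O"})
        if sym == "H":
            if polar_nbr:
                hydro[i] = -1.0
                don[i] = True
        elif sym == "C" or sym in _HALOGENS:
            hydro[i] = 0.0 if polar_nbr else 1.0
        elif sym in ("N", "O", "S", "P"):
            hydro[i] = -1.0
            if sym in ("N", "O") and atom.GetFormalCharge() <= 0:
                if sym == "O" or atom.GetTotalDegree() < 4:
                    acc[i] = True
    return hydro, don, acc


def record_from_mol(mol: Chem.Mol, mol_id: str, activity: float | None = None,
                    role: str = "query") -> MoleculeRecord:
    """Build a :class:`MoleculeRecord` from an RDKit molecule with a 3D
    conformer. Rejects flat (all z == 0) geometries: grid fields are
    meaningless without 3D structure."""
    if mol.GetNumConformers() == 0:
        raise ValueError(f"molecule {mol_id}: no 3D coordinates")
    conf = mol.GetConformer()
    coords = np.array(conf.GetPositions(), dtype=float)
    if np.allclose(coords[:, 2], 0.0, atol=1e-12):
        raise ValueError(f"molecule {mol_id}: 2D coordinates (all z = 0)")
    elements = np.array([a.GetSymbol() for a in mol.GetAtoms()])
    rstar, eps = _vdw_arrays(elements)
    hydro, don, acc = _comsia_flags(mol)
    rec = MoleculeRecord(
        id=mol_id, mol=mol, coords=coords, elements=elements,
        rstar=rstar, eps=eps, hydrophobe=hydro, donor=don, acceptor=acc,
        activity=activity, role=role,
    )
    rec.validate()
    return rec


def read_activity_table(path: str | Path) -> pd.DataFrame:
    """CSV with columns ``id, pEC50[, role]``."""
    df = pd.read_csv(path, dtype={"id": str})
    if "id" not in df.columns or "pEC50" not in df.columns:
        raise ValueError("activity table needs columns 'id' and 'pEC50'")
    if "role" not in df.columns:
        df["role"] = "train"
    return df


def _iter_mol2_blocks(text: str):
    marker = "@<TRIPOS>MOLECULE"
    parts = text.split(marker)
    for part in parts[1:]:
        yield marker + part


def read_molecule_set(path: str | Path,
                      activity_table: pd.DataFrame | dict | None = None,
                      ) -> list[MoleculeRecord]:
    """Read an SDF (V2000) or MOL2 molecule set into records.

    Every molecule whose id appears in the activity table gets that pEC50 and
    role; ids absent from the table become ``query`` records. A train/test
    role without an activity is a hard error (raised by validation).
    """
    path = Path(path)
    act: dict[str, tuple[float, str]] = {}
    if isinstance(activity_table, pd.DataFrame):
        for _, row in activity_table.iterrows():
            act[str(row["id"])] = (float(row["pEC50"]), str(row.get("role", "train")))
    elif isinstance(activity_table, dict):
        act = {str(k): (float(v), "train") for k, v in activity_table.items()}

    mols: list[tuple[str, Chem.Mol]] = []
    if path.suffix.lower() == ".mol2":
        for block in _iter_mol2_blocks(path.read_text()):
            mol = Chem.MolFromMol2Block(block, removeHs=False)
            if mol is None:
                raise ValueError(f"unparseable MOL2 block in {path}")
            mols.append((mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{len(mols)}", mol))
    else:
        supplier = Chem.SDMolSupplier(str(path), removeHs=False)
        for k, mol in enumerate(supplier):
            if mol is None:
                raise ValueError(f"unparseable molecule #{k} in {path}")
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{k}"
            mols.append((name, mol))

    records = []
    for name, mol in mols:
        if name in act:
            activity, role = act[name]
        else:
            activity, role = None, "query"
        records.append(record_from_mol(mol, name, activity=activity, role=role))
    return records


def write_molecule_set(records: list[MoleculeRecord], path: str | Path) -> None:
    """Write records as an SDF (V2000), carrying pEC50/role as properties."""
    writer = Chem.SDWriter(str(path))
    writer.SetForceV3000(False)
    for rec in records:
        mol = Chem.Mol(rec.mol)
        conf = mol.GetConformer()
        for i, (x, y, z) in enumerate(rec.coords):
            conf.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))
        mol.SetProp("_Name", rec.id)
        if rec.activity is not None:
            mol.SetProp("pEC50", f"{rec.activity:.6f}")
        mol.SetProp("role", rec.role)
        writer.write(mol)
    writer.close()


def assign_partial_charges(record: MoleculeRecord, n_iter: int = 6) -> MoleculeRecord:
    """Iterative Gasteiger partial charges (PEOE), 6 damped iterations.

    The per-iteration damping factor of 1/2 is intrinsic to the scheme; the
    charges conserve the molecule's total formal charge.
    """
    mol = Chem.Mol(record.mol)
    try:
        AllChem.ComputeGasteigerCharges(mol, nIter=n_iter, throwOnParamFailure=True)
    except Exception as exc:  # pragma: no cover - parameterization failures
        raise ValueError(f"molecule {record.id}: Gasteiger parameters missing ({exc})")
    q = np.array([float(a.GetProp("_GasteigerCharge")) for a in mol.GetAtoms()])
    if not np.all(np.isfinite(q)):
        bad = [a.GetIdx() for a in mol.GetAtoms()
               if not np.isfinite(float(a.GetProp("_GasteigerCharge")))]
        raise ValueError(f"molecule {record.id}: unresolvable valence at atoms {bad}")
    formal = float(sum(a.GetFormalCharge() for a in mol.GetAtoms()))
    if abs(q.sum() - formal) > 1e-6:
        raise ValueError(
            f"molecule {record.id}: Gasteiger charges sum {q.sum():.8f} != formal {formal}"
        )
    return replace(record, mol=mol, charges=q)


def _template_scaffold(template: MoleculeRecord, query: Chem.Mol) -> list[int]:
    matches = template.mol.GetSubstructMatches(query, uniquify=False, maxMatches=512)
    if not matches:
        raise ValueError(f"template {template.id} does not match the scaffold query")
    return list(min(matches))


def align_to_template(records: list[MoleculeRecord], template: MoleculeRecord,
                      scaffold_query: str | Chem.Mol,
                      ) -> tuple[list[MoleculeRecord], pd.DataFrame]:
    """Rigidly superpose each record's scaffold match onto the template's.

    Among multiple substructure matches the one with the lowest post-fit
    scaffold RMSD wins; exact ties break on the lexicographically smallest
    atom-index tuple. Records without a match are excluded (logged, and
    flagged in the returned report).

    Returns (aligned records, report) where the report has one row per input
    record: id, scaffold_rmsd (Å, NaN when excluded), excluded flag.
    """
    if isinstance(scaffold_query, str):
        query = Chem.MolFromSmarts(scaffold_query)
        if query is None:
            raise ValueError(f"invalid scaffold SMARTS: {scaffold_query}")
    else:
        query = scaffold_query

    t_idx = _template_scaffold(template, query)
    t_coords = template.coords[t_idx]

    aligned: list[MoleculeRecord] = []
    rows = []
    for rec in records:
        matches = rec.mol.GetSubstructMatches(query, uniquify=False, maxMatches=512)
        if not matches:
            logger.warning("molecule %s: no scaffold match; excluded from alignment", rec.id)
            rows.append({"id": rec.id, "scaffold_rmsd": np.nan, "excluded": True})
            continue
        best = None
        for match in sorted(matches):
            R, t, r = kabsch(rec.coords[list(match)], t_coords)
            if best is None or r < best[0] - 1e-12:
                best = (r, match, R, t)
        r, match, R, t = best
        new_coords = apply_rigid(rec.coords, R, t)
        new_rec = replace(rec, coords=new_coords, scaffold_match=list(match))
        aligned.append(new_rec)
        rows.append({"id": rec.id, "scaffold_rmsd": r, "excluded": False})
    report = pd.DataFrame(rows, columns=["id", "scaffold_rmsd", "excluded"])
    return aligned, report


def split_train_test(records: list[MoleculeRecord], spec: SplitSpec,
                     ) -> tuple[list[MoleculeRecord], list[MoleculeRecord]]:
    """Seeded random partition into train/test; the template molecule is
    always assigned to the training set (and keeps its ``template`` role)."""
    if len(records) != spec.n_total:
        raise ValueError(f"got {len(records)} records, spec says {spec.n_total}")
    ids = [r.id for r in records]
    if spec.template_id not in ids:
        raise ValueError(f"template id {spec.template_id} not among records")
    rng = np.random.default_rng(spec.seed)
    others = [r for r in records if r.id != spec.template_id]
    order = rng.permutation(len(others))
    template = next(r for r in records if r.id == spec.template_id)
    template = replace(template, role="template")
    n_more_train = spec.n_train - 1
    train = [template] + [replace(others[i], role="train") for i in order[:n_more_train]]
    test = [replace(others[i], role="test") for i in order[n_more_train:]]
    assert len(train) == spec.n_train and len(test) == spec.n_test
    return train, test
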