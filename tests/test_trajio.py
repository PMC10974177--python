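"""Trajectory I/O, RMSD/RMSF/Rg, and geometric interaction detection."""

import numpy as np
import pytest

from fieldsar import synthgen, trajio
from fieldsar.trajio import (Topology, Trajectory, detect_contacts,
                             detect_hbonds, gyration_series, read_pdb,
                             read_topology, read_xyz, rmsd_series,
                             rmsf_profile, superpose_kabsch, write_pdb,
                             write_topology, write_xyz)


def _simple_traj(coords, names=None, resids=None, masses=None, dt=1.0):
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[1]
    names = names or ["CA"] * n
    resids = resids if resids is not None else np.arange(1, n + 1)
    top = Topology.guess(names=names, resids=resids, resnames=["ALA"] * n,
                         elements=["C"] * n)
    if masses is not None:
        top.mass = np.asarray(masses, dtype=float)
    return Trajectory(coords=coords, top=top, dt_ps=dt)


# ----------------------------------------------------------------- I/O

def test_xyz_round_trip_lossless(planted_traj):
    traj, _ = planted_traj
    import tempfile, pathlib
    with tempfile.TemporaryDirectory() as d:
        p = pathlib.Path(d) / "t.xyz"
        write_xyz(traj, p)
        back = read_xyz(p, topology=traj.top, dt_ps=traj.dt_ps)
        assert np.abs(back.coords - traj.coords).max() < 1e-9


def test_pdb_round_trip_at_format_precision(tmp_path, planted_traj):
    traj, _ = planted_traj
    sub = Trajectory(coords=traj.coords[:5], top=traj.top, dt_ps=traj.dt_ps)
    p = tmp_path / "t.pdb"
    write_pdb(sub, p)
    back = read_pdb(p)
    assert back.n_frames == 5
    assert np.abs(back.coords - sub.coords).max() < 1.5e-3
    assert list(back.top.resid) == list(sub.top.resid)


def test_topology_round_trip(tmp_path, planted_traj):
    traj, _ = planted_traj
    for name in ("top.json", "top.tsv"):
        p = tmp_path / name
        write_topology(traj.top, p)
        back = read_topology(p)
        assert np.array_equal(back.is_donor_h, traj.top.is_donor_h)
        assert np.array_equal(back.donor_heavy, traj.top.donor_heavy)
        assert np.allclose(back.mass, traj.top.mass)


def test_wrapped_trajectory_warns():
    coords = np.zeros((1, 2, 3))
    coords[0, 1] = [9.0, 0.0, 0.0]
    t = _simple_traj(coords, resids=[1, 1])
    with pytest.warns(UserWarning, match="wrapped"):
        t.check_unwrapped()


# ----------------------------------------------------------- RMSD family

def test_superpose_examples():
    ref = np.random.default_rng(0).normal(size=(6, 3))
    (_, _), r = superpose_kabsch(ref, ref)
    assert r < 1e-12
    (_, _), r = superpose_kabsch(ref + np.array([5.0, 0, 0]), ref)
    assert r < 1e-12
    ref2 = np.array([[0.0, 0, 0], [2.0, 0, 0]])
    mob2 = np.array([[0.0, 0, 0], [1.0, 0, 0]])
    (_, _), r = superpose_kabsch(mob2, ref2)
    assert r == pytest.approx(0.5, abs=1e-12)


def test_static_trajectory_zero_rmsd():
    coords = np.repeat(np.random.default_rng(1).normal(size=(1, 5, 3)), 4, axis=0)
    t = _simple_traj(coords)
    assert rmsd_series(t, selection=np.arange(5)).max() < 1e-9


def test_planted_displacement_closed_form():
    # one atom of n displaced by d -> raw RMSD d / sqrt(n)
    n, d = 16, 0.8
    base = np.random.default_rng(2).normal(size=(n, 3))
    moved = base.copy()
    moved[3, 0] += d
    t = _simple_traj(np.stack([base, moved]))
    series = rmsd_series(t, selection=np.arange(n), superpose=False)
    assert series[1] == pytest.approx(d / np.sqrt(n), abs=1e-12)


def test_rigid_motion_invariance_and_units():
    rng = np.random.default_rng(3)
    base = rng.normal(size=(8, 3))
    th = 0.4
    R = np.array([[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0],
                  [0, 0, 1.0]])
    t = _simple_traj(np.stack([base, base @ R.T + 2.0]))
    series = rmsd_series(t, selection=np.arange(8))
    assert series[1] < 1e-9
    # unit conversion: values in nm are Å / 10
    a = rmsd_series(t, selection=np.arange(8), superpose=False)
    nm = rmsd_series(t, selection=np.arange(8), superpose=False, units="nm")
    assert np.allclose(nm, a / 10.0)


def test_rmsf_static_zero_and_rigid_rotation_removed():
    rng = np.random.default_rng(4)
    base = rng.normal(size=(10, 3)) * 3
    frames = [base]
    for k in range(1, 6):
        th = 0.1 * k
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        frames.append(base @ R.T + k * 0.5)
    t = _simple_traj(np.array(frames))
    prof = rmsf_profile(t, selection=np.arange(10))
    assert prof.rmsf.max() < 1e-9


def test_rmsf_planted_jitter_closed_form():
    """Isotropic Gaussian jitter σ per axis on one residue out of many:
    RMSF ≈ σ√3 within 5% at 2000 frames."""
    rng = np.random.default_rng(5)
    spec = synthgen.TrajPlantSpec(n_residues=20, n_frames=1, jitter=0.0,
                                  include_scene=False)
    base, _ = synthgen.gen_trajectory(spec)
    mean = base.coords[0]
    sigma = 0.3
    n_frames = 2000
    coords = np.repeat(mean[None], n_frames, axis=0)
    target = np.flatnonzero(base.top.resid == 10)
    coords[:, target, :] += rng.normal(0.0, sigma, size=(n_frames, len(target), 3))
    t = Trajectory(coords=coords, top=base.top, dt_ps=1.0)
    prof = rmsf_profile(t)
    got = float(prof[prof.resid == 10].rmsf.iloc[0])
    assert got == pytest.approx(sigma * np.sqrt(3), rel=0.05)
    assert prof[prof.resid != 10].rmsf.max() < 0.1


def test_rmsf_equals_per_atom_rmsd_to_mean(planted_traj):
    traj, _ = planted_traj
    sel = traj.select_backbone()
    prof_atom = rmsf_profile(traj, selection=sel, grouping="atom")
    from fieldsar.trajio import _superpose_to_mean
    fitted = _superpose_to_mean(traj.coords, sel)
    mean = fitted.mean(axis=0)
    per_atom = np.sqrt(((fitted - mean) ** 2).sum(axis=2).mean(axis=0))
    assert np.abs(prof_atom.rmsf.to_numpy() - per_atom[sel]).max() < 1e-9


# -------------------------------------------------------------------- Rg

def test_gyration_closed_form_pair():
    coords = np.array([[[1.0, 0, 0], [-1.0, 0, 0]]])
    t = _simple_traj(coords, masses=[1.0, 1.0])
    assert gyration_series(t)[0] == pytest.approx(1.0, abs=1e-12)
    t2 = _simple_traj(coords * 2.0, masses=[1.0, 1.0])
    assert gyration_series(t2)[0] == pytest.approx(2.0, abs=1e-12)


def test_gyration_stable_band(planted_traj):
    traj, _ = planted_traj
    helix = np.flatnonzero(traj.top.resname == "ALA")
    rg = gyration_series(traj, selection=helix)
    assert rg.std() < 0.2 * rg.mean()


# ------------------------------------------------------------- detectors

def _hbond_scene(d, angle_deg):
    """Donor N at origin, H along +x, acceptor placed for given
    heavy-donor..acceptor distance and angle at H."""
    names = ["ND", "HD", "OA"]
    top = Topology.guess(names=names, resids=[1, 1, 2],
                         resnames=["PCK", "PCK", "LIG"],
                         elements=["N", "H", "O"])
    top.is_donor_h[1] = True
    top.donor_heavy[1] = 0
    top.is_acceptor[2] = True
    u = np.array([1.0, 0.0, 0.0])
    p = np.array([0.0, 1.0, 0.0])
    h = u * 1.0
    ang = np.radians(angle_deg)
    v = np.cos(ang) * (-u) + np.sin(ang) * p
    b = 2.0 * float((h - 0) @ v)
    c = float(h @ h) - d ** 2
    t = (-b + np.sqrt(b * b - 4 * c)) / 2.0
    o = h + t * v
    coords = np.array([[0.0, 0, 0], h, o])
    return coords, top


@pytest.mark.parametrize("d,angle,expected", [
    (2.9, 165.0, 1),   # inside both criteria
    (3.6, 179.0, 0),   # distance fails
    (2.9, 120.0, 0),   # angle fails
    (3.5, 165.0, 0),   # tie at the distance cutoff is a non-event
])
def test_hbond_criteria(d, angle, expected):
    coords, top = _hbond_scene(d, angle)
    events = detect_hbonds(coords, top)
    assert len(events) == expected
    if expected:
        assert events[0].distance == pytest.approx(d, abs=1e-9)
        assert events[0].angle == pytest.approx(angle, abs=1e-6)


def test_contact_cutoffs():
    names = ["CP", "CL", "NG", "OC"]
    top = Topology.guess(names=names, resids=[1, 2, 1, 2],
                         resnames=["PRO", "LIG", "PRO", "LIG"],
                         elements=["C", "C", "N", "O"])
    top.is_apolar[:2] = True
    top.charge_group[:] = [-1, -1, 1, 2]
    top.group_sign[:] = [0, 0, +1, -1]
    lig = np.array([False, True, False, True])
    coords = np.array([[0.0, 0, 0], [4.5, 0, 0],
                       [0.0, 10, 0], [4.0, 10, 0]])
    events = detect_contacts(coords, top, lig)
    kinds = sorted(e.kind for e in events)
    assert kinds == ["salt_bridge"]          # hydrophobic pair at 4.5 > 4.0
    coords[1, 0] = 3.9
    events = detect_contacts(coords, top, lig)
    assert sorted(e.kind for e in events) == ["hydrophobic", "salt_bridge"]


def test_planted_scene_detected_exactly(planted_traj):
    """The generator's scene yields exactly the planted positives, matched
    by a brute-force all-pairs scan."""
    traj, truth = planted_traj
    top = traj.top
    frame = traj.coords[0]
    events = detect_hbonds(frame, top)
    assert len(events) == len(truth["hbonds"]) == 1
    ev = events[0]
    assert ev.donor[2] == "ND" and ev.acceptor[2] == "OA"
    assert ev.distance == pytest.approx(2.9, abs=2e-3)
    assert ev.angle == pytest.approx(165.0, abs=0.5)

    lig = top.resname == "LIG"
    contacts = detect_contacts(frame, top, lig)
    by_kind = {}
    for e in contacts:
        by_kind.setdefault(e.kind, []).append(e)
    assert len(by_kind.get("salt_bridge", [])) == 1
    assert len(by_kind.get("hydrophobic", [])) == 1

    # brute force O(n^2) re-scan for hydrophobic contacts
    count = 0
    for i in range(top.n_atoms):
        for j in range(top.n_atoms):
            if lig[i] and not lig[j] and top.is_apolar[i] and top.is_apolar[j]:
                if np.linalg.norm(frame[i] - frame[j]) < 4.0:
                    count += 1
    assert count == len(by_kind["hydrophobic"])


def test_detectors_rigid_motion_invariant(planted_traj):
    traj, _ = planted_traj
    th = 0.9
    R = np.array([[np.cos(th), 0, np.sin(th)], [0, 1, 0],
                  [-np.sin(th), 0, np.cos(th)]])
    frame = traj.coords[0] @ R.T + np.array([3.0, -7.0, 1.0])
    lig = traj.top.resname == "LIG"
    assert len(detect_hbonds(frame, traj.top)) == \
        len(detect_hbonds(traj.coords[0], traj.top))
    assert len(detect_contacts(frame, traj.top, lig)) == \
        len(detect_contacts(traj.coords[0], traj.top, lig))


def test_donor_h_without_heavy_is_topology_error():
    top = Topology.guess(names=["HD"], resids=[1], resnames=["X"],
                         elements=["H"])
    top.is_donor_h[0] = True
    with pytest.raises(ValueError, match="heavy"):
        top.validate()
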