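"""Shared fixtures: small planted data sets generated once per session."""

import numpy as np
import pytest

from fieldsar import chemio, fields, qsar, synthgen


@pytest.fixture(scope="session")
def small_qsar():
    """CI-scale planted QSAR set (60 molecules, 50/10 split, seed 1),
    run through the full align -> split -> fields pipeline."""
    spec = synthgen.QsarPlantSpec(n_molecules=60, n_train=50, n_test=10, seed=1)
    records, truth = synthgen.gen_qsar_set(spec)
    template = next(r for r in records if r.id == truth["template_id"])
    aligned, report = chemio.align_to_template(records, template,
                                               synthgen.SCAFFOLD_SMARTS)
    split = chemio.SplitSpec(n_total=60, n_train=50, n_test=10, seed=1,
                             template_id=truth["template_id"])
    train, test = chemio.split_train_test(aligned, split)
    grid = fields.build_grid(train, 2.0, 4.0)
    fs_train = fields.compute_comfa_set(train, grid)
    fs_test = fields.compute_comfa_set(test, grid)
    return {
        "spec": spec, "records": records, "truth": truth, "report": report,
        "template": template, "train": train, "test": test, "grid": grid,
        "fs_train": fs_train, "fs_test": fs_test,
        "y_train": np.array([r.activity for r in train]),
        "y_test": np.array([r.activity for r in test]),
    }


@pytest.fixture(scope="session")
def small_qsar_result(small_qsar):
    return qsar.build_qsar_model(small_qsar["fs_train"], small_qsar["y_train"])


@pytest.fixture(scope="session")
def planted_traj():
    """Default planted-mode trajectory with interaction scene, no jitter."""
    traj, truth = synthgen.gen_trajectory(synthgen.TrajPlantSpec())
    return traj, truth


@pytest.fixture(scope="session")
def random_complex():
    """Random protein–ligand scene plus its brute-force energy sheet."""
    return synthgen.gen_complex(n_protein_atoms=50, n_ligand_atoms=10, seed=3)
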