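import pytest

from esmacs import (EnergyComponents, EnsembleSpec, EnsembleTable,
                    SnapshotRecord, gen_ensemble)

#: published 1traj component means (ele, vdw, pol, nonpol -> total) used
#: as worked single-snapshot examples throughout the suite
WORKED_DECOMPOSITIONS = {
    "LDHA12": (-22.24, -26.08, 31.70, -2.79, -16.63),
    "LDHA14": (-7.38, -20.20, 16.95, -2.09, -10.63),
    "LDHA21": (-380.30, -24.95, 361.13, -3.23, -44.12),
    "LDHA26": (-410.61, -56.23, 403.40, -5.89, -63.44),
}


def make_single_record_table(ligand_id, ele, vdw, pol, nonpol, e_int=0.0):
    """One complex snapshot holding the given component differences, with
    all-zero receptor/ligand records so the 1traj difference equals them."""
    zero = EnergyComponents(0, 0, 0, 0, 0)
    recs = [
        SnapshotRecord(ligand_id, "complex", "complex", 1, 0,
                       EnergyComponents(e_int, ele, vdw, pol, nonpol)),
        SnapshotRecord(ligand_id, "receptor", "complex", 1, 0, zero),
        SnapshotRecord(ligand_id, "ligand", "complex", 1, 0, zero),
    ]
    return EnsembleTable.from_records(recs)


@pytest.fixture(scope="session")
def small_ensemble():
    """A 4-ligand, 5-replica synthetic ensemble with known true dG."""
    true_dg = {"LIG01": -10.0, "LIG02": -8.0, "LIG03": -6.0, "LIG04": -4.0}
    spec = EnsembleSpec(true_dg=true_dg, n_replicas=5, n_frames=8,
                        sigma_replica=1.5, sigma_frame=3.0, seed=42)
    return spec, gen_ensemble(spec)
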