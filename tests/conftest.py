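import numpy as np
import pytest

from covshift.chemdata import AssayCutoffs, MoleculeRecord
from covshift.synthetic_data import (
    DriftSimConfig,
    GaussianToyConfig,
    make_fingerprint_drift,
    make_gaussian_toy,
)

SIGMA_GRID_TOY = [0.2, 0.3, 0.5, 0.8, 1.2, 2.0]


@pytest.fixture
def herg_cutoffs() -> AssayCutoffs:
    """hERG rule: active below 10 uM, inactive above 15 uM (values in uM)."""
    return AssayCutoffs("hERG", 10.0, "<", 15.0, ">")


@pytest.fixture
def molecule_csv(tmp_path):
    """Factory writing a small molecule table; returns (path, column_map)."""

    def write(rows, header="mol_id,structure,ic50,reg_date"):
        path = tmp_path / "mols.csv"
        path.write_text("\n".join([header] + rows) + ("\n" if rows else "\n"))
        colmap = {"id": "mol_id", "smiles": "structure", "value": "ic50", "date": "reg_date"}
        return str(path), colmap

    return write


def _records(n, seed=0):
    rng = np.random.default_rng(seed)
    from datetime import date, timedelta

    smiles = ["CCO", "CCN", "CCC", "c1ccccc1", "CC(=O)O", "CCOC", "CCS", "CNC"]
    return [
        MoleculeRecord(
            id=f"m{i:03d}",
            smiles=smiles[i % len(smiles)],
            assay_value=float(rng.uniform(1, 30)),
            registration_date=date(2018, 1, 1) + timedelta(days=int(rng.integers(0, 1000))),
        )
        for i in range(n)
    ]


@pytest.fixture
def random_records():
    return _records


@pytest.fixture(scope="session")
def drift_sim():
    """Default fingerprint-drift simulation (n=2000/2000, 64 bits)."""
    return make_fingerprint_drift(DriftSimConfig(seed=5))


@pytest.fixture(scope="session")
def noshift_sim():
    """Drift simulator with zero drift: train and prediction iid."""
    return make_fingerprint_drift(DriftSimConfig(drift_magnitude=0.0, seed=6))


@pytest.fixture(scope="session")
def gaussian_toy():
    return make_gaussian_toy(GaussianToyConfig(seed=1))
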