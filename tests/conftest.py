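import numpy as np
import pytest
from hypothesis import settings

import ktrkit as k

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

SCORES = (8.0, 10.5, 11.5, 12.5, 15.5)


def sensor_with_score(score: float, *, mw_kda: float = 32.0, copies: int = 2) -> k.SensorSpec:
    return k.SensorSpec(
        name=f"ePKA-{score}", nls_score=score, mw_kda=mw_kda, copies=copies,
        kinase="PKA", channel="KTR_PKA",
    )


@pytest.fixture(scope="session")
def params() -> k.TransportParams:
    return k.TransportParams()


@pytest.fixture(scope="session")
def pharm() -> k.PharmacologyTable:
    return k.PharmacologyTable()


@pytest.fixture(scope="session")
def mid_sensor() -> k.SensorSpec:
    return sensor_with_score(11.5)


@pytest.fixture(scope="session")
def small_experiment():
    """One noisy field, modest size: shared by segmentation/quantification tests."""
    cfg = k.ExperimentConfig(
        seed=21, n_fields=1, n_cells=10, n_frames=12, field_px=(320, 320),
    )
    fields, activities = k.run_experiment(cfg)
    return cfg, fields[0], activities


@pytest.fixture(scope="session")
def clean_experiment():
    """One noise-free, drift-free field for exact-recovery checks."""
    cfg = k.ExperimentConfig(
        seed=22, n_fields=1, n_cells=10, n_frames=6, field_px=(320, 320),
        noise=k.NoiseModel(read_sigma=0.0, poisson=False),
    )
    fields, activities = k.run_experiment(cfg)
    return cfg, fields[0], activities


def match_cells(labels: "k.LabelMaps", gt: "k.GroundTruth") -> dict[int, int]:
    """Map segmented cell ids to ground-truth cell ids by nucleus overlap."""
    out = {}
    for cid in labels.cell_ids:
        vals, cnts = np.unique(
            gt.nucleus_labels[labels.nucleus_labels == cid], return_counts=True
        )
        nz = vals != 0
        if nz.any():
            out[cid] = int(vals[nz][np.argmax(cnts[nz])])
    return out
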