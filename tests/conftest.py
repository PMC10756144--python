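import numpy as np
import pytest

from morphodelim import BS_WORKER, Dataset, MorphRecord, SC_WORKER


def make_record(sid, nest, caste="worker", **measurements):
    return MorphRecord(
        specimen_id=sid, nest_id=nest, caste=caste,
        measurements={k: float(v) for k, v in measurements.items()},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def sc_linear_dataset():
    """SC-system dataset where every trait lies exactly on trait = 5 + 0.3·CL1."""
    records = []
    for nest, sizes in {"A": (450, 500, 550), "B": (400, 480, 560, 600)}.items():
        for i, cl1 in enumerate(sizes):
            records.append(
                make_record(
                    f"{nest}{i}", nest, CL1=cl1,
                    SL=5 + 0.3 * cl1, MW=5 + 0.3 * cl1,
                )
            )
    return Dataset(system=SC_WORKER, records=records)


@pytest.fixture
def bs_small_dataset(rng):
    """Small BS worker dataset with mild noise around plausible values."""
    records = []
    for nest in range(6):
        for j in range(4):
            cs = rng.normal(480, 40)
            r = rng.normal(1.17, 0.02)
            records.append(
                make_record(
                    f"N{nest}-{j}", f"N{nest}",
                    CL2=2 * r * cs / (1 + r), CW=2 * cs / (1 + r),
                    SL=0.70 * cs + rng.normal(0, 4),
                    ML=1.2 * cs + rng.normal(0, 8),
                    CLSPD=0.13 * cs + rng.normal(0, 3),
                    PEW=0.32 * cs + rng.normal(0, 3),
                )
            )
    return Dataset(system=BS_WORKER, records=records)
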