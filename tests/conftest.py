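import numpy as np
import pandas as pd
import pytest

from omnorm.datamodel import (ROLE_BIOLOGICAL, ROLE_QC, Dataset, OmicsMatrix,
                              SampleSheet)

DEFAULT_TIMES = (5, 15, 30, 60, 120, 240, 480, 720, 1440)


def make_sheet(n_bio: int | None = None, n_qc: int = 0, treatments=("a", "b"),
               times=DEFAULT_TIMES, replicates=1) -> SampleSheet:
    """Sample sheet with a full treatments x times x replicates grid when
    n_bio is None, else n_bio plain biological samples (0 = QC only), plus
    n_qc pooled QC."""
    rows, order = [], 1
    if n_bio is not None:
        for i in range(n_bio):
            rows.append((f"S{i + 1}", ROLE_BIOLOGICAL, treatments[i % len(treatments)],
                         float(times[i % len(times)]), order, "B1"))
            order += 1
    else:
        for t in treatments:
            for tm in times:
                for r in range(replicates):
                    rows.append((f"{t}_{tm}_{r + 1}", ROLE_BIOLOGICAL, t,
                                 float(tm), order, "B1"))
                    order += 1
    for q in range(n_qc):
        rows.append((f"QC{q + 1}", ROLE_QC, None, np.nan, order, "B1"))
        order += 1
    return SampleSheet(pd.DataFrame(
        rows, columns=["sample_id", "role", "treatment", "time_minutes",
                       "injection_order", "batch"]))


def make_dataset(values, sheet: SampleSheet | None = None,
                 n_qc: int = 0) -> Dataset:
    values = np.asarray(values, dtype=float)
    if sheet is None:
        sheet = make_sheet(n_bio=values.shape[1] - n_qc, n_qc=n_qc)
    matrix = OmicsMatrix([f"F{i + 1}" for i in range(values.shape[0])],
                         sheet.sample_ids, values)
    return Dataset(matrix, sheet)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_grid_dataset(rng):
    """2 treatments x 9 times x 2 replicates + 6 QC, log-normal intensities."""
    sheet = make_sheet(replicates=2, n_qc=6)
    n = len(sheet.sample_ids)
    X = np.exp(rng.normal(8.0, 1.0, (30, n)))
    return make_dataset(X, sheet)
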