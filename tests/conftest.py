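import numpy as np
import pandas as pd
import pytest

from uromet.datamodel import MetaboliteProfileTable
from uromet.synthetic import GeneratorConfig, generate_study, table1_preset


def make_table(values: np.ndarray, *, subjects=None, interventions=None,
               times=None, roles=None, creatinine=None, metabolites=None,
               normalized=False, transform_state="raw",
               batch=None, injection=None) -> MetaboliteProfileTable:
    """Hand-build a profile table from a value matrix and metadata lists."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n, p = values.shape
    metabolites = metabolites or [f"m{j + 1}" for j in range(p)]
    subjects = subjects if subjects is not None else [f"S{i:02d}" for i in range(1, n + 1)]
    interventions = interventions if interventions is not None else ["alcohol"] * n
    times = times if times is not None else [0] * n
    roles = roles if roles is not None else ["experimental"] * n
    creatinine = creatinine if creatinine is not None else [10.0] * n
    batch = batch if batch is not None else ["B1"] * n
    injection = injection if injection is not None else list(range(1, n + 1))
    meta = pd.DataFrame({
        "sample_id": [f"{s}_{a[0].upper()}{t}_{i}" for i, (s, a, t) in
                      enumerate(zip(subjects, interventions, times))],
        "subject_id": subjects,
        "intervention": interventions,
        "time_h": times,
        "role": roles,
        "batch_id": batch,
        "injection_order": injection,
        "creatinine_mmol_per_L": creatinine,
    })
    df = pd.concat([meta, pd.DataFrame(values, columns=metabolites)], axis=1)
    return MetaboliteProfileTable(df, normalized=normalized,
                                  transform_state=transform_state)


@pytest.fixture(scope="session")
def preset_truth():
    return table1_preset()


@pytest.fixture(scope="session")
def study_table(preset_truth):
    """One study-noise synthetic study without the QC layout."""
    table, truth = generate_study(GeneratorConfig(), preset_truth, seed=314)
    return table, truth


@pytest.fixture(scope="session")
def layout_table(preset_truth):
    """One synthetic study emitted in the full 25-injection batch layout."""
    table, truth = generate_study(
        GeneratorConfig(include_qc_layout=True), preset_truth, seed=2718)
    return table, truth
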