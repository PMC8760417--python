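import numpy as np
import pandas as pd
import pytest

from cyclesig import periodicity, preprocess, signature
from cyclesig.simulate import SimConfig, simulate_cell_cycle_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """2000-protein dataset with 6% planted periodicity, shared across tests."""
    cfg = SimConfig(n_proteins=2000, frac_periodic=0.06, seed=101)
    table, truth = simulate_cell_cycle_dataset(cfg)
    return table, truth


@pytest.fixture(scope="session")
def ppm_table(small_dataset):
    table, _ = small_dataset
    return preprocess.ppm_normalize(table)


@pytest.fixture(scope="session")
def psp_calls(ppm_table):
    pts = preprocess.assemble_pseudotimecourses(ppm_table)
    results = periodicity.test_pseudotimecourses(pts)
    return periodicity.call_psps(results)


@pytest.fixture(scope="session")
def psp_ids(psp_calls):
    return list(psp_calls.index[psp_calls["is_psp"]])


@pytest.fixture(scope="session")
def signature_model(ppm_table, psp_ids):
    model = signature.build_signature(ppm_table, psp_ids)
    return signature.aggregate_ccs(model, seed=202)


def make_design_table(values_by_sample: dict[str, list[float]], ids=None):
    """Small abundance table from explicit per-sample value lists."""
    df = pd.DataFrame(values_by_sample)
    df.index = pd.Index(
        ids if ids is not None else [f"Q{i}" for i in range(len(df))],
        name="protein_id",
    )
    return df


def full_design_table(n_proteins=5, n_pops=16, n_bio=2, n_tech=2, seed=0):
    """Complete crossed-design table of positive random intensities."""
    rng = np.random.default_rng(seed)
    cols = {
        f"P{p}_B{b}_T{t}": rng.uniform(10, 100, n_proteins)
        for b in range(1, n_bio + 1)
        for p in range(1, n_pops + 1)
        for t in range(1, n_tech + 1)
    }
    return make_design_table(cols)
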