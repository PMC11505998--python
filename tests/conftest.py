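import numpy as np
import pandas as pd
import pytest

from oncopipe import synth


@pytest.fixture
def single_pair_spec():
    """One cell line x one drug on the default ladder, noise-free."""
    return synth.PlateSpec(
        cell_lines=("A",), drugs=("gedatolisib",),
        gr_params={("A", "gedatolisib"): (-0.5, 20.0, 1.0)},
        doubling_time_h={"A": 24.0}, noise_cv=0.0, seed=0)


def make_plate_table(gr_values, concentrations, t=72.0, x0=1000.0, k0=1.0 / 24.0):
    """Build a plate table whose recomputed GR values equal gr_values exactly."""
    rows = [("A", "DMSO", 0.0, 0, x0, x0 * 2.0 ** (k0 * t), t)]
    for c, gr in zip(concentrations, gr_values):
        kc = k0 * np.log2(1.0 + gr)
        rows.append(("A", "drug", float(c), 0, x0, x0 * 2.0 ** (kc * t), t))
    return pd.DataFrame(rows, columns=["cell_line", "drug", "conc_nM", "replicate",
                                       "signal_t0", "signal_t", "duration_h"])


@pytest.fixture(scope="session")
def small_cohort():
    return synth.gen_expression_cohort(synth.CohortSpec(
        n_samples=150, n_genes=600, n_batches=3, batch_shift_sd=0.5, seed=11))
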