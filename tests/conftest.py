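import numpy as np
import pandas as pd
import pytest

from immunomrm import AnalysisConfig
from immunomrm.simulate import SimParams, simulate_curve_dataset


@pytest.fixture
def cfg():
    return AnalysisConfig()


@pytest.fixture
def noise_free_params():
    """Deterministic generator: no lognormal noise, no background."""
    return SimParams(n_peptides=2, sigma_within=0.0, sigma_between_day=0.0,
                     background_mean=0.0, background_sd=0.0, rt_jitter=0.0,
                     seed=11)


@pytest.fixture
def small_curve(noise_free_params):
    report, design, truth = simulate_curve_dataset(noise_free_params, reps=3)
    return report, design, truth


def make_report(rows):
    """Assemble a transition report DataFrame from short tuples."""
    return pd.DataFrame(rows, columns=["sample_id", "peptide_id", "label",
                                       "transition_id", "peak_area",
                                       "background", "retention_time"])


@pytest.fixture
def tiny_panel():
    return pd.DataFrame({
        "gene_symbol": ["G1"], "peptide_id": ["PEPTIDEK"],
        "accession": ["P00001"], "description": ["x"], "status": ["active"],
        "spike_multiplier": [1.0], "heavy_spike_conc": [200.0],
        "is_phospho": [False],
    })
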