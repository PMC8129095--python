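import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def tone_trace():
    """Noiseless 40 Hz unit-amplitude sinusoid, 60 s at 5 kHz."""
    from lfpexcite import simulate_trace
    trace, truth = simulate_trace(gamma_freq=40.0, gamma_amp=1.0, noise_sd=0.0)
    return trace, truth


@pytest.fixture(scope="session")
def small_cohort_summary():
    """Summary table of a reduced simulated cohort (trace level)."""
    from lfpexcite import simulate_cohort, summarize_cohort
    cohort = simulate_cohort(
        n_mice_per_genotype=2, slices_per_mouse=2,
        ka_ladder=(0.0, 150.0, 400.0), seed=7)
    return summarize_cohort(cohort), cohort


@pytest.fixture(scope="session")
def de_study():
    from lfpexcite import simulate_de_study
    return simulate_de_study(n_genes=3000, seed=11)


def make_de_table(logfc, genes=None, pvalue=0.5):
    logfc = np.asarray(logfc, dtype=float)
    if genes is None:
        genes = [f"g{i}" for i in range(len(logfc))]
    return pd.DataFrame({"gene": genes, "logFC": logfc,
                         "pvalue": np.full(len(logfc), pvalue)})
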