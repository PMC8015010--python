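import numpy as np
import pandas as pd
import pytest

from oxiprot import (
    SyntheticConfig,
    default_registry,
    generate_proteome,
    generate_quant_table,
)

# Published class-by-category peptide counts for the irradiated E. coli
# TMT experiment (detected, quantified, no-change, >1, >2, <1, <0.5).
ECOLI_COUNTS = pd.DataFrame(
    {
        "total_detected": [15108, 117, 1861, 351, 55],
        "total_quantified": [13262, 80, 1664, 285, 41],
        "no_change": [11703, 72, 1437, 247, 28],
        "increase_gt1": [764, 5, 175, 24, 11],
        "increase_gt2": [48, 0, 19, 2, 2],
        "decrease_lt1": [795, 3, 52, 14, 2],
        "decrease_lt05": [2, 0, 0, 0, 0],
    },
    index=["total", "carbonylated", "hydroxylated", "dioxidized", "trioxidized"],
)

ECOLI_PERCENTS = pd.DataFrame(
    {
        "total_detected": [0.8, 12.3, 2.3, 0.4],
        "total_quantified": [0.6, 12.5, 2.1, 0.3],
        "no_change": [0.6, 12.3, 2.1, 0.2],
        "increase_gt1": [0.7, 22.9, 3.1, 1.4],
        "increase_gt2": [0.0, 39.6, 4.2, 4.2],
        "decrease_lt1": [0.4, 6.5, 1.8, 0.3],
        "decrease_lt05": [0.0, 0.0, 0.0, 0.0],
    },
    index=["carbonylated", "hydroxylated", "dioxidized", "trioxidized"],
)

# The same, for the radioresistant-organism experiment; the two rightmost
# columns are empty so their percentages are undefined (N/A).
DEINO_COUNTS = pd.DataFrame(
    {
        "total_detected": [13777, 189, 2198, 498, 43],
        "total_quantified": [11526, 134, 1779, 399, 26],
        "no_change": [11525, 134, 1778, 399, 26],
        "increase_gt1": [1, 0, 1, 0, 0],
        "increase_gt2": [1, 0, 1, 0, 0],
        "decrease_lt1": [0, 0, 0, 0, 0],
        "decrease_lt05": [0, 0, 0, 0, 0],
    },
    index=["total", "carbonylated", "hydroxylated", "dioxidized", "trioxidized"],
)

DEINO_PERCENTS = pd.DataFrame(
    {
        "total_detected": [1.4, 16.0, 3.6, 0.3],
        "total_quantified": [1.2, 15.4, 3.5, 0.2],
        "no_change": [1.2, 15.4, 3.5, 0.2],
        "increase_gt1": [0.0, 100.0, 0.0, 0.0],
        "increase_gt2": [0.0, 100.0, 0.0, 0.0],
        "decrease_lt1": [np.nan] * 4,
        "decrease_lt05": [np.nan] * 4,
    },
    index=["carbonylated", "hydroxylated", "dioxidized", "trioxidized"],
)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(n_proteins=30, n_peptides=300)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """One seeded synthetic experiment shared across tests."""
    rng = np.random.default_rng(42)
    proteome, catalog = generate_proteome(small_config, rng)
    records, truth = generate_quant_table(small_config, rng, proteome=proteome)
    return {
        "config": small_config,
        "proteome": proteome,
        "catalog": catalog,
        "records": records,
        "truth": truth,
    }
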