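import numpy as np
import pandas as pd
import pytest

from glycohex import synthetic as syn


@pytest.fixture(scope="session")
def design() -> syn.CohortDesign:
    return syn.CohortDesign()


@pytest.fixture(scope="session")
def sample_table(design) -> pd.DataFrame:
    return design.sample_table()


@pytest.fixture(scope="session")
def zero_noise_glycome(design) -> pd.DataFrame:
    profiles = syn.default_profiles(design, "tissue", dispersion=0.0)
    return syn.generate_glycome_table(design, profiles, seed=7)


@pytest.fixture(scope="session")
def null_truth() -> dict:
    """Feature truth map with mostly-unchanged features and one elevated one."""
    return {
        ("P05164", 483, "Hex3HexNAc2dHex1"): {
            "control": 1.0, "I": 2.0, "II": 2.0, "III": 2.0, "IV": 2.0
        },
        ("P07602", 101, "Hex2HexNAc2dHex1"): 1.0,
        ("P02788", 156, "Hex5HexNAc2"): 1.0,
        ("P61626", 60, "Hex9HexNAc2"): 1.0,
        ("P04406", 205, "Hex5HexNAc4dHex1"): 1.0,
    }
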