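import warnings

import numpy as np
import pandas as pd
import pytest

from nefwheat.simulate import SyntheticDesign, generate_phenotypes, generate_spectra

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def default_design():
    return SyntheticDesign(seed=1)


@pytest.fixture(scope="session")
def default_spectra(default_design):
    return generate_spectra(default_design)


@pytest.fixture(scope="session")
def default_phenotypes(default_design):
    return generate_phenotypes(default_design)


@pytest.fixture(scope="session")
def small_spectra():
    """Fast fixture: 6 varieties, 1 region, 64 bands."""
    design = SyntheticDesign(
        n_varieties=6, regions_per_plot=2, include_references=False, seed=3
    )
    return design, generate_spectra(design, n_bands=64)


@pytest.fixture()
def toy_phenotypes():
    """2 varieties × 2 levels × 2 replicates with hand-friendly numbers."""
    rows = []
    for variety, level, rep, wy, ana, wdmm, tgw in [
        ("A", "N0", 1, 4000.0, 1.8, 12.0, 40.0),
        ("A", "N0", 2, 4200.0, 2.0, 14.0, 42.0),
        ("A", "N1", 1, 5000.0, 2.4, 16.0, 44.0),
        ("A", "N1", 2, 5200.0, 2.6, 18.0, 46.0),
        ("B", "N0", 1, 3000.0, 1.2, 10.0, 36.0),
        ("B", "N0", 2, 3200.0, 1.4, 11.0, 38.0),
        ("B", "N1", 1, 2900.0, 1.5, 12.0, 39.0),
        ("B", "N1", 2, 3100.0, 1.7, 13.0, 41.0),
    ]:
        rows.append(
            {
                "variety": variety,
                "n_level": level,
                "replicate": rep,
                "WY_raw": wy,
                "ANA_raw": ana,
                "WDMM_raw": wdmm,
                "TGW_raw": tgw,
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
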