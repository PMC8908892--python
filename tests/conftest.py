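import numpy as np
import pytest

from raylife.diet import StomachSample
from raylife.growth import GrowthParams
from raylife.inference import MCMCConfig


@pytest.fixture
def table_medians():
    """Posterior-median growth parameters for the three fitted families."""
    return {
        "von_bertalanffy": GrowthParams("von_bertalanffy", 44.7, 13.9, 0.1, 1.5),
        "gompertz": GrowthParams("gompertz", 38.1, 14.0, 0.2, 1.5),
        "logistic": GrowthParams("logistic", 34.5, 14.0, 0.3, 1.5),
    }


@pytest.fixture
def quick_mcmc():
    """Shortened chain protocol for unit tests that only need a rough posterior."""
    return MCMCConfig(n_chains=2, n_iter=1200, n_warmup=400, seed=99)


@pytest.fixture
def four_stomachs():
    """Hand-checkable fixture: three stomachs with food plus one empty."""
    return [
        StomachSample(
            "s1", "adult", 500.0,
            masses={"crustaceans": 5.0, "bivalves": 2.5, "unidentified": 0.5},
            counts={"crustaceans": 3, "bivalves": 1, "unidentified": 1},
        ),
        StomachSample(
            "s2", "adult", 250.0,
            masses={"crustaceans": 1.0, "teleosts": 2.0},
            counts={"crustaceans": 2, "teleosts": 1},
        ),
        StomachSample(
            "s3", "adult", 1000.0,
            masses={"polychaetes": 4.0, "unidentified": 1.0},
            counts={"polychaetes": 6, "unidentified": 2},
        ),
        StomachSample("s4", "adult", 400.0, masses={}, counts={}),
    ]
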