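import pandas as pd
import pytest

from growthlnc import GrowthModelParams

# Published parameter estimates for the three growth models fitted to the
# QingYu pig cohort (asymptote A kg, shape B, rate k per day).
TABLE1_PARAMS = {
    "logistic": GrowthModelParams("logistic", 135.63, 22.075, 0.017),
    "von_bertalanffy": GrowthModelParams("von_bertalanffy", 198.903, 0.826, 0.005),
    "gompertz": GrowthModelParams("gompertz", 165.829, 4.141, 0.008),
}


@pytest.fixture
def table1_params():
    return TABLE1_PARAMS


@pytest.fixture
def toy_candidates():
    """Six candidate transcripts exercising every branch of the filter."""
    return pd.DataFrame(
        {
            "transcript_id": [f"t{i}" for i in range(1, 7)],
            "length": [150, 500, 500, 2000, 300, 250],
            "exon_count": [1, 1, 3, 5, 2, 1],
            "read_support": [10, 2, 10, 10, 10, 10],
            "cnci": [-3, -3, -3, 4, -0.5, 0.5],
            "cpc": [-2, -2, -2, 2, -1.5, -2],
        }
    )
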