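import numpy as np
import pandas as pd
import pytest


def two_group_frame(nc_values, vt_values, trait="t", generation="F1", covariate=None):
    """Build a minimal long-format trait table from two value vectors."""
    rows = []
    for i, v in enumerate(np.asarray(nc_values, dtype=float)):
        rows.append(
            {
                "animal_id": f"nc{i}",
                "group": "NC",
                "generation": generation,
                "trait": trait,
                "value": v,
            }
        )
    for i, v in enumerate(np.asarray(vt_values, dtype=float)):
        rows.append(
            {
                "animal_id": f"vt{i}",
                "group": "VT",
                "generation": generation,
                "trait": trait,
                "value": v,
            }
        )
    df = pd.DataFrame(rows)
    if covariate is not None:
        df["covariate"] = np.asarray(covariate, dtype=float)
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
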