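import numpy as np
import pandas as pd
import pytest

from matchedcc import SimConfig, build_design, simulate_matched_design


@pytest.fixture(scope="session")
def matched_500():
    """500 1:1 strata generated under the exact conditional model, true OR 1.5."""
    return simulate_matched_design(500, np.log(1.5), seed=42)


@pytest.fixture(scope="session")
def design_500(matched_500):
    return build_design(matched_500)


@pytest.fixture()
def toy_pairs():
    """1:1 strata with known discordance: 10 case-exposed, 5 control-exposed, 7 concordant."""
    rows, sid = [], 0
    for _ in range(10):
        rows += [(sid, 1, 1.0), (sid, 0, 0.0)]
        sid += 1
    for _ in range(5):
        rows += [(sid, 1, 0.0), (sid, 0, 1.0)]
        sid += 1
    for _ in range(7):
        rows += [(sid, 1, 1.0), (sid, 0, 1.0)]
        sid += 1
    return pd.DataFrame(rows, columns=["stratum_id", "is_case", "exposure"])


@pytest.fixture(scope="session")
def small_cohort():
    cfg = SimConfig(n_women=4000, seed=7)
    from matchedcc import simulate_cohort

    return simulate_cohort(cfg)
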