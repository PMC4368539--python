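import pandas as pd
import pytest
from hypothesis import settings

import rppatterns as rp

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from rppatterns import PatternCode


@pytest.fixture(scope="session")
def small_design() -> rp.DesignSpec:
    """One region/fraction, 2 planted proteins, 4 mice/group: fast but complete."""
    return rp.DesignSpec(
        n_mice_per_group=4,
        regions=["hippocampus"],
        fractions=["nuclear"],
        n_proteins=2,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_effects(small_design) -> pd.DataFrame:
    return rp.effects_table(
        small_design,
        {
            ("P001", "hippocampus", "nuclear"): rp.archetype_to_effects(PatternCode.FL_EQ_NL, 20),
            ("P002", "hippocampus", "nuclear"): rp.archetype_to_effects(PatternCode.B_PLUS_FL, 40, 20),
        },
    )


@pytest.fixture(scope="session")
def table3_long() -> pd.DataFrame:
    return rp.table3_results()


def profile(nl, fl, b, rl, btm, protein="X", region="hippocampus", fraction="nuclear"):
    """Shorthand: each argument is (percent, significant)."""
    return rp.InstanceProfile(
        protein, region, fraction,
        {"NL": nl, "FL": fl, "B": b, "RL": rl, "B-tm": btm},
    )
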