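import pandas as pd
import pytest

import gicomp as g


@pytest.fixture(scope="session")
def battery():
    return g.demo_battery()


@pytest.fixture(scope="session")
def cohort(battery):
    """A mid-sized simulated cohort with grades, shared across tests."""
    cfg = g.demo_sim_config(n_subjects=2000, seed=7, grade_fraction=0.5)
    return g.generate_study_cohort(cfg)


@pytest.fixture(scope="session")
def norms(cohort, battery):
    return g.build_norm_table(cohort, battery)


@pytest.fixture(scope="session")
def lookup(cohort, battery, norms):
    return g.build_reliability_lookup(cohort, battery, norms)


@pytest.fixture(scope="session")
def pair(cohort, battery, norms, lookup):
    """FSIQ7 vs ABIQ2 with all six criteria evaluated."""
    return g.compare_pair(cohort, battery, norms, "FSIQ7", "ABIQ2", lookup)


@pytest.fixture
def mini_battery():
    """Two subtests, one composite, one age band: for hand-arithmetic checks."""
    return g.BatteryConfig(
        name="mini",
        subtests=(
            g.SubtestSpec("s1", "Gf", 0.7, 0.85),
            g.SubtestSpec("s2", "Gc", 0.7, 0.85),
        ),
        composites=(g.CompositeSpec("IQ2", ("s1", "s2")),),
        age_bands=((5, 21),),
    )
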