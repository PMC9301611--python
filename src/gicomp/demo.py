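"""Built-in battery configurations.

``demo_battery``/``demo_sim_config`` define the synthetic battery used by the
simulation-driven analyses: 14 subtests, two per broad-ability slot of a
seven-slot profile (with short-term memory contributing two slots, so six
distinct CHC codes), a 14-subtest extended composite, a 7-subtest full-scale
composite and a 2-subtest screener.  Its loadings and reliabilities are
synthetic stand-ins chosen to resemble a well-constructed child battery
(loadings .56-.78, subtest reliabilities .82-.90).

``reference_batteries`` encode the published composite *compositions* (ability
profiles and subtest counts) of three commercial batteries — an extended 14- /
full 7- / screening 2-subtest battery, a 10-subtest battery with a 2-subtest
screener, and a 4-subtest battery with a 2-subtest screener — as needed for
content-overlap arithmetic.  ``published_reliabilities`` carries the
composites' published overall internal consistencies and test-retest
coefficients, used as hand-entered inputs for CI-width and disattenuation
checks.  The per-subtest loadings/reliabilities of the reference batteries are
synthetic placeholders (the manuals' values are proprietary) and play no role
in those checks.
"""

from __future__ import annotations

from .battery import BatteryConfig, CompositeSpec, SubtestSpec
from .simulate import SimConfig

_PROFILE = (
    # (stem, ability, loading, reliability) for the seven profile slots
    ("visual_processing", "Gv", 0.72, 0.87),
    ("processing_speed", "Gs", 0.58, 0.88),
    ("auditory_memory", "Gsm", 0.68, 0.84),
    ("spatial_memory", "Gsm", 0.66, 0.83),
    ("long_term_memory", "Glr", 0.70, 0.85),
    ("abstract_reasoning", "Gf", 0.78, 0.90),
    ("verbal_reasoning", "Gc", 0.74, 0.89),
)


def demo_battery() -> BatteryConfig:
    """The synthetic 14-subtest battery driving all simulation analyses."""
    subtests = []
    for stem, ability, lam, rel in _PROFILE:
        subtests.append(SubtestSpec(stem, ability, lam, rel, retest=0.80))
        subtests.append(SubtestSpec(f"{stem}_2", ability, lam - 0.02, rel - 0.01, retest=0.78))
    first_seven = [s[0] for s in _PROFILE]
    composites = [
        CompositeSpec("EBIQ14", tuple(s.name for s in subtests), retest=0.90),
        CompositeSpec("FSIQ7", tuple(first_seven), retest=0.88),
        CompositeSpec("ABIQ2", ("abstract_reasoning", "verbal_reasoning"), retest=0.84),
    ]
    return BatteryConfig(
        name="synthetic-14",
        subtests=tuple(subtests),
        composites=tuple(composites),
        age_bands=((5, 7), (7, 9), (9, 13), (13, 16), (16, 21)),
    )


def demo_sim_config(n_subjects: int = 1600, seed: int = 0, **overrides) -> SimConfig:
    """Default simulation conditions on the demo battery."""
    return SimConfig(battery=demo_battery(), n_subjects=n_subjects, seed=seed, **overrides)


def _placeholder(name: str, ability: str) -> SubtestSpec:
    # composition-only batteries: loading/reliability values are inert stand-ins
    return SubtestSpec(name, ability, loading=0.70, reliability=0.85)


def reference_batteries() -> dict[str, BatteryConfig]:
    """Published composite compositions of three commercial batteries.

    Only subtest counts and ability profiles matter here; they drive the
    content-overlap percentages 100 / 44 / 38 / 50 / 100 for the five
    within-battery composite pairs.
    """
    ids2_profile = ["Gv", "Gs", "Gsm", "Gsm", "Glr", "Gf", "Gc"]
    ids2_subtests = []
    for i, ability in enumerate(ids2_profile, 1):
        ids2_subtests.append(_placeholder(f"s{i}a", ability))
        ids2_subtests.append(_placeholder(f"s{i}b", ability))
    ids2 = BatteryConfig(
        name="battery-A",
        subtests=tuple(ids2_subtests),
        composites=(
            CompositeSpec("EBIQ14", tuple(s.name for s in ids2_subtests)),
            CompositeSpec("FSIQ7", tuple(f"s{i}a" for i in range(1, 8))),
            CompositeSpec("ABIQ2", ("s6a", "s7a")),  # the Gf and Gc subtests
        ),
        age_bands=((5, 21),),
    )

    sb5_abilities = ["Gf", "Gc", "Gq", "Gv", "Gsm"]
    sb5_subtests = []
    for i, ability in enumerate(sb5_abilities, 1):
        sb5_subtests.append(_placeholder(f"v{i}", ability))   # verbal
        sb5_subtests.append(_placeholder(f"n{i}", ability))   # nonverbal
    sb5 = BatteryConfig(
        name="battery-B",
        subtests=tuple(sb5_subtests),
        composites=(
            CompositeSpec("FSIQ10", tuple(s.name for s in sb5_subtests)),
            CompositeSpec("ABIQ2", ("n1", "v2")),  # the two routing subtests (Gf, Gc)
        ),
        age_bands=((4, 84),),
    )

    rias_subtests = (
        _placeholder("verbal1", "Gc"),
        _placeholder("verbal2", "Gc"),
        _placeholder("nonverbal1", "Gf"),
        _placeholder("nonverbal2", "Gf"),
    )
    rias = BatteryConfig(
        name="battery-C",
        subtests=rias_subtests,
        composites=(
            CompositeSpec("FSIQ4", tuple(s.name for s in rias_subtests)),
            CompositeSpec("ABIQ2", ("verbal1", "nonverbal1")),
        ),
        age_bands=((3, 100),),
    )
    return {"battery-A": ids2, "battery-B": sb5, "battery-C": rias}


def published_reliabilities() -> dict[str, dict[str, float]]:
    """Published overall internal consistencies and retest coefficients.

    Keyed by '<battery>/<composite>'; these are the printed manual-derived
    coefficients for the seven composites of the three reference batteries,
    used as inputs to CI-width and disattenuation arithmetic.
    """
    return {
        "battery-A/EBIQ14": {"overall": 0.98, "retest": 0.85},
        "battery-A/FSIQ7": {"overall": 0.97, "retest": 0.89},
        "battery-A/ABIQ2": {"overall": 0.95, "retest": 0.86},
        "battery-B/FSIQ10": {"overall": 0.99, "retest": 0.94},
        "battery-B/ABIQ2": {"overall": 0.97, "retest": 0.86},
        "battery-C/FSIQ4": {"overall": 0.95, "retest": 0.88},
        "battery-C/ABIQ2": {"overall": 0.93, "retest": 0.87},
    }
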