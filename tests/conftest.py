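import numpy as np
import pandas as pd
import pytest

from seromic import (
    CohortDesign,
    EffectSpec,
    PlantedEffect,
    aggregate_replicates,
    make_cohort,
    make_panel,
    normalize,
    simulate_spot_table,
)


@pytest.fixture(scope="session")
def small_panel():
    return make_panel(n_ct=15, n_ta=5, n_replicates=3, seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    design = CohortDesign(
        groups=[("PDAC", 10, "serum"), ("CP", 5, "serum"),
                ("DYS", 5, "serum"), ("LTBI", 10, "serum")],
        channels=["IgG", "IgA"],
        psa_fraction=0.0,
        seed=11,
    )
    return make_cohort(design)


@pytest.fixture(scope="session")
def small_spots(small_panel, small_cohort):
    effects = EffectSpec(planted_effects=[
        PlantedEffect("PDAC", "IgA", "CT001", 1.0),
        PlantedEffect("PDAC", "IgA", "CT002", 1.0, penetrance=0.8),
    ])
    return simulate_spot_table(small_panel, small_cohort, effects, seed=11)


@pytest.fixture(scope="session")
def small_rfu(small_panel, small_spots):
    matrices, _ = aggregate_replicates(small_spots, small_panel)
    return {ch: normalize(m) for ch, m in matrices.items()}


def spot_rows(net_values, sample="S1", channel="IgG", antigen="CT001", background=100.0):
    """Hand-build spot-table rows with the given net intensities."""
    rows = []
    for i, net in enumerate(net_values):
        rows.append({
            "sample_id": sample, "channel": channel, "antigen_id": antigen,
            "replicate_index": i, "block": i + 1, "row": 1, "column": 1,
            "foreground_median": background + net, "local_background": background,
            "flag": 0,
        })
    return pd.DataFrame(rows)
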