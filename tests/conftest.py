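import pytest

from rgctyping.pipeline import make_protocols
from rgctyping.stimuli import FieldGeometry
from rgctyping.synthetic import (
    ArchetypeSpec,
    default_archetypes,
    noiseless_responses,
    sample_population,
)

PROTOCOL_SEEDS = {"marching_square": 101, "narrow_bars": 102,
                  "width_test": 103, "speed_test": 104}


@pytest.fixture(scope="session")
def field():
    return FieldGeometry()


@pytest.fixture(scope="session")
def protocols(field):
    return make_protocols(PROTOCOL_SEEDS, field)


@pytest.fixture(scope="session")
def archetypes():
    return default_archetypes()


def canonical_archetypes():
    """One deterministic cell per archetype: distribution SDs set to zero so
    every draw equals the archetype's canonical parameters."""
    out = []
    for a in default_archetypes():
        out.append(ArchetypeSpec(
            name=a.name, polarity=a.polarity, latency_mean=a.latency_mean,
            latency_sd=0.0, transience_target=a.transience_target,
            is_ds=a.is_ds, ds_concentration=a.ds_concentration,
            preferred_direction=90.0 if a.is_ds else None,
            speed_pref=a.speed_pref, speed_bandwidth=a.speed_bandwidth,
            width_pref=a.width_pref, width_bandwidth=a.width_bandwidth,
            rf_diameter_mean=a.rf_diameter_mean, rf_diameter_sd=0.0,
            peak_rate=a.peak_rate, baseline_rate=a.baseline_rate))
    return out


@pytest.fixture(scope="session")
def canonical_cells(field):
    """One cell per archetype, placed at the field centre (receptive field
    fully inside the mapping grid, no traversal-boundary asymmetry)."""
    cells = sample_population(canonical_archetypes(), 1, field, seed=0,
                              margin=499.9)
    assert all(abs(c.rf_center[0] - 500.0) < 0.2 for c in cells)
    return cells


@pytest.fixture(scope="session")
def canonical_responses(canonical_cells, protocols):
    return {c.archetype: noiseless_responses(c, protocols)
            for c in canonical_cells}
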