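import pytest

from neurolapse.synthetic_data import (
    ConditionSpec,
    DynamicsRates,
    ImagingSchedule,
    RenderNoise,
    SimulationConfig,
)


@pytest.fixture
def small_schedule() -> ImagingSchedule:
    """A 600 um field imaged every 6 h for 2 days (9 frames)."""
    return ImagingSchedule(
        interval_hours=6.0, duration_days=2.0, field_size_um=(600.0, 600.0)
    )


@pytest.fixture
def frozen_rates() -> DynamicsRates:
    """All dynamics switched off: states must stay constant."""
    return DynamicsRates(
        node_gain_rate_per_day=0.0,
        node_loss_rate_per_day=0.0,
        neurite_growth_um_per_day=0.0,
        neurite_retract_um_per_day=0.0,
        soma_growth_um_per_day=0.0,
        soma_shrink_um_per_day=0.0,
        base_death_hazard_per_day=0.0,
        hazard_per_missing_node=0.0,
        motility_um_per_step=0.0,
        soma_radius_jitter_um=0.0,
    )


@pytest.fixture
def noiseless() -> RenderNoise:
    return RenderNoise(gaussian_sd=0.0)


def make_config(**kw) -> SimulationConfig:
    defaults = dict(
        n_cells=10,
        schedule=ImagingSchedule(
            interval_hours=6.0, duration_days=2.0, field_size_um=(600.0, 600.0)
        ),
        condition=ConditionSpec("TF+"),
        seed=0,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)
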