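import pytest

from skyshine import (
    BeamSpec,
    DEFAULT_K,
    RoofShield,
    Scenario,
    VaultGeometry,
)


@pytest.fixture
def elder_geom() -> VaultGeometry:
    """Elder et al. vault: d_w 4.5 m, h 3.6 m, d_i 6.6 m."""
    return VaultGeometry(d_w=4.5, h=3.6, d_i=6.6)


@pytest.fixture
def elder_beam_6mv() -> BeamSpec:
    return BeamSpec(nominal_mv=6, field_area_f0=1600.0, dose_rate_d0=600.0)


@pytest.fixture
def nominal_geom() -> VaultGeometry:
    """Nominal worst-case audit vault: d_w 5 m, h 4 m, no roof."""
    return VaultGeometry(d_w=5.0, h=4.0)


@pytest.fixture
def worst_case_scenario() -> Scenario:
    """Outdoor-seating worst case: W=500 Gy/wk, U=0.25, T=1/20, primary wall."""
    return Scenario(
        workload_w=500.0,
        use_factor_u=0.25,
        occupancy_t=1.0 / 20.0,
        hourly_workload_wh=800.0,
        wall_design_goal_p=10.0,
        wall_type="primary",
    )


@pytest.fixture
def open_roof() -> RoofShield:
    return RoofShield(1.0)


@pytest.fixture
def k6():
    return DEFAULT_K[6]
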