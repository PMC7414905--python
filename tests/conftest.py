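import numpy as np
import pytest

from thermoniche.synth import (FlightTraceSet, SpeciesProfile, TraceSimConfig,
                               simulate_flight_trace)


@pytest.fixture
def noise_free_profile() -> SpeciesProfile:
    """Fast-saturating, noise-free species: endothermy recoverable exactly."""
    return SpeciesProfile(name="clean", endothermy_true=5.0,
                          warmup_amplitude=5.0, warmup_rate=5.0,
                          slope_th_true=0.0, slope_abd_true=0.0,
                          mechanism_true="NONE", noise_sd=0.0)


@pytest.fixture
def noise_free_flight(noise_free_profile) -> FlightTraceSet:
    return simulate_flight_trace(noise_free_profile, TraceSimConfig(seed=0))


def make_flight(profile_kwargs=None, cfg_kwargs=None) -> FlightTraceSet:
    profile = SpeciesProfile(name="sp", **(profile_kwargs or {}))
    cfg = TraceSimConfig(**(cfg_kwargs or {}))
    return simulate_flight_trace(profile, cfg)
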