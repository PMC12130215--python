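import numpy as np
import pytest

from neurouq import (
    AgentParams,
    PopulationSpec,
    TaskConfig,
    generate_schedule,
    simulate_behavior,
    synthesize_population,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def expert_schedule():
    """200-trial imaging schedule with expert-agent outcomes, fixed seed."""
    r = np.random.default_rng(7)
    sched = generate_schedule(TaskConfig(n_trials=200), r)
    # a lapsy expert so FA and probe-lick trials are reliably present
    return simulate_behavior(sched, AgentParams(lapse_rate=0.2), r)


@pytest.fixture(scope="session")
def small_recording(expert_schedule):
    """High-SNR 40-neuron recording with planted go/lick neurons."""
    r = np.random.default_rng(11)
    spec = PopulationSpec(
        n_neurons=40,
        frac_go_neurons=0.2,
        frac_lick_neurons=0.2,
        response_amplitude=6.0,
        lick_amplitude=6.0,
        noise_sd=1.0,
        gain_variability=0.1,
        choice_coupling=0.0,
        tuning_center=420.0,
        tuning_width=60.0,
    )
    return synthesize_population(expert_schedule, spec, r, session_id="fix", day=8)
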