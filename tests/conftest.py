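import pytest

import vtapipe as vp


@pytest.fixture(scope="session")
def task_spec():
    return vp.TaskSpec()


@pytest.fixture(scope="session")
def config():
    return vp.AnalysisConfig()


@pytest.fixture(scope="session")
def small_sim(task_spec):
    """12-neuron full-task simulation shared across the suite."""
    pop = vp.PopulationSpec(n_phasic=6, n_sustained_excited=4,
                            n_sustained_inhibited=2, seed=7)
    return vp.simulate_population(pop, task_spec)


@pytest.fixture(scope="session")
def small_dataset(task_spec, small_sim):
    behavior = vp.simulate_behavior(task_spec, vp.BehaviorParams(), seed=7)
    return vp.Dataset(
        spikes=small_sim.spikes,
        events=small_sim.events,
        waveforms=small_sim.waveforms,
        behavior=behavior,
    ).validate()
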