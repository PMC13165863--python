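import pytest

from dyadsense.pipeline import analyze_session
from dyadsense.simulate import preset_scenarios, simulate_session


@pytest.fixture(scope="session")
def presets():
    return preset_scenarios()


@pytest.fixture(scope="session")
def simulated(presets):
    """Simulated log + ground truth per preset, seed fixed."""
    return {name: simulate_session(sc, seed=7) for name, sc in presets.items()}


@pytest.fixture(scope="session")
def analyses(presets, simulated):
    """Full pipeline output per preset (feedback forced on)."""
    return {name: analyze_session(log, task_events=presets[name].task_events,
                                  run_feedback=True)
            for name, (log, _) in simulated.items()}
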