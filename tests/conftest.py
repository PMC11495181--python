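import numpy as np
import pytest

from gaspnet import hypoxia_default, gen_session, detect_cycles, \
    classify_epochs, detect_gasps, AnalysisConfig


@pytest.fixture(scope="session")
def default_run():
    """One simulated hypoxia_default session (seed 1) plus its truth."""
    session, truth = gen_session(hypoxia_default(), seed=1)
    return session, truth


@pytest.fixture(scope="session")
def segmented(default_run):
    """Cycles, epochs, sighs and gasps of the default session."""
    session, truth = default_run
    cfg = AnalysisConfig()
    phr = session.signals["phrenic_integrated"]
    cycles = detect_cycles(phr, cfg, control_window=session.control_window)
    epochs, sighs = classify_epochs(phr, cycles, session.control_window,
                                    cfg)
    gasps = detect_gasps(phr, epochs, cfg, cycles=cycles,
                         control_window=session.control_window)
    return {"cycles": cycles, "epochs": epochs, "sighs": sighs,
            "gasps": gasps}


def poisson_train(rate, duration, seed, neuron_id="n", region="other"):
    from gaspnet import SpikeTrain
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate * duration)
    return SpikeTrain(neuron_id, np.sort(rng.uniform(0, duration, n)),
                      (0.0, duration), region)
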