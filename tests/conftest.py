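import numpy as np
import pytest

from ripplecortex import SynthConfig, generate_emg, generate_lfp


@pytest.fixture(scope="session")
def default_session():
    """One default synthetic session shared by read-only tests."""
    cfg = SynthConfig(rng_seed=1)
    lfp, truth = generate_lfp(cfg)
    emg = generate_emg(cfg, truth)
    return {"cfg": cfg, "lfp": lfp, "emg": emg, "truth": truth}


@pytest.fixture(scope="session")
def widefield_session():
    """Session with a wide-field stack (glutamate) and ground truth."""
    from ripplecortex import default_masks, generate_widefield_stack

    cfg = SynthConfig(rng_seed=1)
    lfp, truth = generate_lfp(cfg)
    masks = default_masks()
    stack = generate_widefield_stack(cfg, masks, truth)
    return {"cfg": cfg, "lfp": lfp, "truth": truth, "masks": masks, "stack": stack}


@pytest.fixture
def rng():
    return np.random.default_rng(0)
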