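import numpy as np
import pytest

import bnnvision as bv


@pytest.fixture(scope="session")
def image_set():
    """Small deterministic 3-class fixture set (12 per class)."""
    return bv.generate_synthetic_images(12, side=40, seed=7)


@pytest.fixture(scope="session")
def trained_extractor(image_set):
    """Extractor trained once per test session on the fixture images."""
    train, val = [], []
    for lbl in range(3):
        group = [im for im in image_set if im.label == lbl]
        train += group[:10]
        val += group[10:]
    cfg = bv.ExtractorConfig(seed=1, max_epochs=25)
    return bv.train_feature_extractor(train, val, cfg)


@pytest.fixture(scope="session")
def nine_programs():
    """Nine distinct pulse programs from random binary slot matrices."""
    rng = np.random.default_rng(0)
    programs = []
    while len(programs) < 9:
        bits = (rng.random((8, 10)) < 0.45).astype(int)
        pm = bv.PulseMatrix(bits=bits)
        programs.append(bv.from_binary_matrix(pm))
    return programs


@pytest.fixture(scope="session")
def separable_session(nine_programs):
    """Session with strongly separable stimulation gains (drift off)."""
    nch = 64
    gain = bv.make_gain(nch, 8, seed=3, base=0.05, drive=2.0, p_drive=0.1)
    cfg = bv.SimulatorConfig(n_channels=nch, gain=gain)
    return bv.simulate_session(nine_programs, cfg, seed=11)


@pytest.fixture(scope="session")
def blank_session(nine_programs):
    """Blank-control session: chip without neurons, zero events."""
    cfg = bv.SimulatorConfig(n_channels=64, gain=bv.make_gain(64, 8, seed=3))
    return bv.simulate_session(nine_programs, cfg, seed=11, blank=True)
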