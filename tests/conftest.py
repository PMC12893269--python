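import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from ictalmea.mea_io import ElectrodeLayout, Recording
from ictalmea.synthetic import EventRates, RecordingConfig, generate_recording


@pytest.fixture
def layout() -> ElectrodeLayout:
    return ElectrodeLayout.default()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def small_noise_recording(seed: int = 0, duration_s: float = 2.0, fs: float = 1000.0) -> Recording:
    """A short noise-only recording for I/O and plumbing tests."""
    rng = np.random.default_rng(seed)
    layout = ElectrodeLayout.default()
    data = rng.normal(0, 10, size=(layout.n_recording, int(duration_s * fs))).astype(np.float32)
    return Recording(
        data=data,
        fs_hz=fs,
        layout=layout,
        epochs=[("baseline", 0.0, duration_s / 2), ("treatment", duration_s / 2, duration_s)],
    )


@pytest.fixture(scope="session")
def separated_recording():
    """One 240 s single-source recording, generated and decomposed once per session."""
    from ictalmea.separation import DecomposeConfig, PreprocessConfig, decompose, preprocess

    cfg = RecordingConfig(
        fs_hz=1000.0,
        epochs=[("baseline", 0.0, 240.0)],
        rates=EventRates(ile_per_20min=10, ile_duration_s=20.0, discharge_rate_hz=3.0, n_active_electrodes=21),
    )
    rec, truth = generate_recording(cfg, seed=42)
    model = decompose(
        preprocess(rec, PreprocessConfig(target_fs_hz=250.0)),
        DecomposeConfig(max_ics=8, seed=0),
    )
    return rec, truth, model
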