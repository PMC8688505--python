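import numpy as np
import pytest

from microdyn.containers import EEGRecording
from microdyn.montage import standard_1010_montage
from microdyn.synth import SynthConfig, make_template_maps, simulate_eeg, simulate_label_sequence


@pytest.fixture(scope="session")
def montage63():
    return standard_1010_montage()


@pytest.fixture(scope="session")
def montage64():
    return standard_1010_montage(include_reference=True)


@pytest.fixture(scope="session")
def planted7(montage64):
    """Planted 7-class maps, labels and a noisy recording at 250 Hz."""
    cfg = SynthConfig(
        n_channels=64, fs=250.0, k_true=7, mean_duration_ms=50.0, snr=4.0, seed=11
    )
    maps = make_template_maps(montage64, 7, seed=11)
    labels = simulate_label_sequence(cfg, 30000)
    rec = simulate_eeg(maps, labels, cfg, montage=montage64)
    return cfg, maps, labels, rec


def make_recording(data, fs=250.0, montage=None):
    """Wrap a raw matrix as an EEGRecording with dummy spherical positions."""
    n_ch = data.shape[0]
    if montage is not None:
        return EEGRecording(
            data=data,
            fs=fs,
            channel_labels=list(montage.channel_labels)[:n_ch],
            positions=montage.positions[:n_ch],
        )
    golden = np.pi * (3 - np.sqrt(5))
    idx = np.arange(n_ch)
    z = 1 - 2 * (idx + 0.5) / n_ch
    r = np.sqrt(1 - z**2)
    pos = np.column_stack([r * np.cos(golden * idx), r * np.sin(golden * idx), z])
    return EEGRecording(
        data=data,
        fs=fs,
        channel_labels=[f"E{i}" for i in range(n_ch)],
        positions=pos,
    )
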