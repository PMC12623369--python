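import numpy as np
import pytest

from sleepconn.recording import Recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(data, rate=1000.0, region="S1"):
    """Wrap an array as a single-region Recording with generated labels."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    channels = [f"{region}_{i + 1:02d}" for i in range(data.shape[0])]
    return Recording(data=data, rate=rate, channels=channels,
                     region_of={c: region for c in channels})


def two_region_recording(data_s1, data_rfa, rate=1000.0):
    data_s1 = np.atleast_2d(np.asarray(data_s1, dtype=float))
    data_rfa = np.atleast_2d(np.asarray(data_rfa, dtype=float))
    channels = [f"S1_{i + 1:02d}" for i in range(data_s1.shape[0])] + \
               [f"RFA_{i + 1:02d}" for i in range(data_rfa.shape[0])]
    region_of = {c: c.split("_")[0] for c in channels}
    return Recording(data=np.vstack([data_s1, data_rfa]), rate=rate,
                     channels=channels, region_of=region_of)
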