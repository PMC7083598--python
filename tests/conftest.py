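import logging

import numpy as np
import pandas as pd
import pytest

from salieeg.types import Epochs

logging.disable(logging.WARNING)


def epochs_from_array(data: np.ndarray, fs: float = 256.0,
                      window: tuple[float, float] = (-5.0, 5.0),
                      kind: str = "control",
                      tiers: list[str] | None = None) -> Epochs:
    """Wrap a (trials, channels, samples) array as Epochs with one group."""
    n_tr, n_ch, _ = data.shape
    labels = [f"E{k + 1:03d}" for k in range(n_ch)]
    meta = pd.DataFrame({
        "kind": [kind] * n_tr,
        "tier": tiers if tiers is not None else [""] * n_tr,
        "scene": 0, "subject": 0,
        "onset_time": np.arange(n_tr, dtype=float),
        "event_time": np.nan,
    })
    return Epochs(data, fs, window, meta, labels,
                  {"central": labels[: max(n_ch // 2, 1)], "frontal": []})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
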