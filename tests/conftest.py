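import numpy as np
import pytest

import blurtex as bt

#: seed of the frozen study conditions used across the suite
FROZEN_SEED = 7

#: the nine Gaussian blur levels
SIGMAS = tuple(np.arange(0.0, 4.01, 0.5))


def band_texture(seed: int, size: int = 64, frequency: float = 0.15,
                 orientation: float = 0.6, contrast: float = 1.0) -> np.ndarray:
    """A single seeded oriented band-pass texture for unit tests."""
    return bt.render_texture(
        bt.ClassParams(orientation=orientation, frequency=frequency, contrast=contrast),
        size=size,
        seed=seed,
    )


@pytest.fixture(scope="session")
def frozen_sets():
    """The frozen study conditions: clean train set A and evaluation set B."""
    return bt.default_datasets(seed=FROZEN_SEED)


@pytest.fixture(scope="session")
def train_set(frozen_sets):
    return frozen_sets[0]


@pytest.fixture(scope="session")
def eval_set(frozen_sets):
    return frozen_sets[1]


@pytest.fixture(scope="session")
def eval_scores(eval_set):
    """Lazily cached blur scores of every evaluation image at each sigma level,
    shared between the measure-quality and prediction-error tests."""
    cache: dict[str, dict] = {}

    def get(measure_id: str):
        if measure_id not in cache:
            cache[measure_id] = bt.score_table(eval_set, measure_id, SIGMAS)
        return cache[measure_id]

    return get
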