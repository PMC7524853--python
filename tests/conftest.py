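import numpy as np
import pytest

import migshuttle as ms


@pytest.fixture(scope="session")
def default_schedule():
    return ms.make_schedule()


@pytest.fixture(scope="session")
def short_schedule():
    """A small two-rate grid: 3 pre-shift frames, 5-min post grid to 120."""
    return ms.make_schedule(30, 5, -90, 120, 4)


@pytest.fixture(scope="session")
def rendered_movie():
    """A small noisy rendered movie with ground truth, shared across tests."""
    schedule = ms.make_schedule(30, 15, -60, 240, 4)
    config = ms.preset("wt", "glucose", n_cells=8, seed=5)
    truths = ms.simulate_traces(config, schedule)
    geometry = ms.SceneGeometry(image_size=(224, 224))
    rng = np.random.default_rng(9)
    stack, labels, nuclear_labels = ms.render_movie(truths, geometry, schedule, rng)
    return {
        "schedule": schedule,
        "config": config,
        "truths": truths,
        "stack": stack,
        "labels": labels,
        "nuclear_labels": nuclear_labels,
    }
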