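import numpy as np
import pytest

from budscan import (DivisionTimeline, ScheduleParams, SyntheticCellSpec,
                     render_cell_movie)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def demo_cell():
    """One rendered synthetic cell with a known three-event schedule."""
    timeline = DivisionTimeline(cell_id="demo", event_frames=(10, 20, 30), n_frames=38)
    spec = SyntheticCellSpec(cell_id="demo", rng_seed=42)
    movie, bud_log = render_cell_movie(spec, timeline)
    return movie, bud_log, timeline, spec


@pytest.fixture(scope="session")
def default_schedule():
    return ScheduleParams()
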