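import numpy as np
import pytest

from blastotrace import AreaTrace, CollapseSpec, SceneSpec, make_area_trace, render_frames


def trace_from_areas(areas, zp=None, dt_min=10.0, **kw):
    """Build a minimal AreaTrace from a cavity-area list (helper used across
    the event-detection tests)."""
    areas = np.asarray(areas, dtype=float)
    n = areas.size
    t = np.arange(n) * dt_min / 60.0
    zp = np.full(n, 10 * np.nanmax(areas)) if zp is None else np.asarray(zp, float)
    return AreaTrace(
        time_hpi=t,
        cavity_area=areas,
        zp_interior_area=zp,
        zp_thickness=np.full(n, 10.0),
        frame_interval_min=dt_min,
        **kw,
    )


@pytest.fixture
def toy_trace():
    return trace_from_areas


@pytest.fixture(scope="session")
def collapse_scene():
    return SceneSpec(
        tSB_hpi=100.0,
        tB_hpi=110.0,
        end_hpi=122.0,
        collapses=[CollapseSpec(114.0, 0.30, 1.0)],
    )


@pytest.fixture(scope="session")
def collapse_trace(collapse_scene):
    return make_area_trace(collapse_scene)


@pytest.fixture(scope="session")
def rendered(collapse_scene, collapse_trace):
    trace, _ = collapse_trace
    stack, masks = render_frames(trace, collapse_scene, seed=1)
    return stack, masks
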