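import numpy as np
import pytest

from pulstrans import CrossSection, FlowTrace, VesselSegment


def trace_with_ppi(p: float, mean: float = 1.0) -> FlowTrace:
    """Two-phase trace whose pulsatility index is exactly p (mean positive)."""
    return FlowTrace(np.array([mean * (1 - p / 2), mean * (1 + p / 2)]))


def straight_segment(
    sid: str = "S0",
    n: int = 5,
    start=(0.0, 0.0, 0.0),
    direction=(0.0, 0.0, 1.0),
    step: float = 1.0,
    traces=None,
    area: float = 3.0,
    r_min: float = 1.0,
    r_max: float = 1.0,
) -> VesselSegment:
    """A straight polyline segment with uniform geometry for test scaffolding."""
    start = np.asarray(start, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    if traces is None:
        traces = [trace_with_ppi(0.5) for _ in range(n)]
    cs = [
        CrossSection(
            segment_id=sid,
            order_index=k,
            position=start + k * step * d,
            tangent=d,
            area=area,
            r_min=r_min,
            r_max=r_max,
            trace=traces[k],
        )
        for k in range(n)
    ]
    return VesselSegment(sid, cs)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def assert_segments_equal(a: VesselSegment, b: VesselSegment, rtol=0.0, atol=0.0):
    assert a.segment_id == b.segment_id
    assert len(a) == len(b)
    for ca, cb in zip(a.cross_sections, b.cross_sections):
        assert ca.order_index == cb.order_index
        np.testing.assert_allclose(ca.position, cb.position, rtol=rtol, atol=atol)
        np.testing.assert_allclose(ca.tangent, cb.tangent, rtol=rtol, atol=atol)
        np.testing.assert_allclose(
            [ca.area, ca.r_min, ca.r_max], [cb.area, cb.r_min, cb.r_max],
            rtol=rtol, atol=atol,
        )
        np.testing.assert_allclose(ca.trace.values, cb.trace.values, rtol=rtol, atol=atol)
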