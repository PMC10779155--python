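"""Shared fixtures: geometry and cached scaled-down scenario renders.

Full-scale runs (3.2 us at 50 ps) are reserved for the acceptance suite;
module tests use shorter durations with proportionally scaled event counts,
which preserves every structural property of the generator.
"""

from dataclasses import replace

import pytest

from kperm import default_geometry, get_preset, render_frames, simulate_timeline


@pytest.fixture(scope="session")
def geom():
    return default_geometry()


def scaled_preset(name: str, duration_us: float = 0.4):
    """Preset with duration (and expected events, pro rata) scaled down."""
    p = get_preset(name)
    factor = duration_us / p.duration_us
    return replace(
        p,
        duration_us=duration_us,
        expected_events=round(p.expected_events * factor),
    )


@pytest.fixture(scope="session")
def render_cache(geom):
    """Memoised (preset, seed, interval, duration) -> (timeline, trajectory)."""
    cache = {}

    def build(name: str, seed: int, frame_interval: float = 0.05, duration_us: float = 0.4):
        key = (name, seed, frame_interval, duration_us)
        if key not in cache:
            params = scaled_preset(name, duration_us)
            timeline = simulate_timeline(params, seed)
            traj = render_frames(timeline, geom, frame_interval=frame_interval, seed=seed)
            cache[key] = (timeline, traj)
        return cache[key]

    return build
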