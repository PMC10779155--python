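"""Frame classification, exotic states, mechanisms and density profiles."""

from dataclasses import replace

import numpy as np
import pytest

from kperm import (
    classify_frame,
    classify_mechanism,
    density_profile,
    detect_events,
    exotic_fraction,
    get_preset,
    render_frames,
    simulate_timeline,
)
from kperm.permeation import PermeationEvent
from kperm.sf_model import SiteLabel
from kperm.synthetic import OccupancyTimeline, Segment, REGIME_EXOTIC_S4S3, REGIME_NORMAL
from kperm.trajectory import ROLE_ION, ROLE_WATER, Trajectory, make_topology

from conftest import scaled_preset

SITE_MID = {"S4": 0.155, "S3": 0.465, "S2": 0.775, "S1": 1.085, "S0": 1.395}


def frame_trajectory(*frames):
    """Trajectory from frames given as dicts site -> 'K'/'W' (one particle
    per occupied site; unoccupied sites empty)."""
    n_ions = max(sum(v == "K" for v in f.values()) for f in frames)
    n_wat = max((sum(v == "W" for v in f.values()) for f in frames), default=0)
    rows = [
        dict(name="K", element="K", role=ROLE_ION, resname="K", resid=i + 1, chain="I")
        for i in range(max(n_ions, 1))
    ] + [
        dict(name="O", element="O", role=ROLE_WATER, resname="HOH", resid=i + 1, chain="W")
        for i in range(n_wat)
    ]
    coords = np.full((len(frames), len(rows), 3), -2.0)
    for t, f in enumerate(frames):
        k = 0
        w = max(n_ions, 1)
        for site, kind in f.items():
            z = SITE_MID[site]
            if kind == "K":
                coords[t, k] = [0, 0, z]
                k += 1
            else:
                coords[t, w] = [0, 0, z]
                w += 1
    return Trajectory(
        times=np.arange(len(frames), dtype=float),
        coords=coords,
        topology=make_topology(rows),
    )


class TestClassifyFrame:
    def test_s3_s2_pair_is_exotic(self, geom):
        traj = frame_trajectory({"S3": "K", "S2": "K"})
        state = classify_frame(traj, 0, geom)
        assert state.is_exotic_s3s2 and not state.is_exotic_s4s3

    def test_water_interleaved_pattern_is_not_exotic(self, geom):
        traj = frame_trajectory({"S4": "K", "S3": "W", "S2": "K", "S1": "W"})
        state = classify_frame(traj, 0, geom)
        assert not state.is_exotic
        assert state.content == ("K", "W", "K", "W", "EMPTY")

    def test_empty_filter(self, geom):
        traj = frame_trajectory({})
        state = classify_frame(traj, 0, geom)
        assert state.content == ("EMPTY",) * 5 and not state.is_exotic

    def test_strict_vs_permissive_exotic_definition(self, geom):
        traj = frame_trajectory({"S4": "K", "S3": "K", "S1": "K"})
        assert not classify_frame(traj, 0, geom).is_exotic
        assert classify_frame(traj, 0, geom, permissive=True).is_exotic_s4s3

    def test_atom_order_permutation_invariance(self, geom):
        traj = frame_trajectory({"S4": "K", "S2": "K", "S3": "W"})
        perm = np.array([2, 0, 1])
        shuffled = Trajectory(
            times=traj.times,
            coords=traj.coords[:, perm],
            topology=make_topology(
                [dict(r) for r in traj.topology.iloc[perm].drop(columns="id").to_dict("records")]
            ),
        )
        assert classify_frame(traj, 0, geom).content == classify_frame(shuffled, 0, geom).content


class TestExoticFraction:
    def _render(self, geom, regime, duration=100.0):
        params = replace(get_preset("theta0"), duration_us=duration / 1000.0)
        pattern = (
            ("K", "K", "EMPTY", "EMPTY", "EMPTY")
            if regime == REGIME_EXOTIC_S4S3
            else params.normal_pattern
        )
        tl = OccupancyTimeline(
            duration=duration,
            segments=[Segment(0.0, duration, regime, pattern)],
            events=[],
            seed=0,
            params=params,
        )
        return render_frames(tl, geom, frame_interval=0.5, seed=2)

    def test_all_normal_timeline_has_zero_exotic_fraction(self, geom):
        traj = self._render(geom, REGIME_NORMAL)
        assert exotic_fraction(traj, geom, 5.0).exotic_fraction == 0.0

    def test_all_exotic_timeline_has_unit_fraction(self, geom):
        traj = self._render(geom, REGIME_EXOTIC_S4S3)
        rep = exotic_fraction(traj, geom, 5.0)
        assert rep.exotic_fraction == 1.0
        assert rep.exotic_s4s3_fraction == 1.0

    def test_fractions_sum_to_one(self, geom, render_cache):
        _, traj = render_cache("theta90", 1)
        rep = exotic_fraction(traj, geom, 5.0)
        assert abs(sum(rep.fractions.values()) - 1.0) < 1e-12

    def test_fine_sampling_recovers_exact_time_fraction(self, geom):
        # Riemann-sum property: the frame census converges linearly on the
        # generator's realised exotic time fraction as the interval shrinks
        timeline = simulate_timeline(get_preset("theta90"), 2)
        errs = {}
        for interval in (0.5, 0.1):
            traj = render_frames(timeline, geom, frame_interval=interval, seed=2)
            rep = exotic_fraction(traj, geom, interval=interval)
            errs[interval] = abs(rep.exotic_fraction - timeline.exotic_time_fraction)
        assert errs[0.1] < 1e-3
        assert errs[0.1] < errs[0.5]

    def test_span_shorter_than_interval_rejected(self, geom):
        traj = frame_trajectory({}, {})
        with pytest.raises(ValueError):
            exotic_fraction(traj, geom, interval=5.0)


class TestMechanism:
    def test_contiguous_ion_pairs_classify_direct(self, geom):
        traj = frame_trajectory(
            {"S4": "K", "S3": "K"}, {"S3": "K", "S2": "K"}, {"S2": "K", "S1": "K"}
        )
        ev = PermeationEvent(0, 0.0, 2.0, (), "outward")
        assert classify_mechanism(ev, traj, geom) == "direct"

    def test_water_alternation_classifies_soft(self, geom):
        traj = frame_trajectory(
            {"S4": "K", "S3": "W", "S2": "K"},
            {"S3": "K", "S2": "W", "S1": "K"},
        )
        ev = PermeationEvent(0, 0.0, 1.0, (), "outward")
        assert classify_mechanism(ev, traj, geom) == "soft"

    def test_single_frame_event_is_insufficient(self, geom):
        traj = frame_trajectory({"S4": "K"}, {"S3": "K"})
        ev = PermeationEvent(0, 0.0, 0.4, (), "outward")
        assert classify_mechanism(ev, traj, geom) == "insufficient"

    def test_blind_classification_recovers_generator_labels(self, geom, render_cache):
        hits = total = 0
        for name in ("theta0", "theta90"):
            for seed in (1, 2):
                timeline, traj = render_cache(name, seed)
                detected = [
                    e for e in detect_events(traj, geom) if e.direction == "outward"
                ]
                truth = sorted(timeline.events, key=lambda e: e.t_exit)
                for det, gt in zip(detected, truth):
                    total += 1
                    hits += classify_mechanism(det, traj, geom) == gt.mechanism
        assert total > 100
        assert hits / total >= 0.95


class TestDensity:
    def test_frozen_ion_concentrates_all_mass_in_its_site(self, geom):
        traj = frame_trajectory(*[{"S2": "K"}] * 100)
        prof = density_profile(traj, geom)
        assert prof.site_occupancy["S2"] == pytest.approx(1.0)
        assert prof.mean_sf_ions == pytest.approx(1.0)

    def test_site_integrals_conserve_mean_ion_count(self, geom, render_cache):
        _, traj = render_cache("theta0", 1)
        prof = density_profile(traj, geom)
        assert abs(sum(prof.site_occupancy.values()) - prof.mean_sf_ions) < 1e-12

    def test_s2_occupancy_lower_for_perpendicular_field(self, geom, render_cache):
        # the destabilised filter at theta = 90 deg depletes the S2 site
        _, t0 = render_cache("theta0", 3)
        _, t90 = render_cache("theta90", 3)
        occ0 = density_profile(t0, geom).site_occupancy["S2"]
        occ90 = density_profile(t90, geom).site_occupancy["S2"]
        assert occ90 < occ0

    def test_nonpositive_bin_width_rejected(self, geom):
        traj = frame_trajectory({"S2": "K"})
        with pytest.raises(ValueError):
            density_profile(traj, geom, bin_width=0.0)
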