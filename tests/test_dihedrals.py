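"""Torsion geometry and circular statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation
from scipy.special import i0, i1
from scipy.stats import circmean, circvar, ttest_ind

from kperm import circular_summary, dihedral, get_preset, phi_series, render_frames, simulate_timeline
from kperm.chain import build_chain
from kperm.presets import VonMisesMixture
from kperm.trajectory import ROLE_BACKBONE, Trajectory, make_topology

from conftest import scaled_preset


class TestDihedral:
    @pytest.mark.parametrize(
        "p4,expected",
        [
            ((1, 1, 0), 0.0),  # cis
            ((1, -1, 0), 180.0),  # trans (principal interval is (-180, 180])
        ],
    )
    def test_coplanar_references(self, p4, expected):
        assert dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), p4) == pytest.approx(expected)

    def test_right_handed_quarter_turn(self):
        # oracle: atan2((n1 x n2) . b2_hat, n1 . n2) evaluated by hand
        assert dihedral((0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1)) == pytest.approx(90.0)

    def test_reversal_invariance(self):
        # reversing the atom order flips both plane normals and the central
        # bond, so the signed torsion is unchanged (not negated): the IUPAC
        # angle is well defined no matter which chain end one starts from
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(100, 4, 3))
        fwd = dihedral(pts[:, 0], pts[:, 1], pts[:, 2], pts[:, 3])
        rev = dihedral(pts[:, 3], pts[:, 2], pts[:, 1], pts[:, 0])
        delta = np.abs((fwd - rev + 180) % 360 - 180)
        assert delta.max() < 1e-9

    def test_mirror_antisymmetry(self):
        # a mirror reflection (improper transform) negates the torsion
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(100, 4, 3))
        fwd = dihedral(pts[:, 0], pts[:, 1], pts[:, 2], pts[:, 3])
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        rev = dihedral(mirrored[:, 0], mirrored[:, 1], mirrored[:, 2], mirrored[:, 3])
        delta = np.abs((fwd + rev + 180) % 360 - 180)
        assert delta.max() < 1e-9

    @given(
        seed=st.integers(0, 10_000),
        angles=st.tuples(*[st.floats(-np.pi, np.pi) for _ in range(3)]),
        shift=st.tuples(*[st.floats(-50, 50) for _ in range(3)]),
    )
    @settings(deadline=None, max_examples=80)
    def test_rigid_motion_invariance(self, seed, angles, shift):
        pts = np.random.default_rng(seed).normal(size=(4, 3))
        ref = dihedral(*pts)
        rot = Rotation.from_euler("xyz", angles).as_matrix()
        moved = pts @ rot.T + np.asarray(shift)
        delta = abs((dihedral(*moved) - ref + 180) % 360 - 180)
        assert delta < 1e-9

    def test_collinear_points_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))


class TestCircularSummary:
    def test_constant_series_is_fully_concentrated(self):
        s = circular_summary(np.full(100, -80.0))
        assert s.resultant_length == pytest.approx(1.0)
        assert s.variance == pytest.approx(0.0)
        assert s.mean_deg == pytest.approx(-80.0)

    def test_uniform_grid_has_zero_resultant(self):
        angles = np.linspace(-180.0, 180.0, 3600, endpoint=False) + 0.05
        assert circular_summary(angles).resultant_length < 1e-10

    def test_von_mises_resultant_matches_bessel_ratio(self):
        kappa = 40.0
        draws = VonMisesMixture.single(-80.0, kappa).sample(
            np.random.default_rng(1), 100_000
        )
        oracle = i1(kappa) / i0(kappa)
        assert circular_summary(draws).resultant_length == pytest.approx(
            oracle, abs=0.005
        )

    def test_agrees_with_scipy_circular_statistics(self):
        rng = np.random.default_rng(2)
        angles = np.degrees(rng.vonmises(0.5, 3.0, size=5000))
        s = circular_summary(angles)
        assert s.mean_deg == pytest.approx(
            np.degrees(circmean(np.radians(angles), high=np.pi, low=-np.pi)), abs=1e-8
        )
        assert s.variance == pytest.approx(
            circvar(np.radians(angles), high=np.pi, low=-np.pi), abs=1e-8
        )

    def test_histogram_is_a_probability_distribution(self):
        rng = np.random.default_rng(3)
        s = circular_summary(np.degrees(rng.vonmises(0, 1, size=1000)), bin_width=5.0)
        assert s.hist.sum() == pytest.approx(1.0)
        assert len(s.hist) == 72

    def test_too_few_angles_rejected(self):
        with pytest.raises(ValueError):
            circular_summary(np.array([10.0]))


class TestPhiSeries:
    def _chain_trajectory(self, phi):
        block = build_chain(phi)  # (n_frames, n_res, 4, 3)
        n_frames, n_res = phi.shape
        rows = []
        names = ("N", "CA", "C", "O")
        for resid in range(74, 74 + n_res):
            for name in names:
                rows.append(
                    dict(
                        name=name,
                        element=name[0],
                        role=ROLE_BACKBONE,
                        resname="GLY",
                        resid=resid,
                        chain="A",
                    )
                )
        return Trajectory(
            times=np.arange(n_frames, dtype=float),
            coords=block.reshape(n_frames, n_res * 4, 3),
            topology=make_topology(rows),
        )

    def test_recovers_the_generating_torsions(self):
        rng = np.random.default_rng(4)
        phi = rng.uniform(-179.9, 180.0, size=(50, 7))
        traj = self._chain_trajectory(phi)
        for resid in range(75, 81):
            series = phi_series(traj, resid, "A")
            delta = np.abs((series.angles - phi[:, resid - 74] + 180) % 360 - 180)
            assert delta.max() < 1e-6

    def test_missing_residue_raises_lookup_error(self):
        traj = self._chain_trajectory(np.zeros((3, 7)) + 60.0)
        with pytest.raises(KeyError, match="chain 'B'"):
            phi_series(traj, "GLY77", "B")


class TestPresetDistributions:
    @pytest.fixture(scope="class")
    def summaries(self, geom):
        """Per-preset, per-seed circular summaries from short renders."""
        out = {}
        for name in ("theta0", "theta30", "theta90"):
            per_seed = []
            for seed in range(10):
                params = scaled_preset(name, 0.1)
                tl = simulate_timeline(params, seed)
                traj = render_frames(tl, geom, frame_interval=0.5, seed=seed)
                rec = {}
                for res in ("THR75", "VAL76", "GLY77"):
                    angles = np.concatenate(
                        [phi_series(traj, res, ch).angles for ch in "ABCD"]
                    )
                    rec[res] = circular_summary(angles)
                per_seed.append(rec)
            out[name] = per_seed
        return out

    def test_gly77_stability_ranks_with_field_angle(self, summaries):
        # the axial field stabilises GLY77; the perpendicular field lets its
        # phi wander: variance theta0 < theta30 < theta90 on 10-seed means
        mean_var = {
            name: np.mean([rec["GLY77"].variance for rec in recs])
            for name, recs in summaries.items()
        }
        assert mean_var["theta0"] < mean_var["theta30"] < mean_var["theta90"]

    def test_inner_site_residues_unaffected_by_field_angle(self, summaries):
        # THR75/VAL76 (S4, S3 cages) are statistically indistinguishable
        # across field orientations (two-sample test on R_bar, alpha = 0.01)
        for res in ("THR75", "VAL76"):
            a = [rec[res].resultant_length for rec in summaries["theta0"]]
            b = [rec[res].resultant_length for rec in summaries["theta90"]]
            assert ttest_ind(a, b).pvalue > 0.01
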