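"""Exposure, contact-count, end-to-end and tensile-force observables."""

import numpy as np
import pytest

import shearfold as sf
from shearfold import units
from shearfold.dynamics import TrajectoryRecord
from shearfold.model import HBondContact, NativeHBondSet
from shearfold.observables import (coordination_series, half_drop_time,
                                   site_indices)
from shearfold.synthetic import pull_toy_sheet, _extended_positions


def _traj(frames, dt=0.1):
    frames = np.asarray(frames, float)
    return TrajectoryRecord(times_ns=dt * (1 + np.arange(len(frames))),
                            positions=frames)


class TestCoordinationNumber:
    def test_isolated_site(self):
        frame = np.array([[0.0, 0, 0], [50.0, 0, 0], [60.0, 0, 0]])
        assert sf.coordination_number(frame, np.array([0]),
                                      np.array([1, 2]), 10.0) == 0

    @pytest.mark.parametrize("d,expected", [(9.9, 1), (10.1, 0)])
    def test_strict_boundary(self, d, expected):
        frame = np.array([[0.0, 0, 0], [d, 0, 0]])
        assert sf.coordination_number(frame, np.array([0]),
                                      np.array([1]), 10.0) == expected

    def test_matches_brute_force(self, rng):
        frame = rng.uniform(0, 25, (80, 3))
        site = np.array([0, 1])
        counted = np.arange(2, 80)
        got = sf.coordination_number(frame, site, counted, 10.0)
        brute = sum(1 for c in counted
                    if min(np.linalg.norm(frame[c] - frame[s]) for s in site)
                    < 10.0)
        assert got == brute

    def test_rigid_motion_invariance(self, rng, toy_sheet):
        crit = toy_sheet.criterion
        site, counted = site_indices(toy_sheet.model, crit)
        x = toy_sheet.model.positions()
        n0 = sf.coordination_number(x, site, counted, crit.probe_radius)
        # random rotation + translation
        q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        x2 = x @ q.T + rng.normal(0, 50, 3)
        assert sf.coordination_number(x2, site, counted,
                                      crit.probe_radius) == n0


class TestExposureTime:
    def _coord_traj(self, toy_sheet, seq):
        """Trajectory alternating native and extended frames per seq."""
        native = toy_sheet.model.positions()
        extended = _extended_positions(toy_sheet.model)
        frames = [native if s else extended for s in seq]
        return _traj(frames)

    def test_first_crossing_found(self, toy_sheet):
        traj = self._coord_traj(toy_sheet, [1, 1, 0, 0])
        status, t = sf.exposure_time(traj, toy_sheet.model,
                                     toy_sheet.criterion)
        assert status == "unfolded"
        assert t == pytest.approx(traj.times_ns[2])

    def test_censored_when_never_exposed(self, toy_sheet):
        traj = self._coord_traj(toy_sheet, [1, 1, 1])
        status, t = sf.exposure_time(traj, toy_sheet.model,
                                     toy_sheet.criterion)
        assert status == "censored"
        assert t == pytest.approx(traj.times_ns[-1])

    def test_zero_threshold_always_censored(self, toy_sheet):
        import dataclasses
        crit = dataclasses.replace(toy_sheet.criterion, threshold=0.0)
        traj = self._coord_traj(toy_sheet, [0, 0])
        assert sf.exposure_time(traj, toy_sheet.model, crit)[0] == "censored"

    def test_monotone_in_threshold(self, toy_sheet, toy_sheet_ff):
        import dataclasses
        traj = pull_toy_sheet(toy_sheet, 700.0, seed=2, n_steps=15_000,
                              ff=toy_sheet_ff)
        times = []
        for thr in (4.0, 8.0, 12.0):
            crit = dataclasses.replace(toy_sheet.criterion, threshold=thr)
            times.append(sf.exposure_time(traj, toy_sheet.model, crit)[1])
        # larger threshold → unfolding criterion met no later
        assert times[0] >= times[1] >= times[2]


class TestContactCount:
    def _single(self, d_ref=3.0):
        return NativeHBondSet(contacts=[HBondContact(
            donor_h=0, acceptor_o=1, donor_res=1, acceptor_res=5,
            d_ref=d_ref)], smoothing_a=0.5, cutoff=d_ref)

    def test_half_at_native_distance(self):
        hb = self._single(3.0)
        frame = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        assert sf.contact_count(frame, hb) == pytest.approx(0.5)

    def test_value_at_minus_four_angstrom(self):
        # d − d_ref = −4 Å, a = 0.5 → 1/(1 + e⁻²) ≈ 0.8808
        hb = self._single(6.0)
        frame = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert sf.contact_count(frame, hb) == pytest.approx(
            1.0 / (1.0 + np.exp(-2.0)), abs=1e-10)

    def test_logistic_limits(self):
        hb = self._single(3.0)
        far = np.array([[0.0, 0, 0], [500.0, 0, 0]])
        assert sf.contact_count(far, hb) < 1e-10
        near = np.array([[0.0, 0, 0], [1e-9, 0, 0]])
        assert sf.contact_count(near, hb) >= 0.817

    def test_matches_brute_force(self, rng, toy_sheet):
        frame = toy_sheet.model.positions() + rng.normal(0, 1.0, (60, 3))
        got = sf.contact_count(frame, toy_sheet.hbonds)
        a = toy_sheet.hbonds.smoothing_a
        brute = sum(
            1.0 / (1.0 + np.exp(a * (np.linalg.norm(frame[c.donor_h]
                                                    - frame[c.acceptor_o])
                                     - c.d_ref)))
            for c in toy_sheet.hbonds.contacts)
        assert got == pytest.approx(brute, rel=1e-12)

    def test_monotone_under_uniform_expansion(self, toy_sheet):
        x = toy_sheet.model.positions()
        values = [sf.contact_count(x * s, toy_sheet.hbonds)
                  for s in (1.0, 1.3, 1.8, 2.5)]
        assert all(b < a for a, b in zip(values, values[1:]))


class TestStrandPairContacts:
    def test_native_frame_at_maximum(self, toy_sheet):
        traj = _traj([toy_sheet.model.positions()] * 2)
        series = sf.strand_pair_contacts(traj, toy_sheet.hbonds)
        assert set(series) == {"β1β4", "β4β5", "β5β6"}
        for cs in series.values():
            # every native contact contributes its logistic half value
            assert cs.contacts[0] == pytest.approx(0.5 * cs.n_catalogued)

    def test_extended_frame_nearly_zero(self, toy_sheet):
        ext = _extended_positions(toy_sheet.model)
        traj = _traj([ext] * 2)
        series = sf.strand_pair_contacts(traj, toy_sheet.hbonds)
        for cs in series.values():
            assert cs.contacts[0] < 0.05 * (0.5 * cs.n_catalogued)

    def test_unlabeled_set_rejected(self, toy_sheet):
        hb = NativeHBondSet(contacts=[HBondContact(0, 1, 1, 5, 2.5, "other")])
        traj = _traj([toy_sheet.model.positions()])
        with pytest.raises(ValueError, match="no strand-pair labels"):
            sf.strand_pair_contacts(traj, hb)


class TestEndToEnd:
    def test_two_beads(self):
        frame = np.array([[0.0, 0, 0], [3.0, 4.0, 0]])
        assert sf.end_to_end(frame, np.array([0, 1])) == pytest.approx(5.0)

    def test_extended_chain_contour(self):
        n = 177
        frame = np.stack([3.8 * np.arange(n), np.zeros(n), np.zeros(n)], 1)
        assert sf.end_to_end(frame, np.arange(n)) == pytest.approx(668.8)

    def test_axis_projection(self):
        frame = np.array([[0.0, 0, 0], [3.0, 4.0, 0.0]])
        assert sf.end_to_end(frame, np.array([0, 1]), axis=2) == 0.0


class TestMovingAverageAndTensileForce:
    def test_matches_brute_force_windowed_mean(self, rng):
        x = rng.normal(size=200)
        w = 11
        got = sf.moving_average(x, w)
        for i in (0, 3, 57, 199):
            lo, hi = max(0, i - w // 2), min(200, i + w // 2 + 1)
            assert got[i] == pytest.approx(x[lo:hi].mean())

    def test_boxcar_of_step_series(self):
        x = np.r_[np.zeros(50), np.ones(50)]
        out = sf.moving_average(x, 11)
        # analytic boxcar convolution: linear ramp across the step
        assert out[44] == 0.0
        assert out[55] == 1.0
        assert out[49] == pytest.approx(5 / 11)

    def test_constant_stretch_gives_conversion_constant(self, toy_sheet):
        from shearfold.synthetic import make_three_blob_construct
        model = make_three_blob_construct()
        bond = model.bonds[model.terminal_bonds[0]]
        x = model.positions()
        # displace so the instrumented bond is stretched by exactly 1 Å
        vec = x[bond.j] - x[bond.i]
        d = np.linalg.norm(vec)
        stretch_frames = []
        for _ in range(8):
            f = x.copy()
            shift = (d + 1.0) / d
            # move everything beyond the bond end along the bond axis
            f[bond.j] = f[bond.i] + vec * shift
            stretch_frames.append(f)
        traj = _traj(stretch_frames, dt=0.5)
        ts = sf.tensile_force_series(traj, model, terminal_bond=0,
                                     window_ns=1.2)
        # constant 1 Å stretch: f = k · 1 Å = k · 69.48 pN at all times,
        # and the moving average equals the instantaneous series
        expected = bond.k * units.KCAL_PER_MOL_ANG_TO_PN
        np.testing.assert_allclose(ts.force_pN, expected, rtol=1e-9)
        np.testing.assert_allclose(ts.force_avg_pN, expected, rtol=1e-9)

    def test_zero_at_native_length(self):
        from shearfold.synthetic import make_three_blob_construct
        model = make_three_blob_construct()
        traj = _traj([model.positions()] * 4, dt=0.5)
        ts = sf.tensile_force_series(traj, model, window_ns=1.0)
        np.testing.assert_allclose(ts.force_pN, 0.0, atol=1e-9)

    def test_window_too_short_rejected(self):
        from shearfold.synthetic import make_three_blob_construct
        model = make_three_blob_construct()
        traj = _traj([model.positions()] * 4, dt=2.0)
        with pytest.raises(ValueError, match="window"):
            sf.tensile_force_series(traj, model, window_ns=2.0)


class TestExposureScatter:
    def test_frame_count_conserved(self, toy_sheet, toy_sheet_ff):
        traj = pull_toy_sheet(toy_sheet, 600.0, seed=4, n_steps=5000,
                              ff=toy_sheet_ff)
        df, frac = sf.exposure_scatter(
            traj, toy_sheet.model, toy_sheet.criterion,
            recognition_residues=(17, 19))
        assert len(df) == traj.n_frames
        assert 0.0 <= frac <= 1.0

    def test_identical_sites_give_diagonal(self, toy_sheet):
        site = toy_sheet.criterion.site_residue_local
        traj = _traj([toy_sheet.model.positions()] * 3)
        df, frac = sf.exposure_scatter(
            traj, toy_sheet.model, toy_sheet.criterion,
            recognition_residues=(site, site))
        np.testing.assert_array_equal(df.coord_cleavage, df.coord_recognition)
        assert frac == 0.0


def test_half_drop_time_reference_is_initial_value(toy_sheet):
    from shearfold.observables import ContactSeries
    cs = ContactSeries("β5β6", np.array([0.1, 0.2, 0.3, 0.4]),
                       np.array([2.0, 1.5, 0.9, 0.2]), 4)
    assert half_drop_time(cs) == pytest.approx(0.3)
    cs_flat = ContactSeries("β5β6", np.array([0.1, 0.2]),
                            np.array([2.0, 1.9]), 4)
    assert half_drop_time(cs_flat) == np.inf
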