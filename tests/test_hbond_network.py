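import numpy as np
import pytest

from trimd.hbond_network import (
    ContactTimeSeries,
    HBondCriteria,
    classify_bound,
    contact_series,
    detect_frame_hbonds,
    lifetime_fraction,
    persistent_network,
)
from trimd.structure_io import Atom, Topology
from trimd.structure_io.model import Frame
from trimd.synthetic_data import ToyTrimerConfig, make_toy_trimer

from .conftest import random_rotation


def donor_acceptor_frame(d_no: float, angle_deg: float):
    """N-H donor (residue 1) and O acceptor (residue 2) with set geometry."""
    n = np.array([0.0, 0.0, 0.0])
    o = np.array([d_no, 0.0, 0.0])
    # place H at 1.0 A from N so that angle N-H-O equals angle_deg
    theta = np.deg2rad(180.0 - angle_deg)

    def hpos(t):
        h = n + np.array([np.cos(t), np.sin(t), 0.0])
        v1, v2 = n - h, o - h
        ang = np.degrees(
            np.arccos(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
        )
        return h, ang

    from scipy.optimize import brentq

    if angle_deg >= 179.99:
        h = n + np.array([1.0, 0.0, 0.0])
    else:
        t = brentq(lambda t: hpos(t)[1] - angle_deg, 1e-6, np.pi / 2)
        h, ang = hpos(t)
        assert abs(ang - angle_deg) < 1e-6
    atoms = [
        Atom(serial=1, name="N", element="N", residue_name="ALA", residue_seq=1, chain_id="A"),
        Atom(serial=2, name="H", element="H", residue_name="ALA", residue_seq=1, chain_id="A"),
        Atom(serial=3, name="O", element="O", residue_name="GLY", residue_seq=2, chain_id="B"),
    ]
    return Topology(atoms), Frame(np.vstack([n, h, o]))


class TestDetect:
    def test_inside_both_thresholds(self):
        top, frame = donor_acceptor_frame(2.8, 170.0)
        found = detect_frame_hbonds(frame, top)
        assert (0, 1, 2) in found

    def test_distance_fails(self):
        top, frame = donor_acceptor_frame(3.2, 180.0)
        assert detect_frame_hbonds(frame, top) == set()

    def test_angle_fails(self):
        top, frame = donor_acceptor_frame(2.8, 120.0)
        assert detect_frame_hbonds(frame, top) == set()

    def test_boundary_angle_detected(self):
        top, frame = donor_acceptor_frame(2.8, 135.0)
        assert (0, 1, 2) in detect_frame_hbonds(frame, top)

    def test_same_residue_excluded(self):
        atoms = [
            Atom(serial=1, name="N", element="N", residue_name="ALA", residue_seq=1, chain_id="A"),
            Atom(serial=2, name="H", element="H", residue_name="ALA", residue_seq=1, chain_id="A"),
            Atom(serial=3, name="O", element="O", residue_name="ALA", residue_seq=1, chain_id="A"),
        ]
        frame = Frame(np.array([[0, 0, 0], [1, 0, 0], [2.8, 0, 0]], dtype=float))
        assert detect_frame_hbonds(frame, Topology(atoms)) == set()

    def test_rigid_motion_invariance(self):
        top, frame = donor_acceptor_frame(2.8, 170.0)
        rng = np.random.default_rng(0)
        for _ in range(5):
            moved = Frame(frame.coords @ random_rotation(rng).T + rng.normal(size=3) * 30)
            assert detect_frame_hbonds(moved, top) == detect_frame_hbonds(frame, top)

    def test_no_hydrogen_mode_distance_only(self):
        atoms = [
            Atom(serial=1, name="N", element="N", residue_name="ALA", residue_seq=1, chain_id="A"),
            Atom(serial=2, name="O", element="O", residue_name="GLY", residue_seq=2, chain_id="B"),
        ]
        frame = Frame(np.array([[0, 0, 0], [2.8, 0, 0]], dtype=float))
        found = detect_frame_hbonds(frame, Topology(atoms))
        assert (0, None, 1) in found and (1, None, 0) in found


class TestLifetimeAndBound:
    def make_series(self, mask, dt=0.1):
        return ContactTimeSeries(
            donor=0, acceptor=1, mask=np.asarray(mask, dtype=bool),
            frame_interval_ns=dt, times_ns=np.arange(len(mask)) * dt,
        )

    def test_fraction_300_of_400(self):
        s = self.make_series([True] * 300 + [False] * 100)
        assert lifetime_fraction(s) == 0.75

    def test_fraction_2240_of_4000(self):
        s = self.make_series([True] * 2240 + [False] * 1760)
        assert lifetime_fraction(s) == pytest.approx(0.56)

    def test_all_false(self):
        assert lifetime_fraction(self.make_series([False] * 10)) == 0.0

    def test_complement_identity(self):
        rng = np.random.default_rng(1)
        mask = rng.random(200) < 0.3
        s = self.make_series(mask)
        sc = self.make_series(~mask)
        assert lifetime_fraction(s) + lifetime_fraction(sc) == 1.0

    def test_bound_12_frames(self):
        rec = classify_bound(self.make_series([False] * 3 + [True] * 12 + [False] * 5))
        assert rec.is_bound
        assert len(rec.bound_episodes) == 1

    def test_alternating_unbound(self):
        rec = classify_bound(self.make_series([True, False] * 20))
        assert not rec.is_bound
        assert all(rec.transient_flags)

    def test_mixed_episodes(self):
        mask = [True] * 5 + [False] * 10 + [True] * 30 + [False] * 5
        rec = classify_bound(self.make_series(mask))
        assert rec.is_bound
        assert rec.transient_flags == [True, False]
        start, end = rec.bound_episodes[1]
        assert end - start == pytest.approx(3.0)


class TestOnSynthetic:
    def test_schedule_recovery_exact(self, toy_trimer):
        traj, manifest = toy_trimer
        for label, (donor, acceptor) in manifest.contact_atoms.items():
            series = contact_series(traj, (donor, acceptor))
            np.testing.assert_array_equal(series.mask, manifest.contact_schedules[label])

    def test_never_close_all_false(self, toy_trimer):
        traj, manifest = toy_trimer
        donors = [d for d, _ in manifest.contact_atoms.values()]
        acceptors = [a for _, a in manifest.contact_atoms.values()]
        # cross-station pair is ~18 A apart, never bonded
        series = contact_series(traj, (donors[0], acceptors[1]))
        assert not series.mask.any()

    def test_persistent_network_recovers_planted(self):
        cfg = ToyTrimerConfig(n_frames=80, contact_fractions=(0.9, 0.7, 0.2, 0.1), seed=3)
        traj, manifest = make_toy_trimer(cfg)
        records = persistent_network(traj, chain_pairs={("B", "C")})
        found = {(r.donor, r.acceptor) for r in records}
        expected = {
            manifest.contact_atoms[l]
            for l, sched in manifest.contact_schedules.items()
            if sched.mean() > 0.5
        }
        assert found == expected
        fracs = [r.lifetime_fraction for r in records]
        assert fracs == sorted(fracs, reverse=True)

    def test_threshold_zero_keeps_all_nonzero(self):
        cfg = ToyTrimerConfig(n_frames=50, contact_fractions=(0.9, 0.4), seed=4)
        traj, manifest = make_toy_trimer(cfg)
        records = persistent_network(traj, threshold=0.0, chain_pairs={("B", "C")})
        assert {(r.donor, r.acceptor) for r in records} == set(
            manifest.contact_atoms.values()
        )

    def test_any_threshold_between_bands(self, toy_trimer):
        traj, manifest = toy_trimer
        fracs = {l: s.mean() for l, s in manifest.contact_schedules.items()}
        lo = max(f for f in fracs.values() if f <= 0.5)
        hi = min(f for f in fracs.values() if f > 0.5)
        for thr in (lo + 0.01, (lo + hi) / 2, hi - 0.01):
            records = persistent_network(traj, threshold=thr, chain_pairs={("B", "C")})
            expected = {
                manifest.contact_atoms[l] for l, f in fracs.items() if f > thr
            }
            assert {(r.donor, r.acceptor) for r in records} == expected

    def test_static_frame_constant_mask(self, toy_trimer):
        traj, manifest = toy_trimer
        label, (donor, acceptor) = next(iter(manifest.contact_atoms.items()))
        on_frames = np.nonzero(manifest.contact_schedules[label])[0][:5]
        series = contact_series(traj, (donor, acceptor), window=on_frames)
        assert series.mask.all()

    def test_empty_window_errors(self, toy_trimer):
        traj, _ = toy_trimer
        with pytest.raises(ValueError, match="empty"):
            contact_series(traj, (0, 1), window=np.array([], dtype=int))


class TestCriteriaValidation:
    def test_bad_distance(self):
        with pytest.raises(ValueError):
            HBondCriteria(max_da_distance_A=-1.0)

    def test_bad_angle(self):
        with pytest.raises(ValueError):
            HBondCriteria(min_dha_angle_deg=200.0)
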