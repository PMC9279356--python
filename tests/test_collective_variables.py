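import numpy as np
import pytest

from trimd.collective_variables import (
    CVSeries,
    cdk4_activity_call,
    cluster_frames,
    com_distance_series,
    detect_ejection,
    dissociation_rate,
    time_to_dissociation,
)
from trimd.structure_io import Atom, Topology, Trajectory
from trimd.structure_io.model import Frame
from trimd.synthetic_data import ToyTrimerConfig, make_toy_trimer

from .conftest import random_rotation


def atom(serial, name, element, resseq, chain):
    return Atom(serial=serial, name=name, element=element, residue_name="ALA",
                residue_seq=resseq, chain_id=chain)


class TestCOMDistance:
    def make_traj(self, coords, elements):
        atoms = [
            atom(i + 1, f"X{i}", el, i + 1, "A" if i < len(elements) - 1 else "B")
            for i, el in enumerate(elements)
        ]
        return Trajectory(Topology(atoms), [Frame(np.asarray(coords, dtype=float))])

    def test_two_single_atoms(self):
        traj = self.make_traj([[0, 0, 0], [2, 0, 0]], ["C", "C"])
        s = com_distance_series(traj, "resid 1", "resid 2")
        assert s.values_A[0] == pytest.approx(2.0)

    def test_equal_mass_pair_centroid(self):
        traj = self.make_traj([[0, 0, 0], [2, 0, 0], [1, 0, 4]], ["C", "C", "C"])
        s = com_distance_series(traj, "resid 1-2", "resid 3")
        assert s.values_A[0] == pytest.approx(4.0)

    def test_mass_weighting(self):
        # C (12.011) and H (1.008) at x=0 and x=13.019 -> COM at x ~ 1.008
        traj = self.make_traj([[0, 0, 0], [13.019, 0, 0], [0, 0, 0]], ["C", "H", "O"])
        s = com_distance_series(traj, "resid 1-2", "resid 3")
        com_x = 13.019 * 1.008 / (12.011 + 1.008)
        assert s.values_A[0] == pytest.approx(com_x, abs=1e-6)
        s_uw = com_distance_series(traj, "resid 1-2", "resid 3", mass_weighted=False)
        assert s_uw.values_A[0] == pytest.approx(13.019 / 2)

    def test_rigid_motion_invariance(self, toy_trimer):
        traj, manifest = toy_trimer
        base = com_distance_series(traj, manifest.helix_selection, manifest.pocket_selection)
        rng = np.random.default_rng(0)
        R = random_rotation(rng)
        shift = rng.normal(size=3) * 25
        moved = Trajectory(
            traj.topology,
            [Frame(f.coords @ R.T + shift, time_ns=f.time_ns) for f in traj.frames],
            frame_interval_ns=traj.frame_interval_ns,
        )
        s2 = com_distance_series(moved, manifest.helix_selection, manifest.pocket_selection)
        np.testing.assert_allclose(s2.values_A, base.values_A, atol=1e-9)

    def test_empty_selection_errors(self, toy_trimer):
        traj, _ = toy_trimer
        with pytest.raises(ValueError, match="empty"):
            com_distance_series(traj, "chain Z", "chain A")


def series_from(values, dt=0.1):
    values = np.asarray(values, dtype=float)
    return CVSeries(name="t", times_ns=np.arange(len(values)) * dt, values_A=values)


class TestDetectEjection:
    def test_flat_no_events(self):
        ev = detect_ejection(series_from(np.full(200, 10.0)), baseline_window_ns=5)
        assert ev.events == []

    def test_step_at_150ns(self):
        values = np.concatenate([np.full(1500, 10.0), np.full(500, 18.0)])
        ev = detect_ejection(series_from(values), baseline_window_ns=100.0)
        assert len(ev.events) == 1
        assert ev.events[0].onset_ns == pytest.approx(150.0)
        assert ev.events[0].sustained

    def test_transient_excursion_not_sustained_flag(self):
        values = np.concatenate(
            [np.full(100, 10.0), np.full(80, 18.0), np.full(100, 10.0)]
        )
        ev = detect_ejection(series_from(values), baseline_window_ns=5, sustain_ns=5)
        assert len(ev.events) == 1
        assert not ev.events[0].sustained

    def test_short_blip_ignored(self):
        values = np.full(200, 10.0)
        values[100:110] = 18.0  # 1 ns < sustain 5 ns
        ev = detect_ejection(series_from(values), baseline_window_ns=5, sustain_ns=5)
        assert ev.events == []

    def test_monotone_in_delta(self):
        rng = np.random.default_rng(2)
        values = np.concatenate([np.full(300, 10.0), np.full(700, 17.0)])
        values += rng.normal(0, 0.3, size=1000)
        onsets = []
        for delta in (2.0, 4.0, 6.0):
            ev = detect_ejection(series_from(values), baseline_window_ns=10, delta_A=delta)
            onsets.append(ev.time_to_first_ns)
        finite = [o for o in onsets if o is not None]
        assert finite == sorted(finite)

    def test_empty_baseline_errors(self):
        with pytest.raises(ValueError, match="baseline"):
            detect_ejection(series_from(np.ones(10)), baseline_window_ns=-1.0)

    def test_planted_ejection_recovery(self):
        cfg = ToyTrimerConfig(n_frames=120, ejection_frame=70, seed=5)
        traj, manifest = make_toy_trimer(cfg)
        cv = com_distance_series(traj, manifest.helix_selection, manifest.pocket_selection)
        ev = detect_ejection(cv, baseline_window_ns=3.0, delta_A=5.0, sustain_ns=2.0)
        assert len(ev.events) == 1
        onset_frame = int(round(ev.events[0].onset_ns / cfg.frame_interval_ns))
        assert abs(onset_frame - manifest.ejection_frame) <= 1


class TestDissociation:
    def test_no_events_none(self):
        from trimd.collective_variables import EventSet

        assert time_to_dissociation(EventSet()) is None
        assert dissociation_rate(EventSet()) is None

    def test_sustained_onset(self):
        values = np.concatenate([np.full(1500, 10.0), np.full(500, 18.0)])
        ev = detect_ejection(series_from(values), baseline_window_ns=100.0)
        assert time_to_dissociation(ev) == pytest.approx(150.0)

    def test_rate_ordering(self):
        fast = np.concatenate([np.full(500, 10.0), np.full(1500, 18.0)])  # 50 ns
        slow = np.concatenate([np.full(2000, 10.0), np.full(500, 18.0)])  # 200 ns
        rf = dissociation_rate(detect_ejection(series_from(fast), baseline_window_ns=20))
        rs = dissociation_rate(detect_ejection(series_from(slow), baseline_window_ns=20))
        assert rf > rs


class TestActivityCall:
    def paired(self, anchor, site):
        return series_from(anchor), series_from(site)

    def test_inactive(self):
        a, s = self.paired(np.full(400, 8.0), np.full(400, 12.0))
        call = cdk4_activity_call(a, s)
        assert call.state == "inactive"
        assert call.residue74_bound_start and call.residue74_bound_end

    def test_partially_active_transition(self):
        anchor = np.concatenate([np.full(150, 8.0), np.full(250, 20.0)])
        a, s = self.paired(anchor, np.full(400, 12.0))
        call = cdk4_activity_call(a, s)
        assert call.state == "partially_active"
        assert call.residue74_transition

    def test_active_unbound_throughout(self):
        a, s = self.paired(np.full(400, 30.0), np.full(400, 12.0))
        call = cdk4_activity_call(a, s, bound_threshold_A=12.0)
        assert call.state == "active"

    def test_site_open_overrides_inactive(self):
        site = np.concatenate([np.full(100, 10.0), np.full(300, 20.0)])
        a, s = self.paired(np.full(400, 8.0), site)
        call = cdk4_activity_call(a, s)
        assert call.state == "partially_active"
        assert call.site_open

    def test_decision_table_total(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            anchor = rng.choice([8.0, 30.0], size=100)
            site = rng.choice([10.0, 25.0], size=100)
            call = cdk4_activity_call(
                series_from(anchor), series_from(site),
                bound_threshold_A=15.0, open_threshold_A=18.0,
            )
            assert call.state in {"inactive", "partially_active", "active"}

    def test_window_mismatch_errors(self):
        a = series_from(np.ones(100))
        b = series_from(np.ones(50))
        with pytest.raises(ValueError, match="window"):
            cdk4_activity_call(a, b)


class TestClusterFrames:
    def two_state_traj(self, n_frames=60, noise=0.0, split=0.5, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.normal(size=(6, 3)) * 3
        alt = base + np.array([5.0, 0.0, 0.0]) * (rng.random(size=(6, 1)) > 0.5)
        atoms = [atom(i + 1, "CA", "C", i + 1, "A") for i in range(6)]
        labels = (np.arange(n_frames) % int(round(1 / (1 - split)))) == 0 if split != 0.5 else (np.arange(n_frames) % 2 == 0)
        frames, truth = [], []
        for k in range(n_frames):
            state = labels[k]
            conf = base if state else alt
            frames.append(
                Frame(conf + rng.normal(0, noise, size=conf.shape), time_ns=0.1 * k)
            )
            truth.append(int(state))
        return Trajectory(Topology(atoms), frames), np.array(truth)

    def test_perfect_two_state_recovery(self):
        traj, truth = self.two_state_traj()
        labels, centroids = cluster_frames(traj, "name CA", k=2, seed=0)
        acc = max((labels == truth).mean(), (labels != truth).mean())
        assert acc == 1.0
        assert len(centroids) == 2

    def test_noisy_70_30_recovery(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(6, 3)) * 3
        # internal rearrangement (half the atoms move): a whole-selection
        # rigid shift would be removed by the superposition step
        alt = base.copy()
        alt[:3] += np.array([0.0, 5.0, 0.0])
        atoms = [atom(i + 1, "CA", "C", i + 1, "A") for i in range(6)]
        truth = (rng.random(100) < 0.3).astype(int)
        frames = [
            Frame((alt if t else base) + rng.normal(0, 0.2, size=(6, 3)), time_ns=0.1 * k)
            for k, t in enumerate(truth)
        ]
        traj = Trajectory(Topology(atoms), frames)
        labels, _ = cluster_frames(traj, "name CA", k=2, seed=0)
        acc = max((labels == truth).mean(), (labels != truth).mean())
        assert acc >= 0.95

    def test_identical_frames_k1(self, ideal_alpha_helix):
        top, coords = ideal_alpha_helix
        traj = Trajectory(top, [Frame(coords.copy(), time_ns=0.1 * k) for k in range(5)])
        labels, centroids = cluster_frames(traj, "name CA", k=1, seed=0)
        assert set(labels) == {0}
        assert centroids == [0]

    def test_deterministic_given_seed(self):
        traj, _ = self.two_state_traj(noise=0.2, seed=2)
        l1, c1 = cluster_frames(traj, "name CA", k=2, seed=7)
        l2, c2 = cluster_frames(traj, "name CA", k=2, seed=7)
        np.testing.assert_array_equal(l1, l2)
        assert c1 == c2

    def test_k_too_large(self):
        traj, _ = self.two_state_traj(n_frames=12)
        with pytest.raises(ValueError, match="exceeds"):
            cluster_frames(traj, "name CA", k=20, seed=0)
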