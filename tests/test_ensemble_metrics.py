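"""Ensemble analytics: RMSD series, averages, representative frame, RMSF."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import thermoscreen as ts
from thermoscreen.geometry import HBondCriteria
from thermoscreen.synthetic import EnsembleSpec

from .oracles import quaternion_superpose_rmsd


def constant_ensemble(structure, n=5):
    return ts.Ensemble(structure, np.repeat(structure.all_coords()[None], n, axis=0))


class TestPerFrameRmsd:
    def test_identical_frames_give_zero(self, helix12):
        ens = constant_ensemble(helix12)
        assert ts.per_frame_rmsd(ens, helix12).values == pytest.approx(0.0, abs=1e-6)

    def test_rigid_transforms_give_zero(self, helix12, rng):
        base = helix12.all_coords()
        frames = np.stack([
            base @ Rotation.random(random_state=i).as_matrix().T + rng.normal(size=3)
            for i in range(6)
        ])
        ens = ts.Ensemble(helix12, frames)
        assert ts.per_frame_rmsd(ens, helix12).values == pytest.approx(0.0, abs=1e-6)

    def test_matches_independent_superposition_oracle(self, noisy_ensemble, helix12):
        series = ts.per_frame_rmsd(noisy_ensemble, helix12, selection=("CA",))
        ca = helix12.atom_indices(("CA",))
        ref = helix12.all_coords()[ca]
        for f in range(noisy_ensemble.n_frames):
            expected = quaternion_superpose_rmsd(noisy_ensemble.frames[f][ca], ref)
            assert series.values[f] == pytest.approx(expected, abs=1e-8)

    def test_tiny_selection_rejected(self, helix12):
        ens = constant_ensemble(helix12)
        with pytest.raises(ValueError, match="3"):
            ts.per_frame_rmsd(ens, helix12, selection=("OXT",))


class TestAverageStructure:
    def test_constant_ensemble_returns_itself(self, helix12):
        avg = ts.average_structure(constant_ensemble(helix12))
        assert np.allclose(avg.all_coords(), helix12.all_coords(), atol=1e-10)

    def test_two_scaled_frames_average_to_midpoint(self, helix12):
        # centering on the Ca centroid makes the optimal superposition of a
        # uniformly scaled copy the identity, so the aligned mean is the
        # exact coordinate midpoint
        ca = helix12.atom_indices(("CA",))
        base = helix12.all_coords() - helix12.all_coords()[ca].mean(axis=0)
        frames = np.stack([base, 1.1 * base])
        ens = ts.Ensemble(helix12.with_coords(base), frames)
        avg = ts.average_structure(ens, window=[0, 1])
        assert np.allclose(avg.all_coords(), 1.05 * base, atol=1e-8)

    def test_rigid_motion_is_removed_before_averaging(self, helix12, rng):
        base = helix12.all_coords()
        frames = np.stack([
            base @ Rotation.random(random_state=i).as_matrix().T + rng.normal(size=3)
            for i in range(6)
        ])
        avg = ts.average_structure(ts.Ensemble(helix12, frames), window=range(6))
        # every frame is the same conformation, so the average is it too
        # (up to the arbitrary overall orientation of the alignment target)
        ca = helix12.atom_indices(("CA",))
        assert ts.kabsch_superpose(avg.all_coords()[ca], base[ca]).rmsd < 1e-6

    def test_noisy_average_converges_to_the_base_structure(self, noisy_ensemble, helix12):
        # sigma=0.2 A over 30 frames: standard error ~0.037 A per coordinate
        avg = ts.average_structure(noisy_ensemble, window=range(30))
        ca = helix12.atom_indices(("CA",))
        rmsd = ts.kabsch_superpose(avg.all_coords()[ca],
                                   helix12.all_coords()[ca]).rmsd
        assert rmsd < 0.1

    def test_empty_window_rejected(self, helix12):
        with pytest.raises(ValueError, match="empty"):
            ts.average_structure(constant_ensemble(helix12), window=[])


class TestRepresentativeFrame:
    def test_single_frame_window(self, noisy_ensemble):
        assert ts.representative_frame(noisy_ensemble, window=[7]) == 7

    def test_planted_average_frame_wins(self, helix12):
        ens = ts.make_ensemble(helix12, EnsembleSpec(10, {}, 0.3, seed=1))
        avg = ts.average_structure(ens, range(10))
        frames = ens.frames.copy()
        frames[3] = avg.all_coords()
        planted = ts.Ensemble(helix12, frames)
        assert ts.representative_frame(planted, range(10)) == 3

    def test_matches_exhaustive_scan(self, noisy_ensemble):
        window = list(range(noisy_ensemble.n_frames))
        avg = ts.average_structure(noisy_ensemble, window)
        ca = noisy_ensemble.topology.atom_indices(("CA",))
        avg_ca = avg.all_coords()[ca]
        rmsds = [
            quaternion_superpose_rmsd(noisy_ensemble.frames[f][ca], avg_ca)
            for f in window
        ]
        assert ts.representative_frame(noisy_ensemble, window) == int(np.argmin(rmsds))


class TestRmsf:
    def test_constant_ensemble_is_rigid(self, helix12):
        prof = ts.per_residue_rmsf(constant_ensemble(helix12), window=range(5))
        assert prof.as_array() == pytest.approx(0.0, abs=1e-10)

    def test_gaussian_noise_recovers_sigma_sqrt3(self):
        # a mid-chain residue with iid sigma=0.5 A noise per coordinate:
        # analytic RMSF limit is sigma*sqrt(3) ~ 0.866 A
        helix = ts.make_helix(60)
        ens = ts.make_ensemble(helix, EnsembleSpec(2000, {30: 0.5}, 0.0, seed=3))
        prof = ts.per_residue_rmsf(ens, window=range(2000))
        vals = {k.resnum: v for k, v in prof.values.items()}
        assert vals[30] == pytest.approx(0.5 * np.sqrt(3), rel=0.05)
        assert max(v for k, v in vals.items() if k != 30) < 0.1

    def test_planted_sigma_ratio_recovered(self):
        helix = ts.make_helix(40)
        ens = ts.make_ensemble(helix, EnsembleSpec(2000, {10: 0.6, 30: 0.2},
                                                   0.05, seed=7))
        prof = ts.per_residue_rmsf(ens, window=range(2000))
        vals = {k.resnum: v for k, v in prof.values.items()}
        assert vals[10] / vals[30] == pytest.approx(3.0, rel=0.10)

    def test_invariant_under_common_rigid_transform(self, noisy_ensemble, rng):
        prof = ts.per_residue_rmsf(noisy_ensemble, window=range(30))
        R = Rotation.random(random_state=9).as_matrix()
        t = rng.normal(size=3)
        moved = ts.Ensemble(noisy_ensemble.topology,
                            noisy_ensemble.frames @ R.T + t)
        prof2 = ts.per_residue_rmsf(moved, window=range(30))
        assert np.allclose(prof.as_array(), prof2.as_array(), atol=1e-8)

    def test_needs_two_frames(self, helix12):
        with pytest.raises(ValueError, match="2 frames"):
            ts.per_residue_rmsf(constant_ensemble(helix12, n=1), window=[0])

    def test_tsv_round_trip(self, tmp_path, noisy_ensemble):
        prof = ts.per_residue_rmsf(noisy_ensemble)
        p = tmp_path / "rmsf.tsv"
        prof.to_tsv(p)
        back = ts.FlexibilityProfile.from_tsv(p, temperature_label=300.0)
        assert back.residues == prof.residues
        assert np.allclose(back.as_array(), prof.as_array(), atol=1e-6)


class TestPerResidueRmsd:
    def test_identical_ensembles_give_zero(self, noisy_ensemble):
        d = ts.per_residue_rmsd(noisy_ensemble, noisy_ensemble)
        assert max(d.values()) == pytest.approx(0.0, abs=1e-9)

    def test_planted_displacement_recovered(self, helix40):
        # displace one mid-chain residue by 2 A in every frame of b;
        # anchored by the other 39 residues the shift survives superposition
        base = helix40.all_coords()
        n = 40
        frames_a = np.repeat(base[None], 4, axis=0)
        shifted = base.copy()
        target = helix40.residues[20].key
        idx = [i for i, (k, _) in enumerate(helix40.iter_atoms()) if k == target]
        shifted[idx] += np.array([0.0, 0.0, 2.0])
        frames_b = np.repeat(shifted[None], 4, axis=0)
        d = ts.per_residue_rmsd(ts.Ensemble(helix40, frames_a),
                                ts.Ensemble(helix40, frames_b))
        assert d[target] == pytest.approx(2.0, rel=0.05)
        others = [v for k, v in d.items() if k != target]
        assert max(others) < 0.2

    def test_matches_brute_force_on_averages(self, helix12):
        a = ts.make_ensemble(helix12, EnsembleSpec(8, {}, 0.15, seed=1))
        b = ts.make_ensemble(helix12, EnsembleSpec(8, {}, 0.15, seed=2))
        d = ts.per_residue_rmsd(a, b, window=range(8))
        avg_a = ts.average_structure(a, range(8))
        avg_b = ts.average_structure(b, range(8))
        ca = helix12.atom_indices(("CA",))
        a_ca, b_ca = avg_a.all_coords()[ca], avg_b.all_coords()[ca]
        sup = ts.kabsch_superpose(b_ca, a_ca)
        expected = np.linalg.norm(a_ca - sup.apply(b_ca), axis=1)
        assert np.allclose(list(d.values()), expected, atol=1e-9)

    def test_topology_mismatch_rejected(self, helix12, helix40):
        a = constant_ensemble(helix12)
        b = constant_ensemble(helix40)
        with pytest.raises(ValueError, match="topolog"):
            ts.per_residue_rmsd(a, b)


class TestHBondSeries:
    def test_static_helix_gives_constant_series(self, helix12):
        ens = constant_ensemble(helix12, n=10)
        series = ts.hbond_series(ens)
        assert (series.counts == 12 - 4).all()
        assert series.mean == 12 - 4

    def test_alternating_geometry_halves_the_mean(self, helix12):
        base = helix12.all_coords()
        # pull every second frame apart along z so no bonds survive
        stretched = base + np.array([0.0, 0.0, 50.0]) * (base[:, [2]] > base[:, 2].mean())
        frames = np.stack([base, stretched] * 3)
        series = ts.hbond_series(ts.Ensemble(helix12, frames))
        ideal = series.counts[0]
        assert series.counts[1] < ideal
        assert series.mean == pytest.approx((series.counts[0] + series.counts[1]) / 2)

    def test_counts_match_per_frame_detection(self, noisy_ensemble):
        series = ts.hbond_series(noisy_ensemble, HBondCriteria())
        for f in range(noisy_ensemble.n_frames):
            frame = noisy_ensemble.frame_structure(f)
            assert series.counts[f] == len(ts.detect_hbonds(frame, HBondCriteria()))

    def test_mean_within_count_range(self, noisy_ensemble):
        series = ts.hbond_series(noisy_ensemble)
        assert series.counts.min() <= series.mean <= series.counts.max()


class TestDefaultWindow:
    def test_last_75_percent(self):
        assert ts.last_fraction_window(20) == list(range(5, 20))
        assert ts.last_fraction_window(2) == [0, 1]
        assert ts.last_fraction_window(1) == [0]
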