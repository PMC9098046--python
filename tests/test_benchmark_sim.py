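import numpy as np
import pytest

from topodyn.benchmark_sim import (
    BenchmarkConfig, PerturbationSpec, choose_radius, elasticnet_baseline,
    make_benchmark_dataset, pca_baseline, perturb_roi, rmsf_baseline, roc_auc,
    cone_detection_scores, surface_window_roi, synth_ensemble, run_benchmark,
)
from topodyn.roi_testing import ROISpec

from conftest import make_frame


class TestSynthEnsemble:
    def test_zero_noise_gives_identical_frames(self):
        frames = synth_ensemble(n_atoms=60, n_frames=4, thermal_sigma=0.0, seed=0)
        for f in frames[1:]:
            np.testing.assert_allclose(f.coords, frames[0].coords, atol=1e-8)

    def test_consecutive_spacing_protein_like(self):
        frames, base = synth_ensemble(n_atoms=80, n_frames=1, thermal_sigma=0.0,
                                      seed=1, return_base=True)
        d = np.linalg.norm(np.diff(base, axis=0), axis=1)
        assert d.min() >= 3.0 and d.max() <= 4.6

    def test_rmsf_matches_thermal_sigma(self):
        frames = synth_ensemble(n_atoms=80, n_frames=500, thermal_sigma=0.4,
                                tau=0.0, seed=2)
        coords = np.array([f.coords for f in frames])
        rmsf = np.sqrt((((coords - coords.mean(0)) ** 2).sum(2)).mean(0))
        assert np.all(np.abs(rmsf - 0.4) / 0.4 < 0.10)

    def test_seed_reproducible(self):
        a = synth_ensemble(n_atoms=60, n_frames=3, seed=3)
        b = synth_ensemble(n_atoms=60, n_frames=3, seed=3)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.coords, fb.coords)

    def test_temporal_correlation_decays(self):
        times = np.arange(40, dtype=float)
        frames = synth_ensemble(n_atoms=60, n_frames=40, thermal_sigma=0.5,
                                tau=2.0, times=times, seed=4)
        coords = np.array([f.coords for f in frames])
        dev = coords - coords.mean(0)
        flat = dev.reshape(40, -1)
        lag1 = np.mean([np.corrcoef(flat[i], flat[i + 1])[0, 1] for i in range(39)])
        assert lag1 > 0.3  # exp(-1/2) ~ 0.61 minus estimation noise


class TestPerturbROI:
    @pytest.fixture
    def frames(self):
        return synth_ensemble(n_atoms=60, n_frames=5, thermal_sigma=0.3, seed=5)

    def test_constant_mode_exact_vector(self, frames):
        roi = ROISpec(residue_ranges=[(10, 19)])
        spec = PerturbationSpec(mode="constant", magnitude=1.0, roi=roi, seed=6)
        out = perturb_roi(frames, spec)
        idx = roi.atom_indices(frames[0])
        for before, after in zip(frames, out):
            np.testing.assert_allclose(
                after.coords[idx] - before.coords[idx], 1.0)

    def test_spherical_mode_exact_length(self, frames):
        roi = ROISpec(residue_ranges=[(10, 19)])
        spec = PerturbationSpec(mode="spherical", magnitude=2.0, roi=roi, seed=7)
        out = perturb_roi(frames, spec)
        idx = roi.atom_indices(frames[0])
        for before, after in zip(frames, out):
            lengths = np.linalg.norm(after.coords[idx] - before.coords[idx], axis=1)
            np.testing.assert_allclose(lengths, 2.0, atol=1e-12)

    def test_spherical_redrawn_per_frame(self, frames):
        roi = ROISpec(residue_ranges=[(10, 19)])
        spec = PerturbationSpec(mode="spherical", magnitude=1.0, roi=roi, seed=8)
        out = perturb_roi(frames, spec)
        idx = roi.atom_indices(frames[0])
        d0 = out[0].coords[idx] - frames[0].coords[idx]
        d1 = out[1].coords[idx] - frames[1].coords[idx]
        assert not np.allclose(d0, d1)

    def test_non_roi_untouched(self, frames):
        roi = ROISpec(residue_ranges=[(10, 19)])
        spec = PerturbationSpec(mode="spherical", magnitude=2.0, roi=roi, seed=9)
        out = perturb_roi(frames, spec)
        idx = roi.atom_indices(frames[0])
        other = np.setdiff1d(np.arange(60), idx)
        for before, after in zip(frames, out):
            np.testing.assert_array_equal(after.coords[other], before.coords[other])

    def test_total_length_mode(self, frames):
        roi = ROISpec(residue_ranges=[(1, 5)])
        spec = PerturbationSpec(mode="constant", magnitude=1.5, roi=roi, seed=0,
                                total_length_mode=True)
        out = perturb_roi(frames, spec)
        idx = roi.atom_indices(frames[0])
        disp = out[0].coords[idx] - frames[0].coords[idx]
        np.testing.assert_allclose(np.linalg.norm(disp, axis=1), 1.5)


@pytest.fixture(scope="module")
def ensembles():
    frames = synth_ensemble(n_atoms=60, n_frames=40, thermal_sigma=0.3,
                            tau=0.0, seed=10)
    return frames[:20], frames[20:]


class TestBaselines:
    def test_rmsf_identical_classes_zero(self, ensembles):
        a, _ = ensembles
        np.testing.assert_allclose(rmsf_baseline(a, a), 0.0, atol=1e-12)

    def test_rmsf_exact_shift_invariance(self, ensembles):
        a, _ = ensembles
        shifted = [f.with_coords(f.coords + np.array([2.0, -1.0, 3.0])) for f in a]
        np.testing.assert_allclose(rmsf_baseline(a, shifted), 0.0, atol=1e-10)

    def test_rmsf_matches_brute_force(self, ensembles):
        a, b = ensembles
        scores = rmsf_baseline(a, b)
        ca = np.array([f.coords for f in a])
        cb = np.array([f.coords for f in b])
        for atom in range(0, 60, 7):
            ra = np.sqrt(np.mean(np.sum((ca[:, atom] - ca[:, atom].mean(0)) ** 2, axis=1)))
            rb = np.sqrt(np.mean(np.sum((cb[:, atom] - cb[:, atom].mean(0)) ** 2, axis=1)))
            assert np.isclose(scores[atom], abs(ra - rb))

    def test_rmsf_unequal_atom_counts_rejected(self, ensembles):
        a, b = ensembles
        small = [f.select(np.arange(f.n_atoms) < 30) for f in b]
        with pytest.raises(ValueError, match="correspondence"):
            rmsf_baseline(a, small)

    def test_pca_identical_classes_zero(self, ensembles):
        a, _ = ensembles
        np.testing.assert_allclose(pca_baseline(a, a), 0.0, atol=1e-8)

    def test_pca_matches_svd_recomputation(self, ensembles):
        a, b = ensembles
        scores = pca_baseline(a, b, n_components=5)
        vecs = []
        for frames in (a, b):
            X = np.array([f.coords for f in frames]).reshape(len(frames), -1)
            Xc = X - X.mean(0)
            U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
            # deterministic sign convention: largest-|loading| entry positive
            signs = np.sign(Vt[np.arange(Vt.shape[0]),
                               np.abs(Vt).argmax(axis=1)])
            Vt = Vt * signs[:, None]
            vecs.append((s[:5, None] * Vt[:5]).sum(axis=0))
        expected = np.linalg.norm((vecs[0] - vecs[1]).reshape(-1, 3), axis=1)
        np.testing.assert_allclose(scores, expected, atol=1e-8)

    def test_elasticnet_huge_shift_single_atom_top_score(self):
        frames = synth_ensemble(n_atoms=60, n_frames=60, thermal_sigma=0.2,
                                tau=0.0, seed=11)
        a, b_raw = frames[:30], frames[30:]
        b = [f.with_coords(f.coords + np.eye(60)[7][:, None] * np.array([50.0, 50, 50]))
             for f in b_raw]
        scores = elasticnet_baseline(a, b, seed=12)
        assert np.argmax(scores) == 7

    def test_elasticnet_coefficient_regrouping(self):
        # grouping of coefficients per atom equals explicit reshape-and-sum
        frames = synth_ensemble(n_atoms=60, n_frames=30, thermal_sigma=0.2,
                                tau=0.0, seed=13)
        a, b = frames[:15], frames[15:]
        scores = elasticnet_baseline(a, b, seed=14)
        assert scores.shape == (60,)
        assert np.all(scores >= 0)


class TestDetectionScores:
    def _design(self, gamma, fmap, c, d):
        class Design:
            pass

        class Dirs:
            pass

        design = Design()
        design.atom_feature_maps = [np.asarray(fmap)]
        dirs = Dirs()
        dirs.c, dirs.d = c, d
        design.direction_set = dirs
        return design

    def test_single_cone_is_min_over_directions(self):
        gamma = np.array([0.4, 0.1, 0.9, 0.3])
        fmap = np.array([[0, 2], [1, 3]])
        design = self._design(gamma, fmap, c=1, d=2)
        scores = cone_detection_scores(design, gamma)
        np.testing.assert_allclose(scores, [0.4, 0.1])

    def test_atom_with_global_max_in_a_cone(self):
        gamma = np.array([0.05, 0.9, 0.9, 0.05])
        fmap = np.array([[1, 2, 0, 3]])
        design = self._design(gamma, fmap, c=2, d=2)
        scores = cone_detection_scores(design, gamma)
        assert scores[0] == pytest.approx(0.9)

    def test_threshold_sweep_equivalence(self):
        rng = np.random.default_rng(15)
        c, d, J = 3, 4, 60
        gamma = rng.uniform(size=J)
        fmap = rng.integers(0, J, size=(40, c * d))
        design = self._design(gamma, fmap, c=c, d=d)
        closed = cone_detection_scores(design, gamma)
        for T in np.sort(np.unique(gamma))[::4]:
            selected = gamma >= T
            detected = np.zeros(40, dtype=bool)
            for k in range(c):
                cone_cols = fmap[:, k * d:(k + 1) * d]
                detected |= selected[cone_cols].all(axis=1)
            np.testing.assert_array_equal(detected, closed >= T)


class TestROCAUC:
    def test_perfect_ordering(self):
        truth = np.r_[np.ones(5), np.zeros(5)].astype(bool)
        assert roc_auc(np.r_[np.arange(5, 10), np.arange(5)], truth).auc == 1.0

    def test_reversed_ordering(self):
        truth = np.r_[np.ones(5), np.zeros(5)].astype(bool)
        assert roc_auc(np.r_[np.arange(5), np.arange(5, 10)], truth).auc == 0.0

    def test_constant_scores_half(self):
        truth = np.r_[np.ones(3), np.zeros(4)].astype(bool)
        assert roc_auc(np.ones(7), truth).auc == 0.5

    def test_matches_mann_whitney_oracle(self):
        rng = np.random.default_rng(16)
        scores = rng.integers(0, 20, size=200).astype(float)  # many ties
        truth = rng.uniform(size=200) < 0.3
        res = roc_auc(scores, truth)
        pos = scores[truth]
        neg = scores[~truth]
        wins = (pos[:, None] > neg[None]).sum() + 0.5 * (pos[:, None] == neg[None]).sum()
        assert np.isclose(res.auc, wins / (len(pos) * len(neg)))

    def test_curve_monotone(self):
        rng = np.random.default_rng(17)
        res = roc_auc(rng.normal(size=100), rng.uniform(size=100) < 0.4)
        assert np.all(np.diff(res.tpr) >= 0)
        assert np.all(np.diff(res.fpr) >= 0)

    def test_degenerate_truth_raises(self):
        with pytest.raises(ValueError):
            roc_auc(np.arange(5.0), np.ones(5, dtype=bool))


class TestBenchmarkOrchestration:
    def test_dataset_arithmetic_and_labels(self):
        cfg = BenchmarkConfig(n_atoms=60, n_frames_per_class=10,
                              offsets=(0.0, 0.1), seed=18)
        fa, fb, truth, base, series = make_benchmark_dataset(
            cfg, mode="constant", magnitude=1.0)
        assert len(fa) == len(fb) == 10
        assert truth.sum() == cfg.roi_size
        assert all(f.class_label == 0 for f in fa)
        assert all(f.class_label == 1 for f in fb)
        # class B sampled half a nanosecond after class A
        assert fb[0].frame_time - fa[0].frame_time == pytest.approx(0.5)

    def test_surface_window_is_contiguous(self):
        _, base = synth_ensemble(n_atoms=100, n_frames=1, thermal_sigma=0.0,
                                 seed=19, return_base=True)
        roi = surface_window_roi(base, size=20)
        (lo, hi), = roi.residue_ranges
        assert hi - lo + 1 == 20

    def test_choose_radius_hits_degree_band(self):
        _, base = synth_ensemble(n_atoms=100, n_frames=1, thermal_sigma=0.0,
                                 seed=20, return_base=True)
        from scipy.spatial import cKDTree

        r = choose_radius(base, (4.0, 20.0))
        deg = 2 * len(cKDTree(base).query_pairs(r)) / 100
        assert 4.0 <= deg <= 20.0

    def test_zero_signal_benchmark_near_half(self):
        # tiny no-signal run: RMSF on an unperturbed-magnitude-epsilon setup
        cfg = BenchmarkConfig(n_atoms=60, n_frames_per_class=20,
                              offsets=(0.0,), scenarios=(("spherical", 1e-6),),
                              methods=("rmsf",), seed=21)
        table = run_benchmark(cfg)
        assert abs(table.iloc[0]["auc"] - 0.5) < 0.25

    def test_same_seed_identical_table(self):
        cfg = BenchmarkConfig(n_atoms=60, n_frames_per_class=10,
                              offsets=(0.0,), scenarios=(("constant", 1.0),),
                              methods=("rmsf", "pca"), seed=22)
        t1 = run_benchmark(cfg)
        t2 = run_benchmark(cfg)
        assert t1.equals(t2)
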