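"""KNFST: kernel evaluation, null-space conditions, open-set behavior."""

import numpy as np
import pytest
import scipy.linalg

import tocsynd as t
from tocsynd.knfst import KernelConfig, fit_knfst, kernel_matrix, knfst_distances

from conftest import dataset_from_peaks


def projected_scatters(model, dataset):
    """Within- and between-class scatter of the projected training data
    (independent recomputation, not reusing fit internals)."""
    P = model.project(dataset.features)
    y = np.array([model.classes.index(l) for l in dataset.labels])
    means = np.stack([P[y == i].mean(axis=0) for i in range(len(model.classes))])
    D = P - means[y]
    mu = means - means.mean(axis=0)
    return D.T @ D, mu.T @ mu


class TestKernelMatrix:
    def test_rbf_self_similarity_is_one(self):
        cfg = KernelConfig(bandwidth=50.0)
        k = kernel_matrix([[100.0, 200.0]], [[100.0, 200.0]], cfg)
        assert k[0, 0] == pytest.approx(1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1000, size=(3, 2))
        k = kernel_matrix(X, X, KernelConfig(bandwidth=100.0))
        assert np.max(np.abs(k - k.T)) < 1e-12

    def test_rbf_matches_scalar_formula(self):
        sigma, d = 40.0, 75.0
        k = kernel_matrix([[0.0, 0.0]], [[d, 0.0]], KernelConfig(bandwidth=sigma))
        assert k[0, 0] == pytest.approx(np.exp(-(d**2) / (2 * sigma**2)))

    def test_positive_semidefinite(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 2000, size=(20, 2))
        k = kernel_matrix(X, X, KernelConfig(bandwidth=200.0))
        assert scipy.linalg.eigvalsh(k).min() > -1e-10

    def test_dimensionality_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimensionality"):
            kernel_matrix(np.ones((2, 2)), np.ones((2, 3)),
                          KernelConfig(bandwidth=1.0))


class TestFitKnfst:
    def test_well_separated_classes_collapse(self, separated_synthetic):
        train, _ = separated_synthetic
        ds = dataset_from_peaks(train)
        model = fit_knfst(ds)
        Sw, Sb = projected_scatters(model, ds)
        ratio = scipy.linalg.eigvalsh(Sw)[-1] / scipy.linalg.eigvalsh(Sb)[-1]
        assert ratio <= 1e-8

    def test_two_singleton_classes(self):
        ds = t.Dataset(
            features=np.array([[100.0, 100.0], [600.0, 600.0]]),
            labels=np.array(["a", "b"], dtype=object),
        )
        model = fit_knfst(ds, KernelConfig(bandwidth=100.0))
        assert model.n_dims == 1
        assert np.linalg.norm(model.targets[0] - model.targets[1]) > 0

    def test_real_training_set_structure(self, train_4000):
        model = fit_knfst(train_4000)
        assert len(model.classes) == 24
        assert model.targets.shape[0] == 24
        assert model.n_dims <= 23

    def test_single_class_rejected(self):
        ds = t.Dataset(
            features=np.array([[1.0, 1.0], [2.0, 2.0]]),
            labels=np.array(["a", "a"], dtype=object),
        )
        with pytest.raises(ValueError, match="2 training classes"):
            fit_knfst(ds)

    def test_fit_deterministic(self, separated_synthetic):
        ds = dataset_from_peaks(separated_synthetic[0])
        m1, m2 = fit_knfst(ds), fit_knfst(ds)
        assert np.array_equal(m1.projection, m2.projection)
        assert np.array_equal(m1.targets, m2.targets)


class TestDistances:
    def test_training_instance_near_own_target(self, separated_synthetic):
        train, _ = separated_synthetic
        ds = dataset_from_peaks(train)
        model = fit_knfst(ds)
        d = knfst_distances(model, ds.features[0])
        own = model.classes.index(ds.labels[0])
        assert d[own] <= 1e-4 * model.target_scale
        assert np.argmin(d) == own

    def test_small_perturbation_keeps_class(self, train_4000):
        model = fit_knfst(train_4000)
        # a known multiplet shifted by 5 Hz stays nearest to its own class
        x = np.array([752.0 + 5.0, 494.0 - 5.0])  # Leu multiplet
        d = knfst_distances(model, x)
        assert model.classes[int(np.argmin(d))] == "Leu"

    def test_distance_vector_shape_and_sign(self, separated_synthetic):
        ds = dataset_from_peaks(separated_synthetic[0])
        model = fit_knfst(ds)
        d = knfst_distances(model, np.array([3000.0, 3000.0]))
        assert d.shape == (len(model.classes),)
        assert np.all(d >= 0)

    def test_permutation_invariance(self, separated_synthetic):
        ds = dataset_from_peaks(separated_synthetic[0])
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(ds))
        ds_p = t.Dataset(features=ds.features[perm], labels=ds.labels[perm])
        q = np.array([[1500.0, 2500.0], [4000.0, 1000.0]])
        d1 = np.sort(fit_knfst(ds).distances(q), axis=1)
        d2 = np.sort(fit_knfst(ds_p).distances(q), axis=1)
        assert np.max(np.abs(d1 - d2)) < 1e-8 * fit_knfst(ds).target_scale

    def test_relabeling_invariance(self, separated_synthetic):
        ds = dataset_from_peaks(separated_synthetic[0])
        renamed = t.Dataset(
            features=ds.features,
            labels=np.array([f"zz_{l}" for l in ds.labels], dtype=object),
        )
        q = np.array([[2000.0, 2000.0]])
        d1 = np.sort(fit_knfst(ds).distances(q).ravel())
        d2 = np.sort(fit_knfst(renamed).distances(q).ravel())
        assert np.max(np.abs(d1 - d2)) < 1e-8 * fit_knfst(ds).target_scale

    def test_novel_classes_score_above_known_validation(self, separated_synthetic):
        train, test = separated_synthetic
        ds = dataset_from_peaks(train)
        model = fit_knfst(ds)
        val = t.augment_noise(
            train, 20, t.AugmentationConfig(noise_sigma=10.0, seed=8)
        )
        val_scores, _ = model.score_samples(val.features)
        novel_X = np.array(
            [[p.f2, p.f1] for p in test.peaks if p.metabolite.startswith("novel")]
        )
        novel_scores, _ = model.score_samples(novel_X)
        assert novel_scores.min() > np.percentile(val_scores, 99)


class TestNullSpaceOracle:
    @pytest.mark.parametrize("seed", range(20))
    def test_null_space_conditions_on_random_problems(self, seed):
        """Projected within-class scatter vanishes relative to the
        between-class scatter, and every instance sits on its target."""
        rng = np.random.default_rng(seed)
        n_known = int(rng.integers(3, 7))
        train, _ = t.make_synthetic_table(
            n_known, 0, int(rng.integers(2, 6)),
            min_separation=400.0, seed=seed + 100,
        )
        ds = dataset_from_peaks(train)
        model = fit_knfst(ds)
        Sw, Sb = projected_scatters(model, ds)
        assert scipy.linalg.eigvalsh(Sw)[-1] <= 1e-8 * scipy.linalg.eigvalsh(Sb)[-1]
        P = model.project(ds.features)
        y = np.array([model.classes.index(l) for l in ds.labels])
        dist = np.linalg.norm(P - model.targets[y], axis=1)
        assert dist.max() <= 1e-4 * model.target_scale
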