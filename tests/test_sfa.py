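"""SFA core: expansion, slowness measure, constraint suite, eigenproblem
oracle, and the ICA rotation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import linalg, stats

import placesim as ps
from placesim.sfa import SFATrainer, expanded_dim


def sfa_oracle(data, k):
    """Independent brute-force SFA: solve the dense generalized eigenproblem
    A v = λ B v with A the forward-difference covariance and B the signal
    covariance, normalizing outputs to unit variance w.r.t. B."""
    x = data - data.mean(axis=0)
    t = x.shape[0]
    b = (x.T @ x) / t
    d = np.diff(x, axis=0)
    a = (d.T @ d) / (t - 1)
    evals, vecs = linalg.eigh(a, b)
    return x @ vecs[:, :k], evals[:k]


class TestQuadraticExpand:
    def test_reference_vector(self):
        out = ps.quadratic_expand(np.array([1.0, 2.0]))
        assert np.array_equal(out, [1, 2, 1, 2, 4])

    def test_zero_maps_to_zero(self):
        assert np.all(ps.quadratic_expand(np.zeros(4)) == 0)

    @given(st.integers(1, 12))
    def test_dimension_formula(self, n):
        x = np.arange(1.0, n + 1)
        out = ps.quadratic_expand(x)
        assert out.shape == (expanded_dim(n, "quadratic"),)
        assert out.shape == (n + n * (n + 1) // 2,)

    @given(st.integers(2, 8))
    def test_matches_naive_enumeration(self, n):
        rng = np.random.default_rng(n)
        x = rng.normal(size=n)
        naive = list(x) + [x[i] * x[j] for i in range(n) for j in range(i, n)]
        assert np.allclose(ps.quadratic_expand(x), naive)


class TestDeltaValue:
    def test_constant_signal_is_perfectly_slow(self):
        assert ps.delta_value(np.ones(100)) == 0.0

    def test_constant_with_normalize_rejected(self):
        with pytest.raises(ps.ParameterError):
            ps.delta_value(np.ones(100), normalize=True)

    def test_sampled_sinusoid_closed_form(self):
        # unit-variance sinusoid: Δ = 4 sin²(π/T) ≈ (2π/T)²
        t = 1000
        y = np.sqrt(2) * np.sin(2 * np.pi * np.arange(t) / t)
        expected = (2 * np.pi / t) ** 2
        assert ps.delta_value(y) == pytest.approx(expected, rel=0.01)

    def test_slower_is_smaller(self):
        t = np.arange(2000)
        slow = np.sin(2 * np.pi * t / 2000)
        fast = np.sin(2 * np.pi * 7 * t / 2000)
        assert ps.delta_value(slow, True) < ps.delta_value(fast, True)


def constraint_residuals(y):
    cov = np.cov(y.T, bias=True)
    cov = np.atleast_2d(cov)
    off = cov - np.diag(np.diag(cov))
    return (
        np.abs(y.mean(axis=0)).max(),
        np.abs(np.diag(cov) - 1).max(),
        np.abs(off).max(),
    )


@pytest.fixture(scope="module")
def toy_sources():
    t = np.arange(3000)
    s1 = np.sin(2 * np.pi * t / 3000)
    s2 = np.sin(2 * np.pi * 11 * t / 3000)
    x = np.stack([s1 + s2**2, s2], axis=1)
    return x, s1


class TestFitSFA:
    def test_constraints_on_training_data(self, toy_sources):
        x, _ = toy_sources
        model = ps.fit_sfa(x, 3, expansion="quadratic")
        y = ps.apply_sfa(model, x)
        mean_r, var_r, cov_r = constraint_residuals(y)
        assert mean_r <= 1e-8
        assert var_r <= 1e-6
        assert cov_r <= 1e-6
        assert np.all(np.diff(model.delta_values) >= 0)

    def test_slow_source_recovered(self, toy_sources):
        """The nonlinear mixture s1 + s2² is demixed: the slowest quadratic
        SFA output recovers the slow source."""
        x, s1 = toy_sources
        model = ps.fit_sfa(x, 2, expansion="quadratic")
        y = ps.apply_sfa(model, x)
        assert abs(np.corrcoef(y[:, 0], s1)[0, 1]) > 0.95

    def test_matches_dense_eigenproblem_oracle(self):
        """Whiten-then-diagonalize equals the one-shot generalized
        eigenproblem up to per-component sign."""
        rng = np.random.default_rng(0)
        raw = rng.normal(size=(2000, 8))
        # temporally correlated mixture so eigenvalues are distinct
        kernel = np.exp(-np.arange(40) / 10.0)
        data = np.apply_along_axis(
            lambda c: np.convolve(c, kernel, mode="same"), 0, raw
        ) @ rng.normal(size=(8, 8))
        model = ps.fit_sfa(data, 8)
        y = ps.apply_sfa(model, data)
        y_ref, deltas_ref = sfa_oracle(data, 8)
        for i in range(8):
            sign = np.sign(y[:, i] @ y_ref[:, i])
            assert np.abs(y[:, i] - sign * y_ref[:, i]).max() <= 1e-6
        assert np.allclose(model.delta_values, deltas_ref, atol=1e-9)

    def test_slowness_optimality_vs_random_projections(self):
        """No random unit-variance projection of the whitened expanded data
        is slower than the first SFA output."""
        rng = np.random.default_rng(4)
        data = np.cumsum(rng.normal(size=(1500, 5)), axis=0)
        model = ps.fit_sfa(data, 3, expansion="quadratic")
        y = ps.apply_sfa(model, data)
        d0 = ps.delta_value(y[:, 0])
        from placesim.sfa import _expand

        z = (_expand(data, "quadratic") - model.exp_mean) @ model.whitening.T
        for _ in range(100):
            v = rng.normal(size=z.shape[1])
            v /= np.linalg.norm(v)
            proj = z @ v
            assert ps.delta_value(proj) >= d0 - 1e-12

    def test_single_frame_application(self, toy_sources):
        x, _ = toy_sources
        model = ps.fit_sfa(x, 2, expansion="quadratic")
        out = ps.apply_sfa(model, x[0])
        assert out.shape == (2,)
        assert np.allclose(out, ps.apply_sfa(model, x[:1])[0])

    def test_dimension_mismatch_rejected(self, toy_sources):
        x, _ = toy_sources
        model = ps.fit_sfa(x, 2)
        with pytest.raises(ps.ParameterError):
            ps.apply_sfa(model, np.zeros((5, 3)))

    def test_degenerate_input_advises_noise(self):
        data = np.zeros((200, 3))
        data[:, 0] = np.sin(np.arange(200) / 20)
        with pytest.raises(ps.NumericalRankError, match="noise"):
            ps.fit_sfa(data, 3, noise_sigma=0.0)

    def test_noise_regularizes_degenerate_input(self):
        data = np.zeros((2000, 3))
        data[:, 0] = np.sin(np.arange(2000) / 20)
        model = ps.fit_sfa(data, 3, noise_sigma=1e-3, seed=1)
        assert model.out_dim == 3
        assert model.training_stats["var_dev_max"] <= 1e-6

    def test_zero_noise_application_deterministic(self, toy_sources):
        x, _ = toy_sources
        model = ps.fit_sfa(x, 2, expansion="quadratic")
        assert np.array_equal(ps.apply_sfa(model, x), ps.apply_sfa(model, x))


class TestBatchAccumulation:
    def test_batched_fit_equals_single_fit(self):
        """Moment accumulation treats batches as one continuous recording,
        so the fitted model is independent of the batch split."""
        rng = np.random.default_rng(8)
        data = np.cumsum(rng.normal(size=(1000, 6)), axis=0)
        one = SFATrainer(4, "quadratic").partial_fit(data).finalize()
        many = SFATrainer(4, "quadratic")
        for i in range(0, 1000, 100):
            many.partial_fit(data[i: i + 100])
        split = many.finalize()
        assert np.allclose(
            ps.apply_sfa(one, data), ps.apply_sfa(split, data), atol=1e-10
        )

    def test_batched_fit_with_noise_identical(self):
        rng = np.random.default_rng(9)
        data = np.cumsum(rng.normal(size=(600, 4)), axis=0)
        one = SFATrainer(3, noise_sigma=1e-4, seed=5).partial_fit(data).finalize()
        many = SFATrainer(3, noise_sigma=1e-4, seed=5)
        for i in range(0, 600, 150):
            many.partial_fit(data[i: i + 150])
        # the seeded noise stream is split-independent; only floating-point
        # summation order differs
        assert np.allclose(
            one.sfa_vectors, many.finalize().sfa_vectors, atol=1e-10
        )


@pytest.fixture(scope="module")
def laplace_mixture():
    """Two standardized independent Laplacian sources (approximately white
    by construction) rotated by a known 30°."""
    rng = np.random.default_rng(12)
    s = rng.laplace(size=(6000, 2))
    s = (s - s.mean(axis=0)) / s.std(axis=0)
    th = np.radians(30.0)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return s @ rot.T, s


def logcosh_contrast(y):
    # negentropy approximation: (E[log cosh y] − E_gauss)² summed over signals
    e_gauss = 0.37456
    return np.sum((np.mean(np.log(np.cosh(y)), axis=0) - e_gauss) ** 2)


class TestFitICA:
    def test_rotation_is_orthogonal(self, laplace_mixture):
        x, _ = laplace_mixture
        model = ps.fit_ica(x, seed=0)
        r = model.rotation
        assert np.abs(r @ r.T - np.eye(2)).max() <= 1e-6

    def test_recovers_known_rotation_vs_grid_oracle(self, laplace_mixture):
        """The fitted angle matches a brute-force grid search maximizing the
        same non-Gaussianity contrast, and undoes the 30° mixing."""
        x, _ = laplace_mixture
        model = ps.fit_ica(x, seed=0)
        # W rows are direction vectors; as a rotation-by-θ its angle is the
        # negative of the row angle
        fitted_angle = -np.degrees(
            np.arctan2(model.rotation[0, 1], model.rotation[0, 0])
        )
        grid = np.arange(0.0, 90.0, 0.05)
        scores = []
        for deg in grid:
            th = np.radians(deg)
            r = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
            scores.append(logcosh_contrast(x @ r.T))
        best = grid[int(np.argmax(scores))]
        diff = (fitted_angle - best) % 90.0
        assert min(diff, 90.0 - diff) <= 2.0
        # the oracle itself undoes the +30° mixing: θ ≡ −30 (mod 90)
        mix = (best + 30.0) % 90.0
        assert min(mix, 90.0 - mix) <= 2.0

    def test_outputs_sparser_than_inputs(self, laplace_mixture):
        x, _ = laplace_mixture
        model = ps.fit_ica(x, seed=0)
        y = ps.apply_ica(model, x)
        assert np.mean(stats.kurtosis(y)) >= np.mean(stats.kurtosis(x))

    def test_variance_preserved(self, laplace_mixture):
        x, _ = laplace_mixture
        y = ps.apply_ica(ps.fit_ica(x, seed=0), x)
        assert np.sum(y.var(axis=0)) == pytest.approx(np.sum(x.var(axis=0)))

    def test_agrees_with_sklearn_fastica(self, laplace_mixture):
        """Cross-check against an independent FastICA implementation: both
        unmixing rotations agree up to sign/permutation."""
        from sklearn.decomposition import FastICA

        x, _ = laplace_mixture
        ours = ps.fit_ica(x, seed=0).rotation
        sk = FastICA(whiten=False, fun="logcosh", random_state=0)
        sk.fit(x)
        cross = np.abs(ours @ sk.components_.T)
        # permutation matrix structure: one ~1 entry per row/column
        assert np.allclose(np.sort(cross.ravel())[-2:], 1.0, atol=0.02)
        assert np.allclose(np.sort(cross.ravel())[:2], 0.0, atol=0.02)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ps.ParameterError):
            ps.fit_ica(np.random.default_rng(0).normal(size=(15, 2)))
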