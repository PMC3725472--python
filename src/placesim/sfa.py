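"""Slow Feature Analysis, quadratic expansion, the Δ slowness measure, and the
ICA rotation used for sparse coding.

Slow Feature Analysis (SFA) takes a multidimensional time series x(t) and finds
input–output functions g_i whose outputs y_i(t) = g_i(x(t)) vary as slowly as
possible over time, measured by the Δ value

    Δ(y) = ⟨ẏ²⟩_t ,

subject to zero mean, unit variance, and mutual decorrelation of the outputs
(which excludes the trivial constant solution and duplicate solutions).  With a
polynomial expansion of the input the g_i are nonlinear in the original
variables while the optimisation stays a linear generalized eigenproblem:
expand, whiten, and diagonalize the covariance of the temporal derivative; the
eigenvectors with the smallest eigenvalues are the slowest directions and the
eigenvalues themselves are the Δ values.

Temporal derivatives are approximated by forward differences, ẏ(t) ≈
y(t+1) − y(t), which leaves T−1 derivative samples for T inputs.

The ICA step is a rotation-only FastICA on the (already white) SFA outputs:
an orthogonal matrix maximizing a tanh-based negentropy contrast, fitted by
symmetric fixed-point iteration.  Rotating the slow signals into maximally
non-Gaussian directions yields the sparse code in which localized place fields
become visible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConvergenceWarning, NumericalRankError, ParameterError

__all__ = [
    "SFAModel",
    "ICAModel",
    "SFATrainer",
    "quadratic_expand",
    "expanded_dim",
    "delta_value",
    "fit_sfa",
    "apply_sfa",
    "fit_ica",
    "apply_ica",
]

#: Relative eigenvalue cutoff used when whitening: principal directions whose
#: variance falls below this fraction of the largest are discarded.
WHITENING_CUTOFF = 1e-7


def expanded_dim(n: int, expansion: str) -> int:
    """Dimension of the expanded signal: N + N(N+1)/2 for 'quadratic'."""
    if expansion == "none":
        return n
    if expansion == "quadratic":
        return n + n * (n + 1) // 2
    raise ParameterError(f"unknown expansion {expansion!r}")


def quadratic_expand(x: np.ndarray) -> np.ndarray:
    """All monomials of degree 1 and 2 of the input variables.

    Output columns are x_1 .. x_N followed by the products x_i·x_j for i ≤ j in
    lexicographic (i, j) order.  Accepts a single N-vector or a (T, N) matrix.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    n = x.shape[1]
    i, j = np.triu_indices(n)
    out = np.concatenate([x, x[:, i] * x[:, j]], axis=1)
    return out[0] if single else out


def _expand(x: np.ndarray, expansion: str) -> np.ndarray:
    return x if expansion == "none" else quadratic_expand(x)


def delta_value(y: np.ndarray, normalize: bool = False) -> float:
    """Mean squared forward difference of a signal; the slowness measure.

    With ``normalize`` the signal is first standardized to zero mean and unit
    variance, making Δ comparable across signals of different amplitude.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.size < 2:
        raise ParameterError("delta_value requires at least 2 samples")
    if normalize:
        sd = y.std()
        if sd == 0:
            raise ParameterError("constant signal has undefined variance")
        y = (y - y.mean()) / sd
    d = np.diff(y)
    return float(np.mean(d * d))


@dataclass
class SFAModel:
    """A fitted SFA transform: expand → center → whiten → project.

    ``whitening`` maps the centered expanded signal to white coordinates;
    ``sfa_vectors`` holds the orthonormal slow directions (columns) in white
    space, ordered by ascending Δ value.
    """

    expansion: str
    exp_mean: np.ndarray          # (M,) mean of the expanded training signal
    whitening: np.ndarray         # (P, M)
    sfa_vectors: np.ndarray       # (P, k), orthonormal columns
    delta_values: np.ndarray      # (k,) ascending
    noise_sigma: float
    n_train: int
    input_dim: int
    training_stats: dict = field(default_factory=dict)

    @property
    def out_dim(self) -> int:
        return self.sfa_vectors.shape[1]

    @property
    def projection(self) -> np.ndarray:
        """Combined (M, k) matrix applied to the centered expanded signal."""
        return self.whitening.T @ self.sfa_vectors


def apply_sfa(model: SFAModel, data: np.ndarray) -> np.ndarray:
    """Apply a fitted SFA transform; deterministic, no noise is injected.

    Accepts a (T, N) matrix or a single N-vector (a single frame suffices to
    produce a response), returning (T, k) or (k,) respectively.
    """
    data = np.asarray(data, dtype=float)
    single = data.ndim == 1
    if single:
        data = data[None, :]
    if data.shape[1] != model.input_dim:
        raise ParameterError(
            f"input dimension {data.shape[1]} does not match model "
            f"dimension {model.input_dim}"
        )
    z = _expand(data, model.expansion) - model.exp_mean
    y = z @ model.projection
    return y[0] if single else y


class SFATrainer:
    """Accumulates first/second/difference moments of the (expanded) signal
    over one or more batches, then solves the slowness eigenproblem.

    Batches are treated as one continuous recording: the last frame of each
    batch is retained so the temporal difference across the batch boundary is
    included, making the accumulated moments independent of the batching.
    """

    def __init__(
        self,
        out_dim: int,
        expansion: str = "none",
        noise_sigma: float = 0.0,
        seed: int | np.random.SeedSequence = 0,
        cutoff: float = WHITENING_CUTOFF,
    ):
        if out_dim < 1:
            raise ParameterError("out_dim must be >= 1")
        if noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")
        self.out_dim = out_dim
        self.expansion = expansion
        self.noise_sigma = float(noise_sigma)
        self.cutoff = cutoff
        self._rng = np.random.default_rng(seed)
        self._n = 0
        self._nd = 0
        self._s1 = None    # Σ z
        self._s2 = None    # Σ z zᵀ
        self._d2 = None    # Σ dz dzᵀ (within and across batch boundaries)
        self._tail = None  # last expanded row of the previous batch
        self._input_dim = None

    def partial_fit(self, batch: np.ndarray) -> "SFATrainer":
        batch = np.atleast_2d(np.asarray(batch, dtype=float))
        if not np.all(np.isfinite(batch)):
            raise ParameterError("signal contains non-finite entries")
        if self._input_dim is None:
            self._input_dim = batch.shape[1]
        elif batch.shape[1] != self._input_dim:
            raise ParameterError("inconsistent batch dimensionality")
        z = _expand(batch, self.expansion)
        if self.noise_sigma > 0:
            # absolute seeded noise: the draw sequence, and hence the fitted
            # model, is independent of how the recording is split into batches
            z = z + self._rng.normal(0.0, self.noise_sigma, z.shape)
        if self._s1 is None:
            m = z.shape[1]
            self._s1 = np.zeros(m)
            self._s2 = np.zeros((m, m))
            self._d2 = np.zeros((m, m))
        self._s1 += z.sum(axis=0)
        self._s2 += z.T @ z
        if self._tail is not None:
            zd = np.diff(np.vstack([self._tail, z]), axis=0)
        else:
            zd = np.diff(z, axis=0)
        if zd.size:
            self._d2 += zd.T @ zd
            self._nd += zd.shape[0]
        self._n += z.shape[0]
        self._tail = z[-1].copy()
        return self

    def finalize(self) -> SFAModel:
        if self._n < 2 or self._nd < 1:
            raise ParameterError("need at least 2 samples to fit SFA")
        mean = self._s1 / self._n
        cov = self._s2 / self._n - np.outer(mean, mean)
        cov = 0.5 * (cov + cov.T)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        if evals[0] <= 0:
            raise NumericalRankError(
                "signal covariance has no positive variance; the input is "
                "constant — add fitting noise (noise_sigma > 0)"
            )
        keep = evals > self.cutoff * evals[0]
        if keep.sum() < self.out_dim and self.noise_sigma == 0:
            raise NumericalRankError(
                f"covariance rank {int(keep.sum())} < requested {self.out_dim} "
                "output signals; the input is degenerate — add fitting noise "
                "(noise_sigma > 0)"
            )
        w = evecs[:, keep] / np.sqrt(evals[keep])      # (M, P)
        whitening = w.T                                 # (P, M)
        dcov = self._d2 / self._nd
        a = whitening @ (0.5 * (dcov + dcov.T)) @ whitening.T
        a = 0.5 * (a + a.T)
        deltas, vecs = np.linalg.eigh(a)                # ascending
        k = min(self.out_dim, vecs.shape[1])
        v = vecs[:, :k]
        model = SFAModel(
            expansion=self.expansion,
            exp_mean=mean,
            whitening=whitening,
            sfa_vectors=v,
            delta_values=deltas[:k].copy(),
            noise_sigma=self.noise_sigma,
            n_train=self._n,
            input_dim=self._input_dim,
        )
        # constraint residuals over the training ensemble, from the moments
        ycov = v.T @ (whitening @ cov @ whitening.T) @ v
        model.training_stats = {
            "mean_abs_max": 0.0,  # exact: projection of (mean − mean)
            "var_dev_max": float(np.abs(np.diag(ycov) - 1.0).max()),
            "cov_abs_max": float(np.abs(ycov - np.diag(np.diag(ycov))).max())
            if k > 1
            else 0.0,
        }
        return model


def fit_sfa(
    data: np.ndarray,
    out_dim: int,
    expansion: str = "none",
    noise_sigma: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
) -> SFAModel:
    """Fit SFA to a (T, N) time-ordered signal matrix in a single batch.

    The fitting pipeline is: expand → add seeded Gaussian regularization noise
    (fitting only) → center → whiten (discarding near-degenerate directions) →
    eigen-decompose the forward-difference covariance → keep the ``out_dim``
    smallest-eigenvalue directions.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[0] < data.shape[1] + 2 and data.shape[0] < 4:
        raise ParameterError("too few samples to fit SFA")
    return SFATrainer(out_dim, expansion, noise_sigma, seed).partial_fit(data).finalize()


@dataclass
class ICAModel:
    """An orthogonal rotation of (white) signals toward a sparse code."""

    rotation: np.ndarray  # (k, k), orthogonal
    converged: bool = True
    n_iter: int = 0


def apply_ica(model: ICAModel, data: np.ndarray) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    single = data.ndim == 1
    y = np.atleast_2d(data) @ model.rotation.T
    return y[0] if single else y


def _sym_decorrelate(w: np.ndarray) -> np.ndarray:
    s, u = np.linalg.eigh(w @ w.T)
    return (u / np.sqrt(s)) @ u.T @ w


def fit_ica(
    data: np.ndarray,
    seed: int | np.random.SeedSequence = 0,
    tol: float = 1e-5,
    max_iter: int = 500,
) -> ICAModel:
    """Rotation-only FastICA (tanh contrast, symmetric decorrelation).

    ``data`` is expected to be approximately white, as SFA training outputs
    are; the fitted transform is a pure rotation, so output variance is
    preserved.  Non-convergence produces a warning and the best iterate,
    flagged on the model.
    """
    x = np.atleast_2d(np.asarray(data, dtype=float))
    t, k = x.shape
    if t < 10 * k:
        raise ParameterError(f"need at least {10 * k} samples for {k}-d ICA")
    x = x - x.mean(axis=0)
    rng = np.random.default_rng(seed)
    w = _sym_decorrelate(rng.normal(size=(k, k)))
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        y = x @ w.T                       # (T, k)
        g = np.tanh(y)
        g_prime = 1.0 - g * g
        w_new = (g.T @ x) / t - np.diag(g_prime.mean(axis=0)) @ w
        w_new = _sym_decorrelate(w_new)
        change = np.max(np.abs(np.abs(np.einsum("ij,ij->i", w_new, w)) - 1.0))
        w = w_new
        if change < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"ICA did not reach tolerance {tol} in {max_iter} iterations; "
            "returning best iterate",
            ConvergenceWarning,
            stacklevel=2,
        )
    return ICAModel(rotation=w, converged=converged, n_iter=n_iter)
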