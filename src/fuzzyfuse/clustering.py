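"""Fuzzy and possibilistic c-means clustering kernels.

Implements the five clustering estimators the tissue-modelling stage is
built from:

* ``FCM``   — classic fuzzy c-means (relative memberships, column sums 1);
* ``PCM``   — possibilistic c-means (absolute typicalities, per-cluster
  penalty ``gamma``);
* ``FPCM``  — fuzzy-possibilistic c-means (typicalities row-normalised
  over observations);
* ``BCFCM`` — bias-corrected FCM on image grids: an additive bias field
  ``beta`` models scanner intensity inhomogeneity and a neighbourhood
  regulariser (weight ``alpha``) drives piecewise-homogeneous labelling;
* ``PFCM``  — possibilistic-fuzzy c-means producing memberships U,
  typicalities T and centroids B simultaneously.

Every estimator follows the statsmodels convention: construct from data
plus a :class:`ClusterConfig`, call :meth:`fit`, receive a results object
carrying the partition, centroids, objective trace and ``summary()``.
All updates are exact block-coordinate minimisers of their objective, so
objective traces are non-increasing; iteration stops when the objective
change falls below ``eps``.

Functional wrappers (``fcm_fit`` and friends) expose the same fits as
plain tuples.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage

__all__ = [
    "ClusterConfig",
    "ClusterResults",
    "FCM",
    "PCM",
    "FPCM",
    "BCFCM",
    "PFCM",
    "fcm_fit",
    "pcm_fit",
    "fpcm_fit",
    "bcfcm_fit",
    "pfcm_fit",
    "bcfcm_objective",
    "pfcm_objective",
    "estimate_gamma",
]


@dataclasses.dataclass
class ClusterConfig:
    """Shared configuration of the clustering estimators.

    Parameters
    ----------
    C : int
        Number of clusters (3 tissue classes by default).
    m : float
        Fuzzifier, > 1. The default 2 is the value retained after the
        usual [1.5, 3] sweep; partitions harden as m -> 1.
    eta : float
        Possibilistic exponent, > 1; typicalities soften as it grows.
        Default 4, the midpoint of the customary [3, 5] range.
    a, b : float
        PFCM trade-off weights between the fuzzy and possibilistic terms
        in the centroid update (both > 0).
    alpha : float
        BCFCM neighbourhood regularisation weight; larger values suit
        noisier images.
    eps : float
        Convergence threshold on |J_k+1 - J_k| (default 0.005).
    max_iter : int
        Safety cap on iterations.
    gamma : array-like or None
        Per-cluster possibilistic penalties; estimated from the
        initialising fuzzy partition when None.
    bias_degree : int
        Polynomial degree of the BCFCM bias-field model. The additive
        bias is restricted to a low-order polynomial in the (scaled)
        voxel coordinates: scanner inhomogeneity is spatially smooth,
        and an unconstrained per-voxel offset could absorb the whole
        image and collapse the centroids. The default (1, an affine
        ramp) cannot mimic compact anatomical structure; raise it only
        when the inhomogeneity is known to be more curved than the
        anatomy.
    seed : int
        Seed for random centroid initialisation.
    """

    C: int = 3
    m: float = 2.0
    eta: float = 4.0
    a: float = 1.0
    b: float = 1.0
    alpha: float = 0.7
    eps: float = 0.005
    max_iter: int = 200
    gamma: np.ndarray | None = None
    bias_degree: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C < 1:
            raise ValueError("C must be at least 1")
        if self.m <= 1:
            raise ValueError("fuzzifier m must exceed 1")
        if self.eta <= 1:
            raise ValueError("possibilistic exponent eta must exceed 1")
        if self.a <= 0 or self.b <= 0:
            raise ValueError("PFCM trade-offs a, b must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.eps <= 0:
            raise ValueError("convergence threshold eps must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")


@dataclasses.dataclass
class ClusterResults:
    """Fitted partition, centroids and diagnostics of one clustering run.

    ``u`` holds relative (column-stochastic) memberships where the
    estimator produces them, ``t`` absolute typicalities; either may be
    None depending on the estimator. ``beta`` is the per-voxel additive
    bias estimate (BCFCM only).
    """

    model_name: str
    centroids: np.ndarray
    u: np.ndarray | None = None
    t: np.ndarray | None = None
    beta: np.ndarray | None = None
    gamma: np.ndarray | None = None
    objective_trace: np.ndarray | None = None
    converged: bool = False

    @property
    def n_iter(self) -> int:
        return 0 if self.objective_trace is None else len(self.objective_trace)

    @property
    def objective(self) -> float:
        return float(self.objective_trace[-1])

    @property
    def labels(self) -> np.ndarray:
        """Hard assignment: argmax of memberships (or typicalities)."""
        grid = self.u if self.u is not None else self.t
        return np.argmax(grid, axis=0)

    def summary(self) -> str:
        lines = [
            f"{self.model_name} clustering results",
            "=" * 40,
            f"clusters:     {len(self.centroids)}",
            f"iterations:   {self.n_iter}",
            f"converged:    {self.converged}",
            f"objective:    {self.objective:.6g}",
        ]
        for i, c in enumerate(np.atleast_2d(self.centroids)):
            lines.append(f"centroid[{i}]:  {np.array_str(np.ravel(c), precision=4)}")
        if self.gamma is not None:
            lines.append(f"gamma:        {np.array_str(self.gamma, precision=4)}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# shared numerics


def _as_feature_matrix(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValueError("feature matrix must be (N, dim)")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    return X


def _sqdist(X: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances, shape (C, N)."""
    diff = X[None, :, :] - B[:, None, :]
    return np.einsum("cnd,cnd->cn", diff, diff)


def _inverse_power_partition(d2: np.ndarray, exponent: float, axis: int) -> np.ndarray:
    """Normalised d2**(-exponent) along ``axis`` with the zero-distance
    convention: coincident points take the whole (equally shared) mass."""
    zero = d2 <= 0
    with np.errstate(divide="ignore"):
        inv = np.where(zero, np.inf, d2) ** (-exponent)
    out = inv / inv.sum(axis=axis, keepdims=True)
    degenerate = zero.any(axis=axis, keepdims=True)
    if degenerate.any():
        share = zero / np.maximum(zero.sum(axis=axis, keepdims=True), 1)
        out = np.where(degenerate, share, out)
    return out


def _init_centroids(X: np.ndarray, C: int, init, seed: int) -> np.ndarray:
    """Resolve an init spec: None/int seed -> seeded k-means++-style
    draw of spread data points, otherwise an explicit (C, dim) centroid
    array."""
    if init is None or isinstance(init, (int, np.integer)):
        rng = np.random.default_rng(seed if init is None else int(init))
        uniq = np.unique(X, axis=0)
        if len(uniq) < C:
            # fewer distinct points than clusters: jitter what exists
            base = uniq[rng.choice(len(uniq), size=C, replace=True)]
            return base + rng.normal(0, 1e-6, size=base.shape)
        # k-means++ seeding: subsequent centroids drawn with probability
        # proportional to squared distance from the chosen set
        centers = [uniq[rng.integers(len(uniq))]]
        for _ in range(1, C):
            d2 = np.min(_sqdist(uniq, np.asarray(centers)), axis=0)
            total = d2.sum()
            if total <= 0:
                centers.append(uniq[rng.integers(len(uniq))])
                continue
            centers.append(uniq[rng.choice(len(uniq), p=d2 / total)])
        return np.asarray(centers, dtype=float)
    B = np.asarray(init, dtype=float)
    if B.ndim == 1:
        B = B[:, None]
    if B.shape[0] != C:
        raise ValueError(f"init centroids must have {C} rows")
    return B.copy()


def _warn_coincident(B: np.ndarray, scale: float) -> None:
    C = len(B)
    if C < 2:
        return
    d2 = _sqdist(B, B)
    off = d2[~np.eye(C, dtype=bool)]
    if off.min() < (1e-6 * max(scale, 1e-30)) ** 2:
        warnings.warn("coincident cluster centroids at convergence",
                      RuntimeWarning, stacklevel=3)


def estimate_gamma(X: np.ndarray, U: np.ndarray, B: np.ndarray,
                   cfg: ClusterConfig, K: float = 1.0) -> np.ndarray:
    """Per-cluster possibilistic penalties from an initialising fuzzy
    partition: gamma_i = K * sum_j u_ij^m d^2(x_j, b_i) / sum_j u_ij^m.

    This is the customary choice of the possibilistic penalty as the
    fuzzy intra-cluster spread; gamma ~ 0 (all points on the centroid)
    is flagged as degenerate.
    """
    X = _as_feature_matrix(X)
    um = np.asarray(U, dtype=float) ** cfg.m
    d2 = _sqdist(X, np.atleast_2d(B))
    gamma = K * (um * d2).sum(axis=1) / um.sum(axis=1)
    if np.any(gamma <= 1e-300):
        warnings.warn("degenerate gamma (zero intra-cluster spread)",
                      RuntimeWarning, stacklevel=2)
    return gamma


# ---------------------------------------------------------------------------
# estimators


class _CMeansBase:
    """Common fit loop driver: subclasses provide block updates and the
    objective; the base runs them until |dJ| < eps."""

    name = "c-means"

    def __init__(self, X: np.ndarray, config: ClusterConfig | None = None, **kw):
        self.config = config or ClusterConfig(**kw)
        self.X = _as_feature_matrix(X)
        if len(self.X) < self.config.C:
            raise ValueError("need at least C observations")

    def _resolve_init(self, init):
        return _init_centroids(self.X, self.config.C, init, self.config.seed)


class FCM(_CMeansBase):
    """Classic fuzzy c-means (Bezdek).

    Memberships u_ij = (sum_k (d_ij^2/d_kj^2)^(1/(m-1)))^-1, centroids
    the u^m-weighted means; minimises J = sum u^m d^2 subject to
    column-stochastic U.
    """

    name = "FCM"

    def fit(self, init=None) -> ClusterResults:
        cfg = self.config
        X = self.X
        B = self._resolve_init(init)
        expo = 1.0 / (cfg.m - 1.0)
        trace = []
        converged = False
        for _ in range(cfg.max_iter):
            d2 = _sqdist(X, B)
            U = _inverse_power_partition(d2, expo, axis=0)
            um = U ** cfg.m
            B = (um @ X) / um.sum(axis=1)[:, None]
            J = float((um * _sqdist(X, B)).sum())
            trace.append(J)
            if len(trace) > 1 and abs(trace[-2] - trace[-1]) < cfg.eps:
                converged = True
                break
        _warn_coincident(B, np.ptp(X))
        return ClusterResults(self.name, centroids=B, u=U,
                              objective_trace=np.asarray(trace),
                              converged=converged)


class PCM(_CMeansBase):
    """Possibilistic c-means: absolute typicalities with per-cluster
    penalty gamma, no column-sum constraint (so clusters may coincide).

    t_ij = 1 / (1 + (d^2/gamma_i)^(1/(eta-1))); centroids are t^eta
    weighted means. gamma defaults to the fuzzy spread of an FCM-style
    partition computed at the initial centroids.
    """

    name = "PCM"

    def fit(self, init=None) -> ClusterResults:
        cfg = self.config
        X = self.X
        B = self._resolve_init(init)
        gamma = cfg.gamma
        if gamma is None:
            U0 = _inverse_power_partition(_sqdist(X, B), 1.0 / (cfg.m - 1.0), axis=0)
            gamma = estimate_gamma(X, U0, B, cfg)
        gamma = np.maximum(np.asarray(gamma, dtype=float), 1e-300)
        if np.any(gamma <= 0):
            raise ValueError("gamma must be positive")
        expo = 1.0 / (cfg.eta - 1.0)
        trace = []
        converged = False
        for _ in range(cfg.max_iter):
            d2 = _sqdist(X, B)
            T = 1.0 / (1.0 + (d2 / gamma[:, None]) ** expo)
            te = T ** cfg.eta
            B = (te @ X) / te.sum(axis=1)[:, None]
            J = float((te * _sqdist(X, B)).sum()
                      + (gamma * ((1.0 - T) ** cfg.eta).sum(axis=1)).sum())
            trace.append(J)
            if len(trace) > 1 and abs(trace[-2] - trace[-1]) < cfg.eps:
                converged = True
                break
        _warn_coincident(B, np.ptp(X))
        return ClusterResults(self.name, centroids=B, t=T, gamma=gamma,
                              objective_trace=np.asarray(trace),
                              converged=converged)


class FPCM(_CMeansBase):
    """Fuzzy-possibilistic c-means: FCM memberships plus typicalities
    normalised over observations (each typicality row sums to 1);
    centroids weight each point by u^m + t^eta."""

    name = "FPCM"

    def fit(self, init=None) -> ClusterResults:
        cfg = self.config
        X = self.X
        B = self._resolve_init(init)
        eu = 1.0 / (cfg.m - 1.0)
        et = 1.0 / (cfg.eta - 1.0)
        trace = []
        converged = False
        for _ in range(cfg.max_iter):
            d2 = _sqdist(X, B)
            U = _inverse_power_partition(d2, eu, axis=0)
            T = _inverse_power_partition(d2, et, axis=1)
            w = U ** cfg.m + T ** cfg.eta
            B = (w @ X) / w.sum(axis=1)[:, None]
            J = float((w * _sqdist(X, B)).sum())
            trace.append(J)
            if len(trace) > 1 and abs(trace[-2] - trace[-1]) < cfg.eps:
                converged = True
                break
        _warn_coincident(B, np.ptp(X))
        return ClusterResults(self.name, centroids=B, u=U, t=T,
                              objective_trace=np.asarray(trace),
                              converged=converged)


class BCFCM:
    """Bias-corrected FCM on an image grid.

    Minimises

        J = sum_ij u_ij^m ||x_j - beta_j - b_i||^2
          + (alpha/N_R) sum_ij u_ij^m sum_{k in N(j)} ||x_k - beta_k - b_i||^2

    where beta is a smooth additive bias field and N(j) the voxel's
    3x3 (2D) or 3x3x3 (3D) neighbourhood without its centre, with
    periodic boundary handling so every voxel has exactly N_R
    neighbours and the neighbourhood relation is symmetric.

    The bias field is parameterised as a polynomial of degree
    ``config.bias_degree`` in the voxel coordinates; its block update
    is the weighted least-squares projection of the unconstrained
    per-voxel minimiser onto that smooth subspace. Every block update
    (memberships, centroids, bias coefficients) is therefore an exact
    coordinate minimiser of J over its feasible set, so the objective
    trace is non-increasing.

    Parameters
    ----------
    image : ndarray
        2D or 3D scalar intensity grid.
    config : ClusterConfig
    update_bias : bool
        When False the bias field is held at zero, reducing the
        estimator (with alpha = 0) to plain FCM exactly.
    """

    name = "BCFCM"

    def __init__(self, image: np.ndarray, config: ClusterConfig | None = None,
                 update_bias: bool = True, **kw):
        self.config = config or ClusterConfig(**kw)
        self.image = np.asarray(image, dtype=float)
        if self.image.ndim not in (2, 3):
            raise ValueError("BCFCM expects an image-structured 2D/3D input")
        if not np.all(np.isfinite(self.image)):
            raise ValueError("intensities must be finite")
        self.update_bias = update_bias
        kernel = np.ones((3,) * self.image.ndim)
        kernel[(1,) * self.image.ndim] = 0.0
        self._kernel = kernel
        self.n_r = int(kernel.sum())
        self._basis = self._polynomial_basis(self.config.bias_degree)

    def _polynomial_basis(self, degree: int) -> np.ndarray:
        """Monomials of total degree <= degree in [-1, 1]-scaled voxel
        coordinates, one column per term, rows flattened like the image."""
        import itertools
        axes = [np.linspace(-1.0, 1.0, s) if s > 1 else np.zeros(s)
                for s in self.image.shape]
        coords = [g.ravel() for g in np.meshgrid(*axes, indexing="ij")]
        cols = []
        for powers in itertools.product(range(degree + 1),
                                        repeat=len(coords)):
            if sum(powers) <= degree:
                col = np.ones(self.image.size)
                for c, p in zip(coords, powers):
                    col = col * c ** p
                cols.append(col)
        return np.column_stack(cols)

    def _neigh_sum(self, flat: np.ndarray) -> np.ndarray:
        """Sum of each voxel's neighbours (periodic borders), flattened."""
        img = flat.reshape(self.image.shape)
        return ndimage.convolve(img, self._kernel, mode="wrap").ravel()

    def _distance_terms(self, x, beta, B):
        """w_ij = (x_j-beta_j-b_i)^2 and its neighbour sums, both (C, N)."""
        resid = x[None, :] - beta[None, :] - B[:, None]
        w = resid ** 2
        neigh = np.stack([self._neigh_sum(row) for row in w])
        return w, neigh

    def objective(self, U: np.ndarray, B: np.ndarray, beta: np.ndarray) -> float:
        """Evaluate J for an arbitrary state (used by tests/oracles)."""
        x = self.image.ravel()
        B = np.ravel(np.asarray(B, dtype=float))
        beta = np.ravel(np.asarray(beta, dtype=float))
        w, neigh = self._distance_terms(x, beta, B)
        um = np.asarray(U, dtype=float) ** self.config.m
        return float((um * (w + (self.config.alpha / self.n_r) * neigh)).sum())

    def fit(self, init=None) -> ClusterResults:
        cfg = self.config
        x = self.image.ravel()
        N = x.size
        if N < cfg.C:
            raise ValueError("need at least C voxels")
        B = _init_centroids(x[:, None], cfg.C, init, cfg.seed).ravel()
        beta = np.zeros(N)
        expo = 1.0 / (cfg.m - 1.0)
        anr = cfg.alpha / self.n_r
        trace = []
        converged = False
        for _ in range(cfg.max_iter):
            # memberships: exact minimiser given (B, beta)
            w, neigh = self._distance_terms(x, beta, B)
            U = _inverse_power_partition(w + anr * neigh, expo, axis=0)
            um = U ** cfg.m
            # centroids: exact minimiser given (U, beta)
            xb = x - beta
            drive = xb[None, :] + anr * self._neigh_sum(xb)[None, :]
            B = (um * drive).sum(axis=1) / ((1.0 + cfg.alpha) * um.sum(axis=1))
            # bias: exact minimiser given (U, B) over the smooth subspace.
            # The weight of voxel j in cluster i is u_ij^m plus the
            # alpha-weighted memberships of the voxels whose neighbourhood
            # contains j; the beta-dependent part of J is a weighted least
            # squares about the unconstrained per-voxel minimiser, so the
            # constrained optimum is its weighted projection onto the basis.
            if self.update_bias:
                v = um + anr * np.stack([self._neigh_sum(row) for row in um])
                s = v.sum(axis=0)
                beta_hat = x - (v * B[:, None]).sum(axis=0) / s
                phi = self._basis
                gram = phi.T @ (phi * s[:, None])
                coef = np.linalg.solve(gram, phi.T @ (s * beta_hat))
                beta = phi @ coef
            w, neigh = self._distance_terms(x, beta, B)
            J = float((um * (w + anr * neigh)).sum())
            trace.append(J)
            if len(trace) > 1 and abs(trace[-2] - trace[-1]) < cfg.eps:
                converged = True
                break
        _warn_coincident(B[:, None], np.ptp(x))
        return ClusterResults(self.name, centroids=B[:, None], u=U, beta=beta,
                              objective_trace=np.asarray(trace),
                              converged=converged)


class PFCM(_CMeansBase):
    """Possibilistic-fuzzy c-means.

    Produces three outputs per fit: relative memberships U (FCM-type),
    absolute typicalities T (PCM-type, scaled by the trade-off b and the
    per-cluster penalty gamma) and centroids B weighted by
    a u^m + b t^eta. Intended to be initialised from the hybrid
    BCFCM/GA stage; gamma defaults to the fuzzy spread of the
    initialising partition.
    """

    name = "PFCM"

    def fit(self, init=None) -> ClusterResults:
        cfg = self.config
        X = self.X
        if isinstance(init, tuple):
            U_init, B = init
            B = np.atleast_2d(np.asarray(B, dtype=float))
            if B.shape[0] != cfg.C and B.shape == (1, cfg.C):
                B = B.T
        else:
            B = self._resolve_init(init)
            U_init = _inverse_power_partition(_sqdist(X, B), 1.0 / (cfg.m - 1.0), axis=0)
        gamma = cfg.gamma
        if gamma is None:
            gamma = estimate_gamma(X, U_init, B, cfg)
        gamma = np.asarray(gamma, dtype=float)
        if np.any(gamma <= 0):
            raise ValueError("gamma must be strictly positive")

        eu = 1.0 / (cfg.m - 1.0)
        et = 1.0 / (cfg.eta - 1.0)
        trace = []
        converged = False
        for _ in range(cfg.max_iter):
            d2 = _sqdist(X, B)
            U = _inverse_power_partition(d2, eu, axis=0)
            T = 1.0 / (1.0 + (cfg.b * d2 / gamma[:, None]) ** et)
            w = cfg.a * U ** cfg.m + cfg.b * T ** cfg.eta
            B = (w @ X) / w.sum(axis=1)[:, None]
            J = self._objective(X, U, T, B, gamma)
            trace.append(J)
            if len(trace) > 1 and abs(trace[-2] - trace[-1]) < cfg.eps:
                converged = True
                break
        _warn_coincident(B, np.ptp(X))
        return ClusterResults(self.name, centroids=B, u=U, t=T, gamma=gamma,
                              objective_trace=np.asarray(trace),
                              converged=converged)

    def _objective(self, X, U, T, B, gamma) -> float:
        cfg = self.config
        d2 = _sqdist(X, B)
        data_term = ((cfg.a * U ** cfg.m + cfg.b * T ** cfg.eta) * d2).sum()
        penalty = (gamma * ((1.0 - T) ** cfg.eta).sum(axis=1)).sum()
        return float(data_term + penalty)


# ---------------------------------------------------------------------------
# functional wrappers (spec-shaped op surface)


def fcm_fit(X, cfg: ClusterConfig, init=None):
    """FCM fit returning (memberships U, centroids B, objective trace)."""
    res = FCM(X, cfg).fit(init)
    return res.u, res.centroids, res.objective_trace


def pcm_fit(X, cfg: ClusterConfig, init=None):
    """PCM fit returning (typicalities T, centroids B, objective trace)."""
    res = PCM(X, cfg).fit(init)
    return res.t, res.centroids, res.objective_trace


def fpcm_fit(X, cfg: ClusterConfig, init=None):
    """FPCM fit returning (U, T, centroids, trace)."""
    res = FPCM(X, cfg).fit(init)
    return res.u, res.t, res.centroids, res.objective_trace


def bcfcm_fit(image, cfg: ClusterConfig, init=None, update_bias: bool = True):
    """BCFCM fit returning (U, centroids, bias field beta, trace)."""
    res = BCFCM(image, cfg, update_bias=update_bias).fit(init)
    return res.u, res.centroids, res.beta, res.objective_trace


def pfcm_fit(X, cfg: ClusterConfig, init):
    """PFCM fit returning (U, T, centroids, trace); ``init`` is either a
    centroid set or a (U, B) pair from the hybrid initialisation."""
    res = PFCM(X, cfg).fit(init)
    return res.u, res.t, res.centroids, res.objective_trace


def bcfcm_objective(image, U, B, beta, cfg: ClusterConfig) -> float:
    """Evaluate the bias-corrected objective at an arbitrary state."""
    return BCFCM(image, cfg).objective(U, B, beta)


def pfcm_objective(X, U, T, B, cfg: ClusterConfig, gamma=None) -> float:
    """Evaluate the possibilistic-fuzzy objective at an arbitrary state."""
    model = PFCM(X, cfg)
    if gamma is None:
        gamma = cfg.gamma
    if gamma is None:
        raise ValueError("gamma required to evaluate the PFCM objective")
    return model._objective(model.X, np.asarray(U, float), np.asarray(T, float),
                            np.atleast_2d(np.asarray(B, float)),
                            np.asarray(gamma, float))
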