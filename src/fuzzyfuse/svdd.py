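"""Support vector data description (one-class hypersphere classifier).

SVDD encloses the target class in a minimum-volume hypersphere in
kernel feature space. The primal

    min R^2 + C sum_i xi_i   s.t.  ||phi(x_i) - a||^2 <= R^2 + xi_i

has the dual

    max sum_i alpha_i K(x_i, x_i) - sum_ij alpha_i alpha_j K(x_i, x_j)
    s.t. sum_i alpha_i = 1,  0 <= alpha_i <= C,

solved here by a deterministic SMO-style pairwise coordinate ascent:
each step moves mass between the most violating pair of coefficients.
Points with 0 < alpha < C lie exactly on the sphere; points with
alpha = C sit outside (their count is bounded by 1/C). A test point z
is accepted when its kernel distance to the centre is at most R.

``sigma = 0`` selects the linear kernel (an RBF of zero width is not
meaningful); the RBF kernel is K(x, y) = exp(-||x - y||^2 / sigma^2).

``dac_train`` implements the divide-and-conquer scheme: k-means splits
the target set, a local SVDD solves each cell, and a final SVDD is
trained on the union of the local support vectors, cutting the QP cost
from O(N^3) to about k O((N/k)^3).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans
from sklearn.model_selection import KFold

__all__ = ["SvddConfig", "SvddModel", "SVDD", "svdd_train", "svdd_distance2",
           "svdd_predict", "grid_search", "dac_train", "SvddClassifier"]


@dataclasses.dataclass
class SvddConfig:
    """SVDD hyper-parameters.

    ``C`` in (0, 1] trades sphere volume against training-point
    exclusion (feasibility needs C >= 1/N); ``sigma`` is the RBF width,
    with 0 meaning the linear kernel; ``k_clusters`` > 1 switches on
    divide-and-conquer training.
    """

    C: float = 1.0
    sigma: float = 1.0
    kernel: str = "rbf"
    tol: float = 1e-6
    k_clusters: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.C <= 1:
            raise ValueError("C must lie in (0, 1]")
        if self.kernel not in ("rbf", "linear"):
            raise ValueError("kernel must be 'rbf' or 'linear'")
        if self.sigma == 0:
            self.kernel = "linear"   # zero-width RBF has no meaning
        elif self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.k_clusters < 1:
            raise ValueError("k_clusters must be at least 1")


def _kernel_matrix(A: np.ndarray, B: np.ndarray, cfg: SvddConfig) -> np.ndarray:
    if cfg.kernel == "linear":
        return A @ B.T
    d2 = ((A[:, None, :] - B[None, :, :]) ** 2).sum(-1)
    return np.exp(-d2 / cfg.sigma ** 2)


def _solve_dual(K: np.ndarray, C: float, tol: float,
                max_iter: int = 200_000) -> np.ndarray:
    """Maximise the SVDD dual by most-violating-pair coordinate ascent."""
    N = len(K)
    alpha = np.full(N, 1.0 / N)
    diag = np.diag(K).copy()
    Ka = K @ alpha
    for _ in range(max_iter):
        g = diag - 2.0 * Ka                      # dual gradient
        up = alpha < C - 1e-14                   # can grow
        dn = alpha > 1e-14                       # can shrink
        gi = np.where(up, g, -np.inf)
        gj = np.where(dn, g, np.inf)
        i = int(np.argmax(gi))
        j = int(np.argmin(gj))
        if gi[i] - gj[j] < tol:
            break
        denom = 2.0 * (K[i, i] + K[j, j] - 2.0 * K[i, j])
        step = (g[i] - g[j]) / denom if denom > 1e-300 else np.inf
        step = min(step, C - alpha[i], alpha[j])
        alpha[i] += step
        alpha[j] -= step
        Ka += step * (K[:, i] - K[:, j])
    return alpha


@dataclasses.dataclass
class SvddModel:
    """Fitted hypersphere: coefficients, support vectors and radius."""

    config: SvddConfig
    X: np.ndarray                 # training points (kept for the kernel)
    alphas: np.ndarray
    r2: float
    self_term: float              # sum_ij alpha_i alpha_j K(x_i, x_j)
    work_estimate: float | None = None   # divide-and-conquer QP cost proxy
    n_local_sv: int | None = None

    @property
    def sv_index(self) -> np.ndarray:
        return np.flatnonzero(self.alphas > self.config.tol)

    @property
    def support_vectors(self) -> np.ndarray:
        return self.X[self.sv_index]

    def distance2(self, Z: np.ndarray) -> np.ndarray:
        """Squared kernel distance of each row of Z to the centre:
        K(z,z) - 2 sum_i alpha_i K(z, x_i) + sum_ij alpha_i alpha_j K."""
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        Kzx = _kernel_matrix(Z, self.X, self.config)
        if self.config.kernel == "linear":
            kzz = (Z ** 2).sum(axis=1)
        else:
            kzz = np.ones(len(Z))
        return kzz - 2.0 * Kzx @ self.alphas + self.self_term

    def predict(self, Z: np.ndarray) -> np.ndarray:
        """+1 (accept: inside or on the sphere) or -1 (reject)."""
        d2 = self.distance2(Z)
        return np.where(d2 <= self.r2 + 1e-12, 1, -1)

    def score_samples(self, Z: np.ndarray) -> np.ndarray:
        """Continuous acceptance score R^2 - distance^2 (higher = more
        target-like); used for ROC construction."""
        return self.r2 - self.distance2(Z)

    def summary(self) -> str:
        return "\n".join([
            "SVDD results",
            "=" * 40,
            f"kernel:          {self.config.kernel}"
            + (f" (sigma={self.config.sigma:g})" if self.config.kernel == "rbf" else ""),
            f"C:               {self.config.C:g}",
            f"training points: {len(self.X)}",
            f"support vectors: {len(self.sv_index)}",
            f"R^2:             {self.r2:.6g}",
            f"sum(alpha):      {self.alphas.sum():.9f}",
        ])

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "config": dataclasses.asdict(self.config),
            "alphas": self.alphas.tolist(),
            "X": self.X.tolist(),
            "r2": self.r2,
            "self_term": self.self_term,
        }
        text = json.dumps(payload, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SvddModel":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        payload = json.loads(text)
        return cls(
            config=SvddConfig(**payload["config"]),
            X=np.asarray(payload["X"], dtype=float),
            alphas=np.asarray(payload["alphas"], dtype=float),
            r2=float(payload["r2"]),
            self_term=float(payload["self_term"]),
        )


class SVDD:
    """One-class estimator in the Model/Results style: construct from
    the target set and a config, ``fit()`` returns an
    :class:`SvddModel`."""

    def __init__(self, X: np.ndarray, config: SvddConfig | None = None, **kw):
        self.config = config or SvddConfig(**kw)
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.X.ndim != 2:
            raise ValueError("training data must be (N, dim)")
        if len(self.X) < 1:
            raise ValueError("need at least one training point")
        if self.config.C < 1.0 / len(self.X) - 1e-12:
            raise ValueError(
                f"C={self.config.C} infeasible: sum(alpha)=1 needs C >= 1/N")

    def fit(self) -> SvddModel:
        cfg = self.config
        if cfg.k_clusters > 1:
            return dac_train(self.X, cfg)
        K = _kernel_matrix(self.X, self.X, cfg)
        alpha = _solve_dual(K, cfg.C, cfg.tol)
        self_term = float(alpha @ K @ alpha)
        model = SvddModel(config=cfg, X=self.X, alphas=alpha, r2=0.0,
                          self_term=self_term)
        # radius from the boundary support vectors (0 < alpha < C); if the
        # solution leaves none unbounded, fall back to the farthest SV
        d2_train = model.distance2(self.X)
        unbounded = (alpha > cfg.tol) & (alpha < cfg.C - cfg.tol)
        sv = alpha > cfg.tol
        if unbounded.any():
            model.r2 = float(max(d2_train[unbounded].mean(), 0.0))
        else:
            model.r2 = float(max(d2_train[sv].max(), 0.0))
        return model


def svdd_train(X: np.ndarray, cfg: SvddConfig | None = None, **kw) -> SvddModel:
    """Train a plain SVDD (functional wrapper over :class:`SVDD`)."""
    return SVDD(X, cfg, **kw).fit()


def svdd_distance2(model: SvddModel, z: np.ndarray) -> np.ndarray | float:
    """Squared kernel distance of ``z`` to the fitted centre."""
    d2 = model.distance2(z)
    return float(d2[0]) if np.ndim(z) == 1 else d2


def svdd_predict(model: SvddModel, z: np.ndarray):
    """Accept/reject decision: accept iff distance^2 <= R^2."""
    pred = model.predict(z)
    return int(pred[0]) if np.ndim(z) == 1 else pred


def dac_train(X: np.ndarray, cfg: SvddConfig) -> SvddModel:
    """Divide-and-conquer SVDD training.

    Seeded k-means partitions the target set; each cell is solved by a
    local SVDD (its penalty floored at 1/n_cell to keep the equality
    constraint feasible); the final sphere is trained on the union of
    the local support vectors with the original C, likewise floored.
    Records the k O((N/k)^3) work estimate of the decomposition.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    N = len(X)
    k = cfg.k_clusters
    if k > N:
        raise ValueError("k_clusters cannot exceed the number of points")
    plain_cfg = dataclasses.replace(cfg, k_clusters=1)
    if k == 1:
        return SVDD(X, plain_cfg).fit()

    km = KMeans(n_clusters=k, n_init=10, random_state=cfg.seed).fit(X)
    assign = km.labels_
    sv_rows = []
    sv_counts = []
    for c in np.unique(assign):
        sub = X[assign == c]
        local_cfg = dataclasses.replace(plain_cfg,
                                        C=max(cfg.C, 1.0 / len(sub)))
        local = SVDD(sub, local_cfg).fit()
        sv_rows.append(sub[local.sv_index])
        sv_counts.append(len(local.sv_index))
    pooled = np.vstack(sv_rows)
    final_cfg = dataclasses.replace(plain_cfg, C=max(cfg.C, 1.0 / len(pooled)))
    model = SVDD(pooled, final_cfg).fit()
    model.n_local_sv = int(sum(sv_counts))
    model.work_estimate = k * (N / k) ** 3
    return model


def grid_search(target: np.ndarray, outliers: np.ndarray,
                sigmas, Cs, cv_folds: int = 3, seed: int = 0):
    """Exhaustive (sigma, C) search by one-class cross-validation.

    For every grid cell the target set is split into ``cv_folds``
    folds; the model trains on the remaining folds and is scored by the
    mean of the held-out-target accept rate and the outlier reject
    rate. Ties break toward smaller C, then smaller sigma. Returns the
    best (sigma, C) and the full score table.
    """
    target = np.atleast_2d(np.asarray(target, dtype=float))
    outliers = np.atleast_2d(np.asarray(outliers, dtype=float)) \
        if len(np.asarray(outliers)) else np.empty((0, target.shape[1]))
    rows = []
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    for sigma in sigmas:
        for C in Cs:
            scores = []
            for tr, te in kf.split(target):
                cfg = SvddConfig(C=max(C, 1.0 / len(tr)), sigma=sigma,
                                 seed=seed)
                model = SVDD(target[tr], cfg).fit()
                accept = float((model.predict(target[te]) == 1).mean())
                if len(outliers):
                    reject = float((model.predict(outliers) == -1).mean())
                    scores.append((accept + reject) / 2.0)
                else:
                    scores.append(accept)
            rows.append({"sigma": float(sigma), "C": float(C),
                         "score": float(np.mean(scores))})
    # deterministic tie-break: best score, then smaller C, then smaller sigma
    best = max(rows, key=lambda r: (r["score"], -r["C"], -r["sigma"]))
    return (best["sigma"], best["C"]), rows


class SvddClassifier:
    """sklearn-style binary adapter for the CV harness.

    ``fit`` trains the hypersphere on the target class only (label
    +1); ``predict`` accepts/rejects; ``score_samples`` exposes the
    continuous acceptance score for ROC construction.
    """

    def __init__(self, config: SvddConfig | None = None, **kw):
        self.config = config or SvddConfig(**kw)
        self.model_: SvddModel | None = None

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        target = X[np.asarray(y) == 1]
        if len(target) == 0:
            raise ValueError("no target-class samples to train on")
        cfg = dataclasses.replace(self.config,
                                  C=max(self.config.C, 1.0 / len(target)))
        self.model_ = SVDD(target, cfg).fit()
        return self

    def predict(self, X):
        return self.model_.predict(X)

    def score_samples(self, X):
        return self.model_.score_samples(X)
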