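"""Expectation-maximization clustering of mixed categorical/continuous cases.

The case memory is organized as a finite mixture: each latent cluster k has
a mixing weight pi_k and, under a within-cluster independence (naive)
factorization, a category-probability vector for every categorical
attribute and a univariate Gaussian for every continuous attribute.  The
E-step applies Bayes' theorem to obtain each record's posterior cluster
membership (its *responsibilities*); the M-step re-estimates parameters by
responsibility-weighted maximum likelihood, with Laplace smoothing on
category counts and a variance floor to keep the model proper.

With the Laplace term interpreted as a Dirichlet prior, the alternation is
MAP-EM and the recorded training objective (data log-likelihood plus the
log-prior of the category tables) never decreases; that objective is what
``loglik_trace`` stores.

The number of clusters is selected by K-fold cross-validated held-out
log-likelihood: K grows until the relative improvement over the previous
K drops to the threshold (default 1e-6).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .case_model import EncodedFrame

_LOG2PI = float(np.log(2.0 * np.pi))


class DataSizeError(ValueError):
    """More clusters requested than records available."""


@dataclass
class EMModel:
    """Fitted mixture parameters for mixed-type records."""

    weights: np.ndarray                 # (K,)
    cat_probs: list[np.ndarray]         # per categorical attr: (K, L_j)
    means: np.ndarray                   # (K, p_real)
    variances: np.ndarray               # (K, p_real)
    cat_names: list[str]
    cat_levels: list[int]
    real_names: list[str]
    alpha: float
    var_floor: float
    loglik_trace: list[float] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.weights)

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "cat_probs": [p.tolist() for p in self.cat_probs],
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "cat_names": list(self.cat_names),
            "cat_levels": list(self.cat_levels),
            "real_names": list(self.real_names),
            "alpha": self.alpha,
            "var_floor": self.var_floor,
            "loglik_trace": list(self.loglik_trace),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EMModel":
        return cls(
            weights=np.asarray(d["weights"], dtype=float),
            cat_probs=[np.asarray(p, dtype=float) for p in d["cat_probs"]],
            means=np.asarray(d["means"], dtype=float),
            variances=np.asarray(d["variances"], dtype=float),
            cat_names=list(d["cat_names"]),
            cat_levels=list(d["cat_levels"]),
            real_names=list(d["real_names"]),
            alpha=float(d["alpha"]),
            var_floor=float(d["var_floor"]),
            loglik_trace=list(d["loglik_trace"]),
        )


def _log_joint(model: EMModel, frame: EncodedFrame) -> np.ndarray:
    """log [ pi_k * p(x | k) ] for every record and cluster; shape (n, K)."""
    n = frame.n
    K = model.n_clusters
    ll = np.tile(np.log(model.weights)[None, :], (n, 1))
    for j in range(len(model.cat_names)):
        logp = np.log(model.cat_probs[j])           # (K, L)
        ll += logp[:, frame.cat[:, j]].T            # (n, K)
    for j in range(len(model.real_names)):
        x = frame.real[:, j][:, None]               # (n, 1)
        mu = model.means[:, j][None, :]             # (1, K)
        var = model.variances[:, j][None, :]
        ll += -0.5 * (_LOG2PI + np.log(var) + (x - mu) ** 2 / var)
    return ll


def _m_step(
    frame: EncodedFrame, R: np.ndarray, alpha: float, var_floor: float
) -> tuple[np.ndarray, list[np.ndarray], np.ndarray, np.ndarray]:
    n, K = R.shape
    Nk = R.sum(axis=0)
    weights = np.maximum(Nk, 1e-12) / np.maximum(Nk, 1e-12).sum()
    cat_probs: list[np.ndarray] = []
    for j, L in enumerate(frame.cat_levels):
        counts = np.zeros((K, L))
        codes = frame.cat[:, j]
        for k in range(K):
            counts[k] = np.bincount(codes, weights=R[:, k], minlength=L)
        probs = (counts + alpha) / (Nk[:, None] + alpha * L)
        cat_probs.append(probs)
    p = len(frame.real_names)
    means = np.zeros((K, p))
    variances = np.ones((K, p))
    if p:
        denom = np.maximum(Nk, 1e-12)[:, None]
        means = (R.T @ frame.real) / denom
        ex2 = (R.T @ (frame.real**2)) / denom
        variances = np.maximum(ex2 - means**2, var_floor)
    return weights, cat_probs, means, variances


def _log_prior(model: EMModel) -> float:
    """Dirichlet (Laplace-smoothing) log-prior of the category tables."""
    if model.alpha <= 0:
        return 0.0
    return model.alpha * float(sum(np.log(p).sum() for p in model.cat_probs))


def em_fit(
    frame: EncodedFrame,
    K: int,
    tol: float = 1e-7,
    max_iter: int = 200,
    seed: int = 0,
    restarts: int = 5,
    alpha: float = 1.0,
    var_floor: float = 1e-6,
) -> EMModel:
    """Fit a K-component mixture by (MAP-)EM with random restarts.

    The best of ``restarts`` runs (by final training objective) is kept;
    all randomness derives from ``seed``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if tol <= 0:
        raise ValueError("tol must be positive")
    if frame.n < K:
        raise DataSizeError(f"{frame.n} records cannot support {K} clusters")
    ss = np.random.SeedSequence(seed)
    best: EMModel | None = None
    for child in ss.spawn(max(restarts, 1)):
        rng = np.random.default_rng(child)
        model = _em_single(frame, K, tol, max_iter, rng, alpha, var_floor)
        if best is None or model.loglik_trace[-1] > best.loglik_trace[-1]:
            best = model
    return best


def _em_single(
    frame: EncodedFrame,
    K: int,
    tol: float,
    max_iter: int,
    rng: np.random.Generator,
    alpha: float,
    var_floor: float,
) -> EMModel:
    n = frame.n
    # seed each cluster from a distinct random case: category tables lean
    # toward the seed's codes, Gaussians sit on the seed's values with the
    # global variance.  This breaks the symmetry that a random hard
    # assignment leaves intact (every random subset looks like the data).
    seeds = rng.choice(n, size=K, replace=False)
    smooth = max(alpha, 0.5)
    cat_probs = []
    for j, L in enumerate(frame.cat_levels):
        probs = np.full((K, L), smooth / (1.0 + smooth * L))
        probs[np.arange(K), frame.cat[seeds, j]] += 1.0 / (1.0 + smooth * L)
        cat_probs.append(probs / probs.sum(axis=1, keepdims=True))
    p = len(frame.real_names)
    if p:
        global_var = np.maximum(frame.real.var(axis=0), var_floor)
        means = frame.real[seeds].copy()
        variances = np.tile(global_var, (K, 1))
    else:
        means = np.zeros((K, 0))
        variances = np.ones((K, 0))
    model = EMModel(
        weights=np.full(K, 1.0 / K),
        cat_probs=cat_probs,
        means=means,
        variances=variances,
        cat_names=frame.cat_names,
        cat_levels=frame.cat_levels,
        real_names=frame.real_names,
        alpha=alpha,
        var_floor=var_floor,
    )
    lj = _log_joint(model, frame)
    R = np.exp(lj - logsumexp(lj, axis=1)[:, None])
    prev_obj = -np.inf
    for _ in range(max_iter):
        model.weights, model.cat_probs, model.means, model.variances = _m_step(
            frame, R, alpha, var_floor
        )
        lj = _log_joint(model, frame)
        per_record = logsumexp(lj, axis=1)
        obj = float(per_record.sum()) + _log_prior(model)
        model.loglik_trace.append(obj)
        R = np.exp(lj - per_record[:, None])
        if np.isfinite(prev_obj) and abs(obj - prev_obj) <= tol * max(1.0, abs(prev_obj)):
            break
        prev_obj = obj
    return model


def responsibilities(model: EMModel, frame: EncodedFrame) -> np.ndarray:
    """Posterior cluster-membership probabilities; shape (n, K), rows sum to 1."""
    lj = _log_joint(model, frame)
    return np.exp(lj - logsumexp(lj, axis=1)[:, None])


def hard_labels(model: EMModel, frame: EncodedFrame) -> np.ndarray:
    return np.argmax(_log_joint(model, frame), axis=1)


def heldout_loglik(model: EMModel, frame: EncodedFrame) -> float:
    """Mean per-record log mixture density/mass of held-out records."""
    if frame.n == 0:
        raise ValueError("held-out data must be nonempty")
    return float(logsumexp(_log_joint(model, frame), axis=1).mean())


def select_k(
    frame: EncodedFrame,
    k_max: int,
    threshold: float = 1e-6,
    folds: int = 10,
    seed: int = 0,
    restarts: int = 3,
    tol: float = 1e-6,
    max_iter: int = 150,
    alpha: float = 1.0,
    var_floor: float = 1e-6,
) -> tuple[int, pd.DataFrame]:
    """Choose the cluster count by cross-validated held-out log-likelihood.

    K is increased from 1; at each K the mean ``folds``-fold held-out
    log-likelihood is computed, and the search stops — returning the
    previous K — as soon as the relative improvement over the previous K
    is at or below ``threshold``.  The per-(K, fold) table is returned for
    inspection.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if frame.n < folds:
        raise DataSizeError(f"{frame.n} records cannot support {folds} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(frame.n)
    fold_idx = np.array_split(order, folds)
    ss = np.random.SeedSequence(rng.integers(0, 2**31 - 1))
    rows: list[dict] = []
    mean_ll: dict[int, float] = {}
    chosen = k_max
    for k in range(1, k_max + 1):
        fold_ll = []
        for f, test_idx in enumerate(fold_idx):
            train_idx = np.concatenate([fold_idx[g] for g in range(folds) if g != f])
            fit_seed = int(np.random.default_rng(ss.spawn(1)[0]).integers(0, 2**31 - 1))
            model = em_fit(
                frame.select(train_idx),
                k,
                tol=tol,
                max_iter=max_iter,
                seed=fit_seed,
                restarts=restarts,
                alpha=alpha,
                var_floor=var_floor,
            )
            fold_ll.append(heldout_loglik(model, frame.select(test_idx)))
        mean_ll[k] = float(np.mean(fold_ll))
        rows.append({"k": k, **{f"fold_{f}": v for f, v in enumerate(fold_ll)}, "mean": mean_ll[k]})
        if k >= 2:
            rel = (mean_ll[k] - mean_ll[k - 1]) / abs(mean_ll[k - 1])
            if rel <= threshold:
                chosen = k - 1
                break
    table = pd.DataFrame(rows).set_index("k")
    return chosen, table
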