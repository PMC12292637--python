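"""Unsupervised clustering of latent features by mutual-information maximization.

A small feed-forward head maps each latent feature vector to cluster
probabilities p(y|x). Training maximizes the mutual information between
inputs and assignments, I(X;Y) = H(Y) - H(Y|X): the marginal-entropy term
pushes toward balanced clusters while the conditional-entropy term pushes
each sample toward a confident, single-cluster assignment. A
self-augmented-training (SAT) consistency term — the KL divergence from the
head's prediction on a sample (held fixed) to its prediction on a
transformed version of the same sample — keeps assignments stable under
rotation, translation and scaling; it is the system's "transformation
loss". All entropies use the natural logarithm, so 0 <= I <= ln K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .errors import InvalidArgument, NumericError

__all__ = [
    "augment_tile",
    "SoftAssignment",
    "ClusteringObjectiveReport",
    "ClusteringConfig",
    "ClusterHead",
    "latent_features",
    "mi_objective",
    "sat_loss",
    "train_clustering",
    "hard_labels",
]

_EPS = 1e-12


def augment_tile(pixels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A random SAT transformation of one tile: 90-degree rotation, integer
    translation (wrap-around), or +/-10% isotropic rescaling."""
    from scipy.ndimage import zoom as nd_zoom

    op = rng.integers(0, 3)
    size = pixels.shape[0]
    if op == 0:
        return np.rot90(pixels, k=int(rng.integers(1, 4)), axes=(0, 1)).copy()
    if op == 1:
        dy, dx = rng.integers(-size // 8, size // 8 + 1, size=2)
        return np.roll(pixels, (int(dy), int(dx)), axis=(0, 1))
    factor = 1.0 + rng.uniform(-0.1, 0.1)
    scaled = np.clip(nd_zoom(pixels, (factor, factor, 1.0), order=1), 0.0, 1.0)
    s = scaled.shape[0]
    if s >= size:  # center crop
        o = (s - size) // 2
        return scaled[o : o + size, o : o + size]
    out = np.ones((size, size, 3)) * pixels.mean(axis=(0, 1))
    o = (size - s) // 2
    out[o : o + s, o : o + s] = scaled
    return out


def latent_features(q, mode: str = "mean-pool") -> np.ndarray:
    """Reduce a quantized latent's embedded grid (h, w, d) to a feature vector.

    ``flatten`` keeps the full h*w*d layout; ``mean-pool`` averages over the
    spatial grid, giving a d-dimensional vector.
    """
    grid = np.asarray(q.embedded if hasattr(q, "embedded") else q, dtype=np.float64)
    if grid.ndim != 3:
        raise InvalidArgument("expected an h x w x d latent grid")
    if mode == "flatten":
        return grid.reshape(-1)
    if mode == "mean-pool":
        return grid.mean(axis=(0, 1))
    raise InvalidArgument(f"unknown mode {mode!r}; use 'flatten' or 'mean-pool'")


@dataclass
class SoftAssignment:
    """An n x K matrix of cluster probabilities; rows lie on the simplex."""

    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 2:
            raise InvalidArgument("probs must be an n x K matrix")
        if self.probs.min() < -1e-12:
            raise InvalidArgument("probabilities must be non-negative")
        if np.abs(self.probs.sum(axis=1) - 1.0).max() > 1e-6:
            raise InvalidArgument("each row must sum to 1 within 1e-6")

    @property
    def n(self) -> int:
        return self.probs.shape[0]

    @property
    def K(self) -> int:
        return self.probs.shape[1]


@dataclass
class ClusteringObjectiveReport:
    """Entropy decomposition of the clustering objective for one evaluation."""

    h_marginal: float
    h_conditional: float
    mutual_info: float
    sat_loss: float = 0.0

    @property
    def total(self) -> float:
        # the maximized quantity: mutual information minus the SAT penalty
        return self.mutual_info - self.sat_loss


def _entropy(p: np.ndarray, axis=None) -> np.ndarray:
    plogp = np.where(p > 0, p * np.log(np.maximum(p, _EPS)), 0.0)
    return -plogp.sum(axis=axis)


def mi_objective(assignment: SoftAssignment) -> ClusteringObjectiveReport:
    """H(Y), H(Y|X) and their difference for a soft assignment.

    H(Y) is the entropy of the column means; H(Y|X) the mean row entropy.
    """
    p = assignment.probs
    h_marg = float(_entropy(p.mean(axis=0)))
    h_cond = float(_entropy(p, axis=1).mean())
    return ClusteringObjectiveReport(
        h_marginal=h_marg, h_conditional=h_cond, mutual_info=h_marg - h_cond
    )


class ClusterHead(nn.Module):
    """Feature -> cluster-probability head: linear, SiLU, linear, softmax.

    Inputs are standardized with moments fixed at fit time so the head is a
    deterministic function of its parameters thereafter.
    """

    def __init__(self, p: int, K: int, hidden: int = 64, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.p, self.K = p, K
        self.fc1 = nn.Linear(p, hidden, rng)
        self.fc2 = nn.Linear(hidden, K, rng)
        self._mu = np.zeros(p)
        self._sigma = np.ones(p)

    def fit_standardizer(self, X: np.ndarray) -> None:
        self._mu = X.mean(axis=0)
        self._sigma = np.maximum(X.std(axis=0), 1e-8)

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=np.float64) - self._mu) / self._sigma

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        """Log-probabilities for a batch of standardized features."""
        return nn.log_softmax(self.fc2(nn.silu(self.fc1(x))), axis=1)

    def log_probs_t(self, X: np.ndarray) -> nn.Tensor:
        return self.forward(nn.Tensor(self._standardize(X)))

    def predict(self, X: np.ndarray) -> SoftAssignment:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        return SoftAssignment(np.exp(self.log_probs_t(X).data))


def sat_loss(head: ClusterHead, features: np.ndarray, augmented: np.ndarray) -> float:
    """Mean KL(p(y|x) || p(y|augmented x)) with the first factor held fixed."""
    features = np.atleast_2d(features)
    augmented = np.atleast_2d(augmented)
    if features.shape[0] != augmented.shape[0]:
        raise InvalidArgument("features and augmented must be positionally paired")
    p = head.predict(features).probs
    q = head.predict(augmented).probs
    return float(_kl_rows(p, q).mean())


def _kl_rows(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    logratio = np.log(np.maximum(p, _EPS)) - np.log(np.maximum(q, _EPS))
    return np.where(p > 0, p * logratio, 0.0).sum(axis=1)


def hard_labels(assignment: SoftAssignment) -> np.ndarray:
    """Argmax per row; ties resolve to the lowest cluster index."""
    return np.argmax(assignment.probs, axis=1)


@dataclass
class ClusteringConfig:
    epochs: int = 300
    lr: float = 5e-3
    hidden: int = 64
    mu_sat: float = 1.0
    marginal_weight: float = 1.0
    n_restarts: int = 5
    seed: int = 0


def train_clustering(
    features: np.ndarray,
    K: int,
    config: ClusteringConfig | None = None,
    augmented_features: np.ndarray | None = None,
) -> tuple[ClusterHead, SoftAssignment, list[ClusteringObjectiveReport]]:
    """Fit the clustering head by full-batch gradient ascent on MI - mu*SAT.

    ``augmented_features`` (positionally paired with ``features``) enables
    the SAT consistency term; without them the objective is pure mutual
    information. The objective is non-convex, so ``n_restarts`` heads are
    trained from different initializations and the one with the best final
    objective is kept.
    """
    if config is None:
        config = ClusteringConfig()
    best: tuple[float, ClusterHead, SoftAssignment, list[ClusteringObjectiveReport]] | None = None
    for r in range(max(config.n_restarts, 1)):
        head, assign, history = _train_clustering_once(
            features, K, config, augmented_features, init_seed=config.seed + 1000 * r
        )
        objective = history[-1].total
        if best is None or objective > best[0]:
            best = (objective, head, assign, history)
    return best[1], best[2], best[3]


def _train_clustering_once(
    features: np.ndarray,
    K: int,
    config: ClusteringConfig,
    augmented_features: np.ndarray | None,
    init_seed: int,
) -> tuple[ClusterHead, SoftAssignment, list[ClusteringObjectiveReport]]:
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2:
        raise InvalidArgument("features must be an n x p matrix")
    n, p = X.shape
    if not 2 <= K <= n:
        raise InvalidArgument(f"need n >= K >= 2, got n={n}, K={K}")
    if augmented_features is not None:
        augmented_features = np.asarray(augmented_features, dtype=np.float64)
        if augmented_features.shape != X.shape:
            raise InvalidArgument("augmented_features must match features in shape")

    head = ClusterHead(p, K, hidden=config.hidden, seed=init_seed)
    head.fit_standardizer(X)
    opt = nn.Adam(head.parameters(), lr=config.lr)
    history: list[ClusteringObjectiveReport] = []

    for _ in range(config.epochs):
        opt.zero_grad()
        logp = head.log_probs_t(X)
        prob = logp.exp()
        marginal = prob.mean(axis=0)
        h_marg = -(marginal * (marginal + _EPS).log()).sum()
        h_cond = -(prob * logp).sum(axis=1).mean()
        mi = config.marginal_weight * h_marg - h_cond
        loss = -mi
        sat_val = 0.0
        if augmented_features is not None and config.mu_sat > 0:
            target = prob.detach()
            logq = head.log_probs_t(augmented_features)
            kl = (target * (target + _EPS).log()).sum(axis=1) - (target * logq).sum(axis=1)
            sat = kl.mean()
            loss = loss + config.mu_sat * sat
            sat_val = sat.item()
        if not np.isfinite(loss.item()):
            raise NumericError("clustering objective became non-finite")
        loss.backward()
        opt.step()
        history.append(
            ClusteringObjectiveReport(
                h_marginal=h_marg.item(),
                h_conditional=h_cond.item(),
                mutual_info=h_marg.item() - h_cond.item(),
                sat_loss=sat_val,
            )
        )

    return head, head.predict(X), history
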