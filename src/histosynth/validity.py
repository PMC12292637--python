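"""Internal cluster-validity indices and consensus selection of k.

Five label-free quality scores for a clustering of points in Euclidean
space, and a direction-aware majority vote across them:

* Calinski–Harabasz (maximize): trace(B_k)/trace(W_k) x (n-k)/(k-1).
* C index (minimize): (S - S_min)/(S_max - S_min), with S the sum of
  intra-cluster pairwise distances and S_min/S_max the sums of the n_w
  smallest/largest distances in the global pairwise pool (Hubert–Levin).
* Dunn (maximize): min single-linkage inter-cluster distance over max
  cluster diameter.
* Hartigan (maximize): ln(SSB/SSW), between- over within-cluster sum of
  squares.
* McClain–Rao (minimize): mean intra-cluster distance over mean
  inter-cluster distance.

All distances are Euclidean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import DegenerateInput, InvalidArgument

__all__ = [
    "LabeledPointSet",
    "IndexReport",
    "calinski_harabasz",
    "c_index",
    "dunn",
    "hartigan",
    "mcclain_rao",
    "compute_index_report",
    "consensus_select_k",
    "INDEX_DIRECTIONS",
]

#: larger-is-better (+1) or smaller-is-better (-1) for each index
INDEX_DIRECTIONS = {
    "ch": +1,
    "c_index": -1,
    "dunn": +1,
    "hartigan": +1,
    "mcclain_rao": -1,
}


@dataclass
class LabeledPointSet:
    """Points with hard cluster labels; every cluster must be non-empty."""

    points: np.ndarray
    labels: np.ndarray
    k: int

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.points.ndim != 2:
            raise InvalidArgument("points must be an n x p matrix")
        n = self.points.shape[0]
        if self.labels.shape != (n,):
            raise InvalidArgument("labels must have one entry per point")
        if self.k < 2:
            raise InvalidArgument("k must be >= 2")
        if n <= self.k:
            raise InvalidArgument(f"need n > k, got n={n}, k={self.k}")
        present = np.unique(self.labels)
        if present.min() < 0 or present.max() >= self.k:
            raise InvalidArgument("labels must lie in [0, k)")
        if len(present) != self.k:
            raise InvalidArgument("every cluster in [0, k) must be non-empty")

    @property
    def n(self) -> int:
        return self.points.shape[0]


@dataclass
class IndexReport:
    """The five validity indices evaluated for one cluster count k."""

    k: int
    ch: float
    c_index: float
    dunn: float
    hartigan: float
    mcclain_rao: float


def _scatter_traces(ps: LabeledPointSet) -> tuple[float, float]:
    """(trace B_k, trace W_k) == (SSB, SSW) for Euclidean scatter matrices."""
    grand = ps.points.mean(axis=0)
    ssb = 0.0
    ssw = 0.0
    for c in range(ps.k):
        members = ps.points[ps.labels == c]
        centroid = members.mean(axis=0)
        ssb += len(members) * float(np.sum((centroid - grand) ** 2))
        ssw += float(np.sum((members - centroid) ** 2))
    return ssb, ssw


def calinski_harabasz(ps: LabeledPointSet) -> float:
    ssb, ssw = _scatter_traces(ps)
    if ssw <= 0.0:
        raise DegenerateInput("within-cluster scatter is zero")
    return (ssb / ssw) * (ps.n - ps.k) / (ps.k - 1)


def hartigan(ps: LabeledPointSet) -> float:
    ssb, ssw = _scatter_traces(ps)
    if ssw <= 0.0 or ssb <= 0.0:
        raise DegenerateInput("SSB and SSW must both be positive")
    return float(np.log(ssb / ssw))


def _intra_mask(labels: np.ndarray) -> np.ndarray:
    """Condensed-form boolean mask of same-cluster pairs, matching pdist order."""
    same = labels[:, None] == labels[None, :]
    return squareform(same, checks=False).astype(bool)


def c_index(ps: LabeledPointSet) -> float:
    d = pdist(ps.points)
    intra = _intra_mask(ps.labels)
    n_w = int(intra.sum())
    if n_w == 0:
        raise DegenerateInput("no intra-cluster pair exists")
    s = float(d[intra].sum())
    d_sorted = np.sort(d)
    s_min = float(d_sorted[:n_w].sum())
    s_max = float(d_sorted[-n_w:].sum())
    if s_max <= s_min:
        raise DegenerateInput("all pairwise distances are equal")
    return (s - s_min) / (s_max - s_min)


def dunn(ps: LabeledPointSet) -> float:
    dm = squareform(pdist(ps.points))
    diam = 0.0
    for c in range(ps.k):
        idx = np.flatnonzero(ps.labels == c)
        if len(idx) > 1:
            diam = max(diam, float(dm[np.ix_(idx, idx)].max()))
    if diam <= 0.0:
        raise DegenerateInput("maximum cluster diameter is zero")
    sep = np.inf
    for a in range(ps.k):
        ia = np.flatnonzero(ps.labels == a)
        for b in range(a + 1, ps.k):
            ib = np.flatnonzero(ps.labels == b)
            sep = min(sep, float(dm[np.ix_(ia, ib)].min()))
    return sep / diam


def mcclain_rao(ps: LabeledPointSet) -> float:
    d = pdist(ps.points)
    intra = _intra_mask(ps.labels)
    n_w = int(intra.sum())
    n_b = int((~intra).sum())
    if n_w == 0 or n_b == 0:
        raise DegenerateInput("need at least one intra- and one inter-cluster pair")
    mean_inter = float(d[~intra].mean())
    if mean_inter <= 0.0:
        raise DegenerateInput("mean inter-cluster distance is zero")
    return float(d[intra].mean()) / mean_inter


def compute_index_report(ps: LabeledPointSet) -> IndexReport:
    return IndexReport(
        k=ps.k,
        ch=calinski_harabasz(ps),
        c_index=c_index(ps),
        dunn=dunn(ps),
        hartigan=hartigan(ps),
        mcclain_rao=mcclain_rao(ps),
    )


def consensus_select_k(reports: list[IndexReport]) -> tuple[int, dict[str, int]]:
    """Direction-aware majority vote across the five indices.

    Returns ``(selected_k, winners)`` where ``winners`` maps each index name
    to the k it prefers. The selected k is the one winning the most indices;
    ties go to the smallest tied k.
    """
    if len(reports) < 2:
        raise InvalidArgument("need at least two reports")
    ks = [r.k for r in reports]
    if len(set(ks)) != len(ks):
        raise InvalidArgument("duplicate k values in reports")
    winners: dict[str, int] = {}
    for name, direction in INDEX_DIRECTIONS.items():
        vals = [getattr(r, name) * direction for r in reports]
        best = max(range(len(reports)), key=lambda i: (vals[i], -ks[i]))
        winners[name] = ks[best]
    counts: dict[int, int] = {}
    for k in winners.values():
        counts[k] = counts.get(k, 0) + 1
    top = max(counts.values())
    selected = min(k for k, c in counts.items() if c == top)
    return selected, winners
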