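"""Clustering of per-stride synergies and activation patterns.

Each stride is decomposed independently (NNMF, smallest N reaching
>= 80% VAF); the pooled synergies and patterns are then partitioned by
k-means in cosine space (Euclidean k-means on unit-normalized vectors),
the number of clusters chosen by the Calinski-Harabasz index over
k = 2..20, and cluster membership quality-controlled with a cosine
silhouette: items with silhouette <= 0.2 are left unmatched.
"""
from __future__ import annotations

import warnings

import numpy as np
from sklearn.cluster import KMeans

from .containers import CYCLE_SAMPLES, ClusterResult, EmgEnvelopeSet
from .decomposition import decompose

VAF_THRESHOLD = 80.0
SILHOUETTE_THRESHOLD = 0.2


def per_stride_decompose(
    emg: EmgEnvelopeSet,
    vaf_threshold: float = VAF_THRESHOLD,
    max_n: int = 8,
    restarts: int = 20,
    seed=None,
) -> dict:
    """NNMF each stride separately at the smallest N reaching the VAF threshold.

    Returns pooled ``synergies`` (n_items, n_muscles), ``patterns``
    (n_items, 200), the per-stride module count ``n_by_stride`` and a
    provenance index ``stride_of`` per pooled item.  A stride that never
    reaches the threshold is retained at ``max_n`` with a warning.
    """
    rng = np.random.default_rng(seed)
    syn, pat, n_by_stride, stride_of = [], [], [], []
    for s in range(emg.n_strides):
        stride = emg.data[:, s * CYCLE_SAMPLES:(s + 1) * CYCLE_SAMPLES]
        chosen = None
        for n in range(1, max_n + 1):
            res = decompose(stride, "spatial", "nnmf", n, restarts, rng)
            if res.vaf >= vaf_threshold:
                chosen = res
                break
        if chosen is None:
            warnings.warn(
                f"stride {s}: VAF below {vaf_threshold}% even at N={max_n}; retained"
            )
            chosen = res
        n_by_stride.append(chosen.n_modules)
        for i in range(chosen.n_modules):
            syn.append(chosen.synergies[i])
            pat.append(chosen.patterns[0, i])  # single-stride: one pattern set
            stride_of.append(s)
    return {
        "synergies": np.array(syn),
        "patterns": np.array(pat),
        "n_by_stride": np.array(n_by_stride),
        "stride_of": np.array(stride_of),
    }


def _unit_rows(X: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return X / norms


def calinski_harabasz(X: np.ndarray, labels: np.ndarray) -> float:
    """CH index: (SS_B / SS_W) * (N - k) / (k - 1) with L2 norms.

    ``X`` is expected already in the space where distances are measured
    (unit-normalized rows for the cosine-space clustering used here).
    """
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    ks = np.unique(labels)
    k = ks.size
    n = X.shape[0]
    if k < 2:
        raise ValueError("need at least two clusters")
    m = X.mean(axis=0)
    ss_b = ss_w = 0.0
    for c in ks:
        Xi = X[labels == c]
        mi = Xi.mean(axis=0)
        ss_b += Xi.shape[0] * np.sum((mi - m) ** 2)
        ss_w += np.sum((Xi - mi) ** 2)
    if ss_w == 0:
        return np.inf
    return float((ss_b / ss_w) * (n - k) / (k - 1))


def cosine_silhouette(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Silhouette S_i = (b_i - a_i)/max(a_i, b_i) with distance 1 - cos.

    a_i: mean distance to the other members of i's cluster; b_i: minimum
    over other clusters of the mean distance to their members.
    Singleton clusters get S_i = 0.
    """
    Xn = _unit_rows(np.asarray(X, float))
    D = 1.0 - Xn @ Xn.T
    labels = np.asarray(labels)
    ks = np.unique(labels)
    n = X.shape[0]
    S = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own < 2:
            continue
        a = D[i, own].sum() / (n_own - 1)  # exclude self (distance 0)
        b = min(D[i, labels == c].mean() for c in ks if c != labels[i])
        S[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return S


class ModuleKMeans:
    """Cosine k-means with CH-based model selection and silhouette QC.

    Parameters
    ----------
    k_range : iterable of candidate cluster counts (default 2..20;
        truncated with a warning when the item count is insufficient).
    n_replicates : k-means restarts per k (best inertia kept).
    silhouette_threshold : items at or below it are flagged unmatched.
    random_state : int or Generator.

    Attributes after ``fit(X)``: ``ch_index_``, ``optimal_k_``,
    ``labels_``, ``silhouettes_``, ``retained_``, ``centroids_``
    (spherical: normalized cluster means).
    """

    def __init__(
        self,
        k_range=range(2, 21),
        n_replicates: int = 100,
        silhouette_threshold: float = SILHOUETTE_THRESHOLD,
        random_state=None,
    ):
        self.k_range = k_range
        self.n_replicates = n_replicates
        self.silhouette_threshold = silhouette_threshold
        self.random_state = random_state

    def get_params(self, deep=True):
        return {
            "k_range": self.k_range,
            "n_replicates": self.n_replicates,
            "silhouette_threshold": self.silhouette_threshold,
            "random_state": self.random_state,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X):
        X = np.asarray(X, float)
        ks = sorted(self.k_range)
        if X.shape[0] <= ks[0]:
            raise ValueError(
                f"need more than {ks[0]} items to cluster, got {X.shape[0]}"
            )
        if X.shape[0] <= ks[-1]:
            warnings.warn("fewer items than max k; k_range truncated")
            ks = [k for k in ks if k < X.shape[0]]
        rng = (
            self.random_state
            if isinstance(self.random_state, np.random.Generator)
            else np.random.default_rng(self.random_state)
        )
        Xn = _unit_rows(X)
        ch, labelings = [], []
        for k in ks:
            km = KMeans(
                n_clusters=k,
                n_init=self.n_replicates,
                random_state=int(rng.integers(2**31 - 1)),
            ).fit(Xn)
            ch.append(calinski_harabasz(Xn, km.labels_))
            labelings.append(km.labels_)
        best = int(np.argmax(ch))
        labels = labelings[best]
        sil = cosine_silhouette(X, labels)
        centroids = np.array(
            [_unit_rows(Xn[labels == c].mean(axis=0)[None])[0]
             for c in np.unique(labels)]
        )
        self.k_values_ = np.array(ks)
        self.ch_index_ = np.array(ch)
        self.optimal_k_ = int(ks[best])
        self.labels_ = labels
        self.silhouettes_ = sil
        self.retained_ = sil > self.silhouette_threshold
        self.centroids_ = centroids
        return self

    def to_result(self, entity: str = "patterns") -> ClusterResult:
        labels = self.labels_
        if entity == "patterns":
            # order pattern clusters chronologically by centroid peak time
            order = np.argsort(np.argmax(self.centroids_, axis=1), kind="stable")
            remap = np.empty_like(order)
            remap[order] = np.arange(order.size)
            labels = remap[labels]
            centroids = self.centroids_[order]
        else:
            centroids = self.centroids_
        return ClusterResult(
            entity=entity,
            k_values=self.k_values_,
            ch_index=self.ch_index_,
            optimal_k=self.optimal_k_,
            assignments=labels,
            silhouettes=self.silhouettes_,
            retained=self.retained_,
            centroids=centroids,
        )


def cluster(
    items: np.ndarray,
    entity: str = "patterns",
    k_range=range(2, 21),
    replicates: int = 100,
    seed=None,
) -> ClusterResult:
    """Functional wrapper around :class:`ModuleKMeans`."""
    est = ModuleKMeans(k_range=k_range, n_replicates=replicates, random_state=seed)
    return est.fit(items).to_result(entity)
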