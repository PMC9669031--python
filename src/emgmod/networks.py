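"""Intermuscular coherence networks.

Coordination between muscles in the frequency domain: raw EMG is
high-pass filtered at 30 Hz and rectified via the Hilbert envelope;
magnitude-squared coherence is estimated (Welch, Hann windows) between
every muscle pair; the pairs x frequency coherence matrix is decomposed
by NNMF into frequency components c_i(f) and pair loadings w_i, each
loading mapping onto a symmetric 8x8 weighted muscle network.  Network
topology is summarized by weighted betweenness-centrality (edge length
= 1/weight) and mean edge weight over all / intra-limb / inter-limb
edges.
"""
from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np
from scipy.signal import butter, coherence as welch_coherence, filtfilt, hilbert

from .containers import CYCLE_SAMPLES, DEFAULT_MUSCLES, CoherenceNetworkSet
from .decomposition import _nmf_best, vaf as vaf_percent

HIGHPASS_HZ = 30.0


def coherence_preprocess(raw: np.ndarray, sampling_rate: float) -> np.ndarray:
    """30 Hz high-pass, Hilbert-envelope rectification, per-channel centering."""
    raw = np.atleast_2d(np.asarray(raw, float))
    if sampling_rate <= 2 * HIGHPASS_HZ:
        raise ValueError(
            f"sampling_rate must exceed {2 * HIGHPASS_HZ} Hz, got {sampling_rate}"
        )
    b, a = butter(4, HIGHPASS_HZ / (sampling_rate / 2), "high")
    x = filtfilt(b, a, raw, axis=1)
    env = np.abs(hilbert(x, axis=1))
    return env - env.mean(axis=1, keepdims=True)


def muscle_pairs(muscle_labels=DEFAULT_MUSCLES, exclude_homologous: bool = False):
    """All C(n,2) muscle pairs; optionally drop homologous bilateral pairs.

    A homologous pair is the same muscle on the two limbs (e.g. BF and
    BF_CL); excluding the 4 of them reduces the default 28 pairs to 24.
    """
    pairs = list(combinations(muscle_labels, 2))
    if exclude_homologous:
        pairs = [
            (a, b)
            for a, b in pairs
            if a.replace("_CL", "") != b.replace("_CL", "")
        ]
    return pairs


def pairwise_coherence(
    envelopes: np.ndarray,
    sampling_rate: float,
    window_seconds: float = 1.0,
    overlap: float = 0.5,
    muscle_labels=DEFAULT_MUSCLES,
    exclude_homologous: bool = False,
    max_freq: float | None = None,
) -> CoherenceNetworkSet:
    """Welch magnitude-squared coherence between every muscle pair.

    Hann-tapered segments of ``window_seconds`` with fractional
    ``overlap``; at least two analysis windows are required (coherence
    is degenerate at 1 on a single window).
    """
    env = np.atleast_2d(np.asarray(envelopes, float))
    if env.shape[0] < 2:
        raise ValueError("need at least two channels")
    nper = int(round(window_seconds * sampling_rate))
    nover = int(round(overlap * nper))
    n_windows = 1 + max(0, (env.shape[1] - nper) // (nper - nover))
    if env.shape[1] < nper or n_windows < 2:
        raise ValueError("need at least two analysis windows for coherence")
    pairs = muscle_pairs(muscle_labels, exclude_homologous)
    idx = {lbl: i for i, lbl in enumerate(muscle_labels)}
    rows = []
    freqs = None
    for a, b in pairs:
        f, coh = welch_coherence(
            env[idx[a]], env[idx[b]], fs=sampling_rate,
            window="hann", nperseg=nper, noverlap=nover,
        )
        freqs = f
        rows.append(coh)
    coh = np.array(rows)
    if max_freq is not None:
        keep = freqs <= max_freq
        freqs, coh = freqs[keep], coh[:, keep]
    return CoherenceNetworkSet(
        pairs=pairs, frequencies=freqs, coherence=coh, muscle_labels=tuple(muscle_labels)
    )


def loadings_to_network(
    loading: np.ndarray, pairs, muscle_labels=DEFAULT_MUSCLES
) -> np.ndarray:
    """Map a pair-loading vector onto a symmetric zero-diagonal 8x8 matrix."""
    n = len(muscle_labels)
    idx = {lbl: i for i, lbl in enumerate(muscle_labels)}
    net = np.zeros((n, n))
    for w, (a, b) in zip(loading, pairs):
        net[idx[a], idx[b]] = net[idx[b], idx[a]] = w
    return net


class CoherenceNMF:
    """NNMF of the pairs x frequency coherence matrix,
    cohe(f) = sum_i c_i(f) w_i.

    ``fit(netset)`` stores ``components_`` (F x n_freqs, sorted by peak
    frequency), ``loadings_`` (F x n_pairs), ``networks_`` (F x 8 x 8)
    and ``vaf_``.  ``vaf_curve`` evaluates VAF over F = 1..f_max with
    either the nnmf or pca algorithm.
    """

    def __init__(
        self,
        n_components: int = 2,
        n_restarts: int = 20,
        max_iter: int = 500,
        tol: float = 1e-6,
        random_state=None,
    ):
        self.n_components = n_components
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def get_params(self, deep=True):
        return {
            "n_components": self.n_components,
            "n_restarts": self.n_restarts,
            "max_iter": self.max_iter,
            "tol": self.tol,
            "random_state": self.random_state,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, netset: CoherenceNetworkSet):
        X = netset.coherence  # (n_pairs, n_freqs)
        F = self.n_components
        if not 1 <= F <= X.shape[0]:
            raise ValueError("n_components must be in 1..n_pairs")
        rng = (
            self.random_state
            if isinstance(self.random_state, np.random.Generator)
            else np.random.default_rng(self.random_state)
        )
        W, H = _nmf_best(X, F, self.n_restarts, rng, self.max_iter, self.tol)
        # W: (n_pairs, F) loadings; H: (F, n_freqs) frequency components.
        # Normalize components to unit maximum, absorbing scale into loadings.
        peak = H.max(axis=1)
        peak[peak == 0] = 1.0
        H = H / peak[:, None]
        W = W * peak[None, :]
        order = np.argsort(np.argmax(H, axis=1), kind="stable")
        H, W = H[order], W[:, order]
        self.components_ = H
        self.loadings_ = W.T  # (F, n_pairs)
        self.networks_ = np.array(
            [
                loadings_to_network(w, netset.pairs, netset.muscle_labels)
                for w in self.loadings_
            ]
        )
        self.vaf_ = vaf_percent(X, W @ H, "zero")
        self.netset_ = netset
        return self

    def to_result(self) -> CoherenceNetworkSet:
        ns = self.netset_
        return CoherenceNetworkSet(
            pairs=ns.pairs,
            frequencies=ns.frequencies,
            coherence=ns.coherence,
            components=self.components_,
            loadings=self.loadings_,
            networks=self.networks_,
            muscle_labels=ns.muscle_labels,
        )


def decompose_coherence(
    netset: CoherenceNetworkSet,
    n_components: int,
    restarts: int = 20,
    seed=None,
) -> CoherenceNetworkSet:
    """Functional wrapper around :class:`CoherenceNMF`."""
    est = CoherenceNMF(n_components=n_components, n_restarts=restarts, random_state=seed)
    out = est.fit(netset).to_result()
    out.vaf_curve = None
    return out


def coherence_vaf_curve(
    netset: CoherenceNetworkSet,
    f_range=range(1, 9),
    algorithm: str = "nnmf",
    restarts: int = 20,
    seed=None,
) -> np.ndarray:
    """VAF of the coherence matrix reconstruction over module counts."""
    X = netset.coherence
    rng = np.random.default_rng(seed)
    vafs = []
    for F in f_range:
        if algorithm == "nnmf":
            W, H = _nmf_best(X, F, restarts, rng, 500, 1e-6)
            vafs.append(vaf_percent(X, W @ H, "zero"))
        else:
            from sklearn.decomposition import PCA

            pca = PCA(F)
            scores = pca.fit_transform(X)
            vafs.append(vaf_percent(X, pca.inverse_transform(scores), "mean"))
    return np.array(vafs)


def dimensionality_at_vaf(vaf_curve: np.ndarray, threshold: float = 80.0) -> int:
    """Smallest module count whose VAF reaches the threshold (last F if never)."""
    above = np.nonzero(vaf_curve >= threshold)[0]
    return int(above[0]) + 1 if above.size else len(vaf_curve)


def limb_edge_masks(muscle_labels=DEFAULT_MUSCLES):
    """Boolean masks (intra, inter) over the upper triangle of the 8x8 grid."""
    n = len(muscle_labels)
    limb = np.array([lbl.endswith("_CL") for lbl in muscle_labels])
    intra = np.zeros((n, n), bool)
    inter = np.zeros((n, n), bool)
    for i in range(n):
        for j in range(i + 1, n):
            if limb[i] == limb[j]:
                intra[i, j] = True
            else:
                inter[i, j] = True
    return intra, inter


def network_metrics(
    network: np.ndarray,
    component: np.ndarray | None = None,
    frequencies: np.ndarray | None = None,
    muscle_labels=DEFAULT_MUSCLES,
) -> dict:
    """Topological and spectral summaries of one coherence network.

    Returns per-node betweenness-centrality (weighted shortest paths,
    edge length = 1/weight; zero-weight edges absent), mean edge weight
    over all / intra-limb / inter-limb edge sets, and — when the
    frequency component is supplied — its 50% band (first to last
    half-maximum crossing).
    """
    A = np.asarray(network, float)
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T):
        raise ValueError("network must be a symmetric square matrix")
    if np.any(A < 0):
        raise ValueError("edge weights must be nonnegative")
    n = A.shape[0]
    G = nx.Graph()
    G.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if A[i, j] > 0:
                G.add_edge(i, j, weight=A[i, j], length=1.0 / A[i, j])
    betweenness = nx.betweenness_centrality(G, weight="length", normalized=True)
    isolated = [v for v in G.nodes if G.degree(v) == 0]
    intra, inter = limb_edge_masks(muscle_labels)
    iu = np.triu_indices(n, 1)
    out = {
        "betweenness": np.array([betweenness[i] for i in range(n)]),
        "mean_weight_global": float(A[iu].mean()),
        "mean_weight_intralimb": float(A[intra].mean()),
        "mean_weight_interlimb": float(A[inter].mean()),
        "disconnected_nodes": isolated,
    }
    if component is not None and frequencies is not None:
        c = np.asarray(component, float)
        half = c.max() / 2.0
        above = np.nonzero(c >= half)[0]
        out["band50"] = (float(frequencies[above[0]]), float(frequencies[above[-1]]))
    return out
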