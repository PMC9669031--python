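"""Modular decomposition of multi-muscle EMG envelopes.

Three factorization models of the muscles x time envelope matrix, all
expressed over strides s:

- spatial:       m^s(t) = sum_i c_i^s(t) w_i        (synergies shared,
                 per-stride activation patterns)
- temporal:      m^s(t) = sum_i c_i(t) w_i^s        (patterns shared,
                 per-stride synergies)
- space_by_time: m^s(t) = sum_ij c_i(t) a_ij^s w_j  (patterns and
                 synergies shared, per-stride NxN activation-coefficient
                 matrices; sample-based tri-factorization)

Dimensionality is selected from the slope of a cross-stride consistency
measure (pattern similarity, synergy similarity, or diagonality of the
activation-coefficient matrix) as the number of modules varies.
"""
from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.decomposition import NMF, PCA

from .containers import (
    CYCLE_SAMPLES,
    ConsistencyCurve,
    DecompositionResult,
    EmgEnvelopeSet,
)

MODELS = ("spatial", "temporal", "space_by_time")
ALGORITHMS = ("pca", "nnmf")


# ---------------------------------------------------------------------------
# elementary measures


def vaf(data: np.ndarray, reconstruction: np.ndarray, reference: str = "zero") -> float:
    """Percent of variance accounted for by a reconstruction.

    ``reference="zero"`` (NNMF convention) uses uncentered total power;
    ``reference="mean"`` (PCA convention) removes per-channel means first.
    """
    data = np.asarray(data, float)
    reconstruction = np.asarray(reconstruction, float)
    if data.shape != reconstruction.shape:
        raise ValueError("shape mismatch between data and reconstruction")
    if not np.any(data):
        raise ValueError("all-zero data: VAF undefined")
    if reference == "mean":
        ref = data - data.mean(axis=-1, keepdims=True)
    else:
        ref = data
    return float(100.0 * (1.0 - np.sum((data - reconstruction) ** 2) / np.sum(ref**2)))


def diagonality(A: np.ndarray) -> float:
    """Ratio of the diagonal sum to the total sum of a nonnegative square matrix."""
    A = np.asarray(A, float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("A must be square")
    if np.any(A < 0):
        raise ValueError("A must be elementwise nonnegative")
    tot = A.sum()
    if tot == 0:
        raise ValueError("all-zero activation matrix: diagonality undefined")
    return float(np.trace(A) / tot)


def _pairwise_cosine_mean(V: np.ndarray) -> float:
    """Mean cosine over all pairs of rows; zero-norm rows contribute 0."""
    norms = np.linalg.norm(V, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    Vn = V / safe[:, None]
    Vn[norms == 0] = 0.0
    G = Vn @ Vn.T
    iu = np.triu_indices(V.shape[0], 1)
    return float(G[iu].mean())


# ---------------------------------------------------------------------------
# sample-based nonnegative tri-factorization (space-by-time model)


def _snm3f(
    X: np.ndarray,
    n: int,
    rng: np.random.Generator,
    max_iter: int = 500,
    tol: float = 1e-6,
):
    """One run of multiplicative tri-factor updates.

    X is (S, T, M); returns C (T, n), A (S, n, n), W (n, M) and the final
    squared reconstruction error.  Per iteration the factors are updated
    in the order C, A, W, each by its multiplicative rule.
    """
    S, T, M = X.shape
    eps = 1e-12
    scale = np.sqrt(max(X.mean(), eps))
    C = rng.uniform(0.1, 1.0, (T, n)) * scale
    A = rng.uniform(0.1, 1.0, (S, n, n))
    W = rng.uniform(0.1, 1.0, (n, M)) * scale
    prev = np.inf
    for _ in range(max_iter):
        G = W @ W.T
        XWt = X @ W.T  # (S, T, n)
        At = A.transpose(0, 2, 1)
        C *= (XWt @ At).sum(axis=0) / (C @ ((A @ G) @ At).sum(axis=0) + eps)
        CtC = C.T @ C
        CtX = C.T @ X  # (S, n, M)
        A *= (CtX @ W.T) / (CtC @ A @ G + eps)
        At = A.transpose(0, 2, 1)
        W *= (At @ CtX).sum(axis=0) / ((At @ CtC @ A).sum(axis=0) @ W + eps)
        R = C @ (A @ W)  # (S, T, M)
        err = float(np.sum((X - R) ** 2))
        if prev - err < tol * max(prev, eps):
            break
        prev = err
    # push factor scales into A so that C columns and W rows are unit-norm
    dc = np.linalg.norm(C, axis=0)
    dw = np.linalg.norm(W, axis=1)
    dc[dc == 0] = 1.0
    dw[dw == 0] = 1.0
    C = C / dc
    W = W / dw[:, None]
    A = A * dc[None, :, None] * dw[None, None, :]
    return C, A, W, err


def _nmf_best(X: np.ndarray, n: int, restarts: int, rng, max_iter: int, tol: float):
    """Best-of-restarts multiplicative-update NMF of X (nonnegative)."""
    best = None
    scale = np.sqrt(max(X.mean(), 1e-12) / n)
    for _ in range(restarts):
        W0 = rng.uniform(0, 1, (X.shape[0], n)) * scale
        H0 = rng.uniform(0, 1, (n, X.shape[1])) * scale
        model = NMF(
            n_components=n, init="custom", solver="mu", max_iter=max_iter, tol=tol
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            W = model.fit_transform(X, W=W0, H=H0)
        H = model.components_
        err = np.sum((X - W @ H) ** 2)
        if best is None or err < best[0]:
            best = (err, W, H)
    return best[1], best[2]


# ---------------------------------------------------------------------------
# estimator


class ModularDecomposition:
    """Factorize an envelope set under one modularity model.

    Parameters
    ----------
    model : {"spatial", "temporal", "space_by_time"}
    algorithm : {"nnmf", "pca"}
        PCA is deterministic and supports the spatial and temporal
        models only; NNMF takes the best of ``n_restarts`` random
        initializations by squared residual.
    n_modules : int
    n_restarts : int
    max_iter, tol : NNMF stopping rule (relative residual change).
    random_state : int or numpy Generator

    Attributes (after ``fit``)
    --------------------------
    synergies_ : (N, M) or (S, N, M) for the temporal model
    patterns_ : (N, 200) or (S, N, 200) for the spatial model
    activation_coeffs_ : (S, N, N), space-by-time only
    vaf_ : float (percent)
    residuals_, reconstruction_ : same shape as the input data
    """

    def __init__(
        self,
        model: str = "space_by_time",
        algorithm: str = "nnmf",
        n_modules: int = 2,
        n_restarts: int = 100,
        max_iter: int = 500,
        tol: float = 1e-6,
        random_state=None,
    ):
        self.model = model
        self.algorithm = algorithm
        self.n_modules = n_modules
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    # minimal sklearn-compatible parameter plumbing
    def get_params(self, deep=True):
        return {
            k: getattr(self, k)
            for k in (
                "model",
                "algorithm",
                "n_modules",
                "n_restarts",
                "max_iter",
                "tol",
                "random_state",
            )
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def _validate(self, X) -> np.ndarray:
        if isinstance(X, EmgEnvelopeSet):
            X = X.data
        X = np.asarray(X, float)
        if X.ndim != 2 or X.shape[1] % CYCLE_SAMPLES:
            raise ValueError("X must be (n_muscles, n_strides * 200)")
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if not 1 <= self.n_modules <= X.shape[0]:
            raise ValueError("n_modules must be in 1..n_muscles")
        if self.algorithm == "nnmf" and np.any(X < 0):
            raise ValueError("NNMF requires nonnegative data")
        if self.model == "space_by_time" and self.algorithm == "pca":
            raise ValueError("space_by_time supports the nnmf algorithm only")
        return X

    def fit(self, X, y=None):
        X = self._validate(X)
        M, total = X.shape
        S = total // CYCLE_SAMPLES
        N = self.n_modules
        rng = (
            self.random_state
            if isinstance(self.random_state, np.random.Generator)
            else np.random.default_rng(self.random_state)
        )
        if self.model == "spatial":
            # X (M x S*200) = synergies^T (M x N) @ patterns (N x S*200)
            if self.algorithm == "nnmf":
                W, H = _nmf_best(X, N, self.n_restarts, rng, self.max_iter, self.tol)
                rec = W @ H
                self.vaf_ = vaf(X, rec, "zero")
            else:
                pca = PCA(N)
                scores = pca.fit_transform(X.T)  # samples=time
                rec = (pca.inverse_transform(scores)).T
                W = pca.components_.T  # (M, N)
                H = scores.T
                self.vaf_ = vaf(X, rec, "mean")
            self.synergies_ = W.T  # (N, M)
            self.patterns_ = H.reshape(N, S, CYCLE_SAMPLES).transpose(1, 0, 2)
            self.activation_coeffs_ = None
        elif self.model == "temporal":
            # arrange (200 x S*M): columns are muscle-stride profiles
            Xt = np.concatenate(
                [X[:, s * CYCLE_SAMPLES:(s + 1) * CYCLE_SAMPLES].T for s in range(S)],
                axis=1,
            )
            if self.algorithm == "nnmf":
                C, Wall = _nmf_best(Xt, N, self.n_restarts, rng, self.max_iter, self.tol)
                rec_t = C @ Wall
                self.vaf_ = vaf(Xt, rec_t, "zero")
            else:
                pca = PCA(N)
                scores = pca.fit_transform(Xt.T)
                rec_t = pca.inverse_transform(scores).T
                C = pca.components_.T
                Wall = scores.T
                self.vaf_ = vaf(Xt, rec_t, "mean")
            self.patterns_ = C.T  # (N, 200)
            self.synergies_ = Wall.reshape(N, S, M).transpose(1, 0, 2)  # (S, N, M)
            rec = np.concatenate(
                [rec_t[:, s * M:(s + 1) * M].T for s in range(S)], axis=1
            )
            self.activation_coeffs_ = None
        else:  # space_by_time
            Xs = X.reshape(M, S, CYCLE_SAMPLES).transpose(1, 2, 0)  # (S, 200, M)
            best = None
            for _ in range(self.n_restarts):
                C, A, W, err = _snm3f(Xs, N, rng, self.max_iter, self.tol)
                if best is None or err < best[0]:
                    best = (err, C, A, W)
            _, C, A, W = best
            R = np.einsum("ti,sij,jm->stm", C, A, W)
            rec = R.transpose(2, 0, 1).reshape(M, total)
            self.patterns_ = C.T  # (N, 200)
            self.synergies_ = W  # (N, M)
            self.activation_coeffs_ = A  # (S, N, N)
            self.vaf_ = vaf(X, rec, "zero")
        self.reconstruction_ = rec
        self.residuals_ = X - rec
        self.n_strides_ = S
        self.data_ = X
        return self

    def to_result(self) -> DecompositionResult:
        return DecompositionResult(
            model=self.model,
            algorithm=self.algorithm,
            n_modules=self.n_modules,
            synergies=self.synergies_,
            patterns=self.patterns_,
            vaf=self.vaf_,
            residuals=self.residuals_,
            activation_coeffs=self.activation_coeffs_,
            reconstruction=self.reconstruction_,
        )


def decompose(
    data,
    model: str = "space_by_time",
    algorithm: str = "nnmf",
    n_modules: int = 2,
    restarts: int = 100,
    seed=None,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> DecompositionResult:
    """Functional wrapper around :class:`ModularDecomposition`."""
    est = ModularDecomposition(
        model=model,
        algorithm=algorithm,
        n_modules=n_modules,
        n_restarts=restarts,
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    )
    return est.fit(data).to_result()


# ---------------------------------------------------------------------------
# module ordering and consistency


def _mean_patterns(result: DecompositionResult) -> np.ndarray:
    """Stride-averaged patterns, (N, 200)."""
    if result.patterns.ndim == 3:
        return result.patterns.mean(axis=0)
    return result.patterns


def sort_modules(result: DecompositionResult) -> DecompositionResult:
    """Order modules chronologically by pattern peak time.

    For the space-by-time model, the synergies are additionally permuted
    (optimal assignment on the stride-averaged activation-coefficient
    matrix) so that the coefficient matrix is as diagonal as possible.
    """
    mp = _mean_patterns(result)
    order = np.argsort(np.argmax(mp, axis=1), kind="stable")
    if result.patterns.ndim == 3:
        patterns = result.patterns[:, order]
    else:
        patterns = result.patterns[order]
    synergies = result.synergies
    coeffs = result.activation_coeffs
    if result.model == "space_by_time":
        coeffs = coeffs[:, order]
        Abar = coeffs.mean(axis=0)
        _, perm = linear_sum_assignment(-Abar)
        coeffs = coeffs[:, :, perm]
        synergies = synergies[perm]
    elif result.synergies.ndim == 3:  # temporal: per-stride synergies
        synergies = synergies[:, order]
    else:  # spatial: shared synergies follow the patterns
        synergies = synergies[order]
    return DecompositionResult(
        model=result.model,
        algorithm=result.algorithm,
        n_modules=result.n_modules,
        synergies=synergies,
        patterns=patterns,
        vaf=result.vaf,
        residuals=result.residuals,
        activation_coeffs=coeffs,
        reconstruction=result.reconstruction,
        sorted=True,
    )


def stride_consistency(result: DecompositionResult) -> float:
    """Cross-stride consistency of one decomposition.

    Spatial model: mean over modules of the mean pairwise cosine between
    per-stride activation patterns.  Temporal model: the same over
    per-stride synergies.  Space-by-time: mean diagonality of the
    per-stride activation-coefficient matrices after module sorting.
    """
    if result.model == "spatial":
        V = result.patterns  # (S, N, 200)
        if V.shape[0] < 2:
            raise ValueError("insufficient data: need >= 2 strides")
        return float(
            np.mean([_pairwise_cosine_mean(V[:, i]) for i in range(V.shape[1])])
        )
    if result.model == "temporal":
        V = result.synergies  # (S, N, M)
        if V.shape[0] < 2:
            raise ValueError("insufficient data: need >= 2 strides")
        return float(
            np.mean([_pairwise_cosine_mean(V[:, i]) for i in range(V.shape[1])])
        )
    # space_by_time
    res = result if result.sorted else sort_modules(result)
    A = res.activation_coeffs
    if A.shape[0] < 2:
        raise ValueError("insufficient data: need >= 2 strides")
    return float(np.mean([diagonality(a) for a in A]))


def select_dimensionality(
    consistencies: dict,
    vaf_by_n: dict | None = None,
    measure: str = "diagonality",
    low_vaf_threshold: float = 20.0,
    slope_margin: float = 0.01,
) -> ConsistencyCurve:
    """Pick the module count at the maximum consistency-slope.

    ``consistencies`` maps N (a contiguous range starting at 1) to the
    consistency value.  The slope at N is consistency(N) -
    consistency(N+1): the drop incurred by adding one module.  Ties
    break toward the smallest N.  Fallback: when the maximum sits at
    N = 1 while a single module accounts for < 20% of the data variance,
    the N of the second-highest slope is selected instead if that slope
    is within 0.01 of the maximum.
    """
    ns = sorted(consistencies)
    if ns != list(range(1, max(ns) + 1)):
        raise ValueError("consistencies must cover N = 1..n_max without gaps")
    values = np.array([consistencies[n] for n in ns])
    slopes = values[:-1] - values[1:]
    # ties (to numerical tolerance) break toward the smallest N
    tied = np.nonzero(slopes >= slopes.max() - 1e-12)[0]
    selected = int(tied[0]) + 1
    fallback = False
    if (
        selected == 1
        and vaf_by_n is not None
        and vaf_by_n.get(1, np.inf) < low_vaf_threshold
        and slopes.size > 1
    ):
        runner = int(np.argmax(slopes[1:])) + 1
        if slopes[0] - slopes[runner] < slope_margin:
            selected = runner + 1
            fallback = True
    return ConsistencyCurve(
        measure=measure,
        values=values,
        slopes=slopes,
        selected_n=selected,
        fallback_used=fallback,
        vaf_values=(
            np.array([vaf_by_n[n] for n in ns]) if vaf_by_n is not None else None
        ),
    )


def consistency_curve(
    data,
    model: str = "space_by_time",
    algorithm: str = "nnmf",
    n_range=range(1, 9),
    restarts: int = 100,
    seed=None,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> ConsistencyCurve:
    """Decompose at every N, measure consistency, and select dimensionality."""
    rng = np.random.default_rng(seed)
    cons, vafs = {}, {}
    for n in n_range:
        res = decompose(
            data, model, algorithm, n, restarts, rng, max_iter=max_iter, tol=tol
        )
        vafs[n] = res.vaf
        cons[n] = stride_consistency(res)
    measure = {
        "spatial": "pattern_similarity",
        "temporal": "synergy_similarity",
        "space_by_time": "diagonality",
    }[model]
    return select_dimensionality(cons, vafs, measure=measure)


# ---------------------------------------------------------------------------
# across-subject consistency and residual structure


def inter_subject_consistency(results: list, group_labels=None) -> dict:
    """Similarity of matched modules across subjects decomposed at the same N.

    Modules of every subject are matched to the first subject's modules
    by optimal assignment minimizing total (1 - cos) between
    stride-averaged activation patterns; matched patterns and synergies
    are then compared between all subject pairs by mean cosine.
    """
    Ns = {r.n_modules for r in results}
    if len(Ns) != 1:
        raise ValueError("all subjects must be decomposed at the same N")
    # sort first so that pattern i couples to synergy i for every subject
    results = [
        sort_modules(r) if (r.model == "space_by_time" and not r.sorted) else r
        for r in results
    ]
    pats, syns = [], []
    ref = _mean_patterns(results[0])
    refn = ref / np.maximum(np.linalg.norm(ref, axis=1, keepdims=True), 1e-30)
    for r in results:
        P = _mean_patterns(r)
        Pn = P / np.maximum(np.linalg.norm(P, axis=1, keepdims=True), 1e-30)
        cost = 1.0 - refn @ Pn.T
        _, perm = linear_sum_assignment(cost)
        P = P[perm]
        Wm = r.synergies
        if Wm.ndim == 3:
            Wm = Wm.mean(axis=0)
        pats.append(P)
        syns.append(Wm[perm])
    pats = np.array(pats)  # (n_subj, N, 200)
    syns = np.array(syns)
    n_subj = len(results)

    def pair_sim(V):
        sims = []
        for i in range(n_subj):
            for j in range(i + 1, n_subj):
                for k in range(V.shape[1]):
                    a, b = V[i, k], V[j, k]
                    na, nb = np.linalg.norm(a), np.linalg.norm(b)
                    sims.append(a @ b / (na * nb) if na > 0 and nb > 0 else 0.0)
        return np.array(sims)

    out = {
        "pattern_similarity": pair_sim(pats),
        "synergy_similarity": pair_sim(syns),
    }
    if group_labels is not None:
        out["groups"] = dict(zip(group_labels, range(n_subj)))
    return out


def residual_structure(result: DecompositionResult, ci: float = 0.95) -> dict:
    """Cross-stride similarity of residual waveforms, per muscle then averaged.

    Returns the mean pairwise cosine of per-stride residual traces, a
    t-based confidence interval across muscle-level values, and a flag
    marking residuals whose CI encompasses zero (unstructured noise).
    """
    from scipy import stats as sps

    R = result.residuals  # (M, S*200)
    M = R.shape[0]
    S = R.shape[1] // CYCLE_SAMPLES
    per_muscle = []
    for m in range(M):
        V = R[m].reshape(S, CYCLE_SAMPLES)
        if not np.any(np.linalg.norm(V, axis=1) > 0):
            continue
        per_muscle.append(_pairwise_cosine_mean(V))
    if not per_muscle:
        return {"similarity": np.nan, "ci": (np.nan, np.nan), "structured": False,
                "degenerate": True}
    vals = np.array(per_muscle)
    mean = float(vals.mean())
    if len(vals) > 1:
        half = sps.t.ppf(0.5 + ci / 2, len(vals) - 1) * vals.std(ddof=1) / np.sqrt(len(vals))
    else:
        half = np.inf
    lo, hi = mean - half, mean + half
    return {
        "similarity": mean,
        "ci": (float(lo), float(hi)),
        "structured": bool(lo > 0 or hi < 0),
        "degenerate": False,
    }
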