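"""Markov transition analysis and trajectory clustering.

Phenotype timelines are treated as realisations of a discrete-time Markov
chain over {desert, excluded, inflamed, resolved, death}.  Transition
counting stops after the first entry into an absorbing state: the
trailing 0/5 padding of a timeline is bookkeeping, not dynamics (counting
those self-loops would let the padding dominate the probabilities; a flag
restores the alternative).

Significance of individual transitions is assessed against a shuffle
null: each tumour's pre-absorbing code sequence is permuted in place
(preserving its state multiset) and the matrices recomputed.

Trajectory clustering groups tumours by the joint time course of T-cell
abundance and core infiltration ratio, using Ward agglomerative
clustering on standardised per-day features with the number of classes
chosen by silhouette score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, leaves_list
from scipy.spatial.distance import pdist
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import calinski_harabasz_score, silhouette_score

from .states import STATE_ORDER, ABSORBING, validate_codes

_STATE_INDEX = {s: i for i, s in enumerate(STATE_ORDER)}
_ABSORB_IDX = tuple(_STATE_INDEX[s] for s in ABSORBING)


@dataclass
class TransitionMatrix:
    """State-by-state transition counts and row-stochastic probabilities
    over the canonical state order."""

    counts: np.ndarray
    states: tuple[int, ...] = STATE_ORDER

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        n = len(self.states)
        if self.counts.shape != (n, n) or (self.counts < 0).any():
            raise ValueError("counts must be a non-negative square matrix over states")

    @property
    def probs(self) -> np.ndarray:
        """Row-normalised probabilities.  Absorbing states get a unit
        self-loop by convention; zero-count non-absorbing rows are NaN."""
        c = self.counts.astype(float)
        rows = c.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(rows > 0, c / rows, np.nan)
        for i, s in enumerate(self.states):
            if s in ABSORBING:
                p[i] = 0.0
                p[i, i] = 1.0
        return p

    @property
    def n_transitions(self) -> int:
        return int(self.counts.sum())

    def to_frame(self, what: str = "probs") -> pd.DataFrame:
        data = self.probs if what == "probs" else self.counts
        return pd.DataFrame(data, index=list(self.states), columns=list(self.states))


def _observed_steps(codes: np.ndarray, count_absorbing_self_loops: bool) -> list[tuple[int, int]]:
    pairs = []
    for a, b in zip(codes[:-1], codes[1:]):
        pairs.append((int(a), int(b)))
        if int(a) in ABSORBING and not count_absorbing_self_loops:
            pairs.pop()
            break
    return pairs


def transition_counts(timelines, *, count_absorbing_self_loops: bool = False) -> TransitionMatrix:
    """Count code(t) -> code(t+1) transitions over all timelines.

    Counting for a tumour stops after its first entry into an absorbing
    state (the transition *into* the absorbing state is counted).
    """
    counts = np.zeros((5, 5), dtype=int)
    for tl in timelines:
        codes = np.asarray(tl, dtype=int)
        validate_codes(codes)
        for a, b in _observed_steps(codes, count_absorbing_self_loops):
            counts[_STATE_INDEX[a], _STATE_INDEX[b]] += 1
    return TransitionMatrix(counts)


def transition_probabilities(counts: TransitionMatrix) -> np.ndarray:
    """Row-stochastic probabilities of a count matrix (see
    :attr:`TransitionMatrix.probs`)."""
    return counts.probs


def fold_difference(p_treat: np.ndarray, p_control: np.ndarray) -> np.ndarray:
    """Element-wise P_treat / P_control; >1 means the treatment increased
    that transition.  Cells with zero or undefined control probability are
    NaN."""
    a = np.asarray(p_treat, dtype=float)
    b = np.asarray(p_control, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = a / b
    out[~np.isfinite(out)] = np.nan
    return out


@dataclass
class ShuffleNull:
    """Null distribution of transition matrices from within-tumour shuffles."""

    observed: TransitionMatrix
    null_counts: np.ndarray          # (n_perm, 5, 5)
    p_values: np.ndarray             # per-cell empirical two-sided p

    @property
    def n_perm(self) -> int:
        return self.null_counts.shape[0]


def _shuffle_timeline(codes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Permute the pre-absorbing prefix of one timeline in place."""
    out = codes.copy()
    absorbing_at = [i for i, c in enumerate(codes) if int(c) in ABSORBING]
    stop = absorbing_at[0] if absorbing_at else len(codes)
    if stop > 1:
        out[:stop] = rng.permutation(codes[:stop])
    return out


def shuffle_null(timelines, n_perm: int = 10, seed: int = 0) -> ShuffleNull:
    """Shuffle each tumour's pre-absorbing code sequence ``n_perm`` times
    and recompute the transition matrix.

    Per-cell two-sided empirical p-values use the add-one estimator
    (1 + #{null at least as far from the null median as observed}) /
    (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    tls = [np.asarray(t, dtype=int) for t in timelines]
    observed = transition_counts(tls)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, 5, 5), dtype=int)
    for k in range(n_perm):
        shuffled = [_shuffle_timeline(t, rng) for t in tls]
        null[k] = transition_counts(shuffled).counts
    centre = np.median(null, axis=0)
    dev_obs = np.abs(observed.counts - centre)
    dev_null = np.abs(null - centre[None, :, :])
    extreme = (dev_null >= dev_obs[None, :, :]).sum(axis=0)
    p = (1.0 + extreme) / (1.0 + n_perm)
    return ShuffleNull(observed=observed, null_counts=null, p_values=p)


def order_timelines(timelines) -> np.ndarray:
    """Deterministic heat-map display order: leaf order of average-linkage
    agglomerative clustering on Hamming distances between the (padded)
    code vectors."""
    X = np.asarray([np.asarray(t, dtype=int) for t in timelines])
    if X.ndim != 2:
        raise ValueError("timelines must share a common (padded) length")
    if X.shape[0] == 1:
        return np.array([0])
    d = pdist(X, metric="hamming")
    Z = linkage(d, method="average")
    return np.asarray(leaves_list(Z))


@dataclass
class TrajectoryClassModel:
    """Result of trajectory clustering in (abundance, infiltration-ratio)
    space."""

    k: int
    labels: np.ndarray                         # 1..k per tumour
    median_abundance: np.ndarray               # (k, n_days)
    median_ratio: np.ndarray                   # (k, n_days)
    score_by_k: dict[int, float] = field(default_factory=dict)
    silhouette: float | None = None            # at the selected k
    degenerate: bool = False                   # single effective class


def _interpolate_rows(X: np.ndarray) -> np.ndarray:
    """Linear interpolation of interior NaNs per row; edge-held at ends."""
    X = np.asarray(X, dtype=float).copy()
    t = np.arange(X.shape[1])
    for i in range(X.shape[0]):
        good = np.isfinite(X[i])
        if not good.any():
            X[i] = 0.0
        elif not good.all():
            X[i] = np.interp(t, t[good], X[i][good])
    return X


def cluster_trajectories(
    abundance: np.ndarray,
    ratio: np.ndarray,
    k: int | None = None,
    *,
    k_range: tuple[int, int] = (2, 6),
    min_silhouette: float = 0.20,
) -> TrajectoryClassModel:
    """Ward clustering of per-tumour trajectories.

    ``abundance`` and ``ratio`` are (n_tumours, n_days) matrices (NaNs are
    linearly interpolated).  The feature vector concatenates the per-day
    standardised values of both series.  With ``k=None`` the class count
    is chosen by the Calinski–Harabasz variance-ratio criterion over
    ``k_range`` (it resolves trajectory classes that share their early
    time course, where the average silhouette stays flat); the silhouette
    at the chosen k acts as a minimum-separation guard — below
    ``min_silhouette`` the cohort is reported as a single effective class
    (degenerate), as is a cohort of identical trajectories.
    """
    A = _interpolate_rows(abundance)
    R = _interpolate_rows(ratio)
    if A.shape != R.shape:
        raise ValueError("abundance and ratio must have the same shape")
    n = A.shape[0]
    X = np.hstack([A, R])
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X - mu) / sd

    def degenerate_model(score_by_k):
        return TrajectoryClassModel(
            k=1, labels=np.ones(n, dtype=int),
            median_abundance=np.median(A, axis=0, keepdims=True),
            median_ratio=np.median(R, axis=0, keepdims=True),
            score_by_k=score_by_k, degenerate=True,
        )

    def fit(kk: int) -> np.ndarray:
        return AgglomerativeClustering(n_clusters=kk, linkage="ward").fit_predict(X)

    scores: dict[int, float] = {}
    sil_at_k: float | None = None
    if k is None:
        lo, hi = k_range
        hi = min(hi, n - 1)
        if n <= lo:
            raise ValueError(f"need more than {lo} tumours for auto class selection")
        if np.allclose(X, X[0]):
            return degenerate_model(scores)
        labels_by_k = {}
        for kk in range(lo, hi + 1):
            lab = fit(kk)
            labels_by_k[kk] = lab
            scores[kk] = float(calinski_harabasz_score(X, lab))
        best_k = max(scores, key=lambda kk: (scores[kk], -kk))
        sil_at_k = float(silhouette_score(X, labels_by_k[best_k]))
        if sil_at_k < min_silhouette:
            return degenerate_model(scores)
        k, labels0 = best_k, labels_by_k[best_k]
    else:
        if n < k:
            raise ValueError("fewer tumours than requested classes")
        labels0 = fit(k)

    med_a = np.vstack([np.median(A[labels0 == c], axis=0) for c in range(k)])
    med_r = np.vstack([np.median(R[labels0 == c], axis=0) for c in range(k)])
    return TrajectoryClassModel(
        k=k, labels=labels0 + 1, median_abundance=med_a, median_ratio=med_r,
        score_by_k=scores, silhouette=sil_at_k,
    )
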