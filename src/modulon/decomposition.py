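"""Consensus (robust) independent component analysis.

FastICA is restarted many times with random seeds on the centered
log-expression matrix X (genes x samples).  All recovered components are
pooled and clustered with DBSCAN under the sign-invariant distance

    d(x, y) = 1 - |rho(x, y)|

(rho = Pearson correlation), so a component and its sign-flip are identical.
Each dense cluster's centroid is a robust independent component; the final
gene-weight matrix M stacks the centroids and the activity matrix A is
re-fit by least squares, X ~ M @ A.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import lstsq
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import DBSCAN
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "DecompositionRun",
    "RobustComponentSet",
    "RobustICA",
    "run_fastica",
    "component_distance",
    "cluster_components",
    "compute_centroid",
    "robust_decomposition",
]


@dataclass
class DecompositionRun:
    """One FastICA restart: unit-norm gene weights and least-squares activities."""

    weights: np.ndarray      # genes x D, unit L2 columns
    activities: np.ndarray   # D x samples
    seed: int
    converged: bool


@dataclass
class RobustComponentSet:
    """Consensus decomposition: centroid weights M, refit activities A."""

    M: pd.DataFrame            # genes x k
    A: pd.DataFrame            # k x samples
    cluster_sizes: np.ndarray
    dimension: int
    n_runs: int

    @property
    def k(self) -> int:
        return self.M.shape[1]


def double_center(arr: np.ndarray) -> np.ndarray:
    """Remove per-gene (row) and per-sample (column) means.

    Both mean directions are treated as nuisance throughout the
    decomposition: per-gene constants carry reference-centering noise and
    per-sample constants carry TPM compositional offsets; neither is module
    signal.
    """
    arr = np.asarray(arr, dtype=float)
    out = arr - arr.mean(axis=1, keepdims=True)
    return out - out.mean(axis=0, keepdims=True)


def _as_matrix(X) -> tuple[np.ndarray, pd.Index | None, pd.Index | None]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), X.index, X.columns
    arr = np.asarray(X, dtype=float)
    return arr, None, None


def component_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Sign-invariant component distance ``1 - |Pearson rho(x, y)|`` in [0, 1]."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("vectors must have the same length")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance vector has undefined correlation")
    # explicit formula keeps the distance bitwise symmetric in (x, y)
    xm = x - x.mean()
    ym = y - y.mean()
    rho = (xm @ ym) / np.sqrt((xm @ xm) * (ym @ ym))
    return float(np.clip(1.0 - abs(rho), 0.0, 1.0))


def run_fastica(
    X,
    D: int,
    seed: int = 0,
    tol: float = 1e-7,
    max_iter: int = 1000,
) -> DecompositionRun:
    """Whiten to ``D`` dimensions and run fixed-point FastICA (log-cosh
    contrast); weight columns are normalized to unit L2 norm and activities
    re-fit by least squares so ``weights @ activities`` approximates X.

    X is double-centered (per-gene and per-sample means removed) before
    whitening, and the returned activities are fit against the same
    double-centered matrix.  Both mean directions are nuisance: centering to
    a handful of reference replicates leaves a per-gene constant (the
    reference-mean estimation noise) shared by every sample — over thousands
    of genes a rank-one direction strong enough to displace the weakest
    genuine component from the whitened subspace — and TPM renormalization
    leaves per-sample compositional offsets that would otherwise smear a
    constant into every gene's weight.
    """
    arr, _, _ = _as_matrix(X)
    if np.isnan(arr).any():
        raise ValueError("X contains NaNs")
    if D > min(arr.shape):
        raise ValueError(f"D={D} exceeds min(genes, samples)={min(arr.shape)}")
    if not np.any(np.std(arr, axis=0) > 0):
        raise ValueError("X has no variance; cannot whiten")
    centered = double_center(arr)
    ica = FastICA(
        n_components=D,
        algorithm="parallel",
        fun="logcosh",
        whiten="unit-variance",
        tol=tol,
        max_iter=max_iter,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        S = ica.fit_transform(centered)   # genes x D
    converged = ica.n_iter_ < max_iter
    norms = np.linalg.norm(S, axis=0)
    norms[norms == 0] = 1.0
    M = S / norms
    A = lstsq(M, centered)[0]
    return DecompositionRun(weights=M, activities=A, seed=seed, converged=converged)


def _pool_distance_matrix(pool: np.ndarray) -> np.ndarray:
    # pool rows = components
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(pool)
    corr = np.nan_to_num(corr, nan=0.0)
    dist = 1.0 - np.abs(corr)
    np.fill_diagonal(dist, 0.0)
    return np.clip(dist, 0.0, 1.0)


def cluster_components(
    pool: np.ndarray, eps: float = 0.1, min_samples: int = 50
) -> tuple[list[np.ndarray], np.ndarray]:
    """DBSCAN over the precomputed sign-invariant distance matrix.

    ``pool`` has one component per row.  Returns (clusters, noise) as arrays
    of row indices; components in no dense cluster are noise.
    """
    pool = np.asarray(pool, dtype=float)
    if pool.size == 0:
        raise ValueError("empty component pool")
    dist = _pool_distance_matrix(pool)
    labels = DBSCAN(eps=eps, min_samples=min_samples, metric="precomputed").fit(dist).labels_
    clusters = [np.flatnonzero(labels == lab) for lab in sorted(set(labels) - {-1})]
    noise = np.flatnonzero(labels == -1)
    return clusters, noise


def compute_centroid(cluster: np.ndarray) -> np.ndarray:
    """Sign-aligned mean of a cluster of weight vectors, unit-normalized, with
    canonical orientation (largest-|weight| entry positive)."""
    cluster = np.atleast_2d(np.asarray(cluster, dtype=float))
    ref = cluster[0]
    aligned = []
    for v in cluster:
        rho = np.corrcoef(v, ref)[0, 1]
        aligned.append(-v if rho < 0 else v)
    centroid = np.mean(aligned, axis=0)
    norm = np.linalg.norm(centroid)
    if norm > 0:
        centroid = centroid / norm
    if centroid[np.argmax(np.abs(centroid))] < 0:
        centroid = -centroid
    return centroid


def _default_min_samples(n_runs: int) -> int:
    # reproduces the published "minimum cluster seed size of 50" at 100 runs
    return max(2, math.ceil(n_runs / 2))


class RobustICA(TransformerMixin, BaseEstimator):
    """Consensus ICA estimator for expression compendia.

    Parameters
    ----------
    n_components : int
        ICA dimensionality D (number of whitened dimensions per run).
    n_runs : int, default 100
        Number of FastICA restarts with distinct seeds.
    tol : float, default 1e-7
        FastICA convergence tolerance.
    max_iter : int, default 1000
        FastICA iteration cap; non-convergent runs are flagged but kept in
        the pool (the consensus clustering rejects non-reproducible
        components).
    eps : float, default 0.1
        DBSCAN radius under the 1-|rho| distance.
    min_samples : int or None
        DBSCAN core size; ``None`` scales as ``max(2, ceil(n_runs/2))``.
    random_state : int or None
        Seeds the per-run seed stream; fixed values give identical results.

    Attributes
    ----------
    gene_weights_ : DataFrame, genes x k
        Robust component centroids M (unit-norm, sign-canonicalized columns).
    activities_ : DataFrame, k x samples
        Least-squares activities A minimizing ||X - M A||_F.
    cluster_sizes_ : ndarray
        Pool-cluster size per robust component.
    n_converged_ : int
        Number of FastICA runs that converged and entered the pool.

    Notes
    -----
    ``fit`` expects X oriented genes x samples (rows are genes), the standard
    orientation for gene-weight ICA of compendia.
    """

    def __init__(
        self,
        n_components: int,
        n_runs: int = 100,
        tol: float = 1e-7,
        max_iter: int = 1000,
        eps: float = 0.1,
        min_samples: int | None = None,
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.n_runs = n_runs
        self.tol = tol
        self.max_iter = max_iter
        self.eps = eps
        self.min_samples = min_samples
        self.random_state = random_state

    def fit(self, X, y=None):
        arr, gene_index, sample_index = _as_matrix(X)
        rng = np.random.default_rng(self.random_state)
        seeds = rng.integers(0, 2**31 - 1, size=self.n_runs)

        runs = [
            run_fastica(arr, self.n_components, seed=int(s), tol=self.tol, max_iter=self.max_iter)
            for s in seeds
        ]
        self.n_converged_ = sum(r.converged for r in runs)
        self.run_seeds_ = np.array([r.seed for r in runs])

        # Non-converged runs stay in the pool: above the signal rank FastICA
        # wanders on near-Gaussian directions and never meets tol, yet the
        # same runs' signal-subspace components are fine — the consensus
        # clustering, not the convergence flag, separates the reproducible
        # components from the wanderers.
        pool = np.hstack([r.weights for r in runs]).T   # components x genes
        min_samples = (
            self.min_samples if self.min_samples is not None else _default_min_samples(self.n_runs)
        )
        clusters, noise = cluster_components(pool, eps=self.eps, min_samples=min_samples)
        self.n_noise_components_ = int(noise.size)
        if not clusters:
            warnings.warn("DBSCAN found no dense component cluster", stacklevel=2)
            self._set_empty(arr, gene_index, sample_index)
            return self

        centroids = [compute_centroid(pool[idx]) for idx in clusters]
        sizes = np.array([idx.size for idx in clusters])
        order = np.lexsort((np.arange(len(clusters)), -sizes))   # big clusters first
        M = np.column_stack([centroids[i] for i in order])
        self.cluster_sizes_ = sizes[order]
        A = lstsq(M, double_center(arr))[0]

        comp_ids = [f"IM{i + 1:03d}" for i in range(M.shape[1])]
        gidx = gene_index if gene_index is not None else pd.RangeIndex(arr.shape[0])
        sidx = sample_index if sample_index is not None else pd.RangeIndex(arr.shape[1])
        self.gene_weights_ = pd.DataFrame(M, index=gidx, columns=comp_ids)
        self.activities_ = pd.DataFrame(A, index=comp_ids, columns=sidx)
        self.n_components_ = M.shape[1]
        return self

    def _set_empty(self, arr, gene_index, sample_index):
        gidx = gene_index if gene_index is not None else pd.RangeIndex(arr.shape[0])
        sidx = sample_index if sample_index is not None else pd.RangeIndex(arr.shape[1])
        self.gene_weights_ = pd.DataFrame(index=gidx)
        self.activities_ = pd.DataFrame(columns=sidx)
        self.cluster_sizes_ = np.array([], dtype=int)
        self.n_components_ = 0

    def transform(self, X):
        """Project expression onto the fitted components: least-squares
        activities ``A = argmin ||X - M A||_F`` for new samples."""
        check_is_fitted(self, "gene_weights_")
        arr, _, sample_index = _as_matrix(X)
        if self.n_components_ == 0:
            return pd.DataFrame(columns=sample_index if sample_index is not None else None)
        A = lstsq(self.gene_weights_.to_numpy(), double_center(arr))[0]
        sidx = sample_index if sample_index is not None else pd.RangeIndex(arr.shape[1])
        return pd.DataFrame(A, index=self.activities_.index, columns=sidx)

    def to_component_set(self) -> RobustComponentSet:
        check_is_fitted(self, "gene_weights_")
        return RobustComponentSet(
            M=self.gene_weights_,
            A=self.activities_,
            cluster_sizes=self.cluster_sizes_,
            dimension=self.n_components,
            n_runs=self.n_runs,
        )


def robust_decomposition(
    X,
    D: int,
    n_runs: int = 100,
    base_seed: int | None = None,
    **kwargs,
) -> RobustComponentSet:
    """Functional wrapper around :class:`RobustICA`."""
    est = RobustICA(n_components=D, n_runs=n_runs, random_state=base_seed, **kwargs)
    est.fit(X)
    return est.to_component_set()
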