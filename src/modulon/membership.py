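"""From weight vectors to discrete iModulons and explained variance.

Membership calling follows the compendium-mining convention: K-means with
three clusters on the absolute gene weights of a component; genes in the top
two clusters (by cluster center) are members.  Explained variance of a
component subset S is the fraction of the centered matrix's squared Frobenius
norm captured by the least-squares reconstruction restricted to S:

    EV(S) = 1 - ||X - M_S A*_S||_F^2 / ||X||_F^2,   A*_S = argmin ||X - M_S A||_F
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import lstsq
from sklearn.cluster import KMeans

from .decomposition import RobustComponentSet, double_center

__all__ = [
    "IModulon",
    "DegenerateWeightsError",
    "threshold_membership",
    "explained_variance",
    "build_imodulons",
    "annotate_imodulons",
    "category_explained_variance",
]


class DegenerateWeightsError(ValueError):
    """Raised when a weight vector has fewer than three distinct |weights|."""


@dataclass
class IModulon:
    """One robust component's discrete gene set and bookkeeping."""

    id: str
    members: set
    weights: pd.Series
    threshold: float                  # smallest |weight| among members
    explained_variance: float
    category: str = "uncharacterized"
    regulator: str | None = None

    def __len__(self) -> int:
        return len(self.members)


def threshold_membership(weights: pd.Series | np.ndarray, seed: int = 0) -> set:
    """Member genes of one component: top two of three K-means clusters on
    |weights| (10 seeded restarts, best inertia).

    Membership is invariant to the global sign and scale of the weights.
    Raises :class:`DegenerateWeightsError` below three distinct |weights|;
    callers may fall back to nonzero-weight membership.
    """
    if isinstance(weights, pd.Series):
        labels = weights.index
        aw = np.abs(weights.to_numpy(dtype=float))
    else:
        aw = np.abs(np.asarray(weights, dtype=float).ravel())
        labels = pd.RangeIndex(aw.size)
    if np.unique(aw).size < 3:
        raise DegenerateWeightsError("need >= 3 distinct |weight| values for 3-means")
    km = KMeans(n_clusters=3, n_init=10, random_state=seed).fit(aw.reshape(-1, 1))
    order = np.argsort(km.cluster_centers_.ravel())   # ascending
    top_two = set(order[1:])
    mask = np.isin(km.labels_, list(top_two))
    return set(labels[mask])


def explained_variance(X, M, subset=None) -> float:
    """Fraction of the dataset's variance explained by the component subset's
    least-squares reconstruction; EV(empty set) = 0.

    Variance is taken about the per-gene and per-sample means (X is
    double-centered internally, matching the decomposition): per-gene
    constants are reference-centering residue and per-sample constants are
    TPM compositional offsets, neither of which is module signal.
    """
    Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    Xa = double_center(Xa)
    Ma = M.to_numpy(dtype=float) if isinstance(M, pd.DataFrame) else np.asarray(M, dtype=float)
    total = np.linalg.norm(Xa) ** 2
    if total == 0:
        raise ValueError("X has zero norm; explained variance undefined")
    if subset is not None:
        cols = sorted(subset)
        if isinstance(M, pd.DataFrame) and cols and not isinstance(cols[0], (int, np.integer)):
            Ma = M[cols].to_numpy(dtype=float)
        else:
            Ma = Ma[:, cols]
    if Ma.shape[1] == 0:
        return 0.0
    A = lstsq(Ma, Xa)[0]
    resid = np.linalg.norm(Xa - Ma @ A) ** 2
    return float(1.0 - resid / total)


def build_imodulons(
    robust: RobustComponentSet,
    X,
    seed: int = 0,
) -> list[IModulon]:
    """One iModulon per robust component: thresholded members, the weight
    threshold (smallest member |weight|), and single-component explained
    variance.  Components with no members are dropped; the list is ordered by
    descending explained variance (ties by component id)."""
    out: list[IModulon] = []
    for comp in robust.M.columns:
        w = robust.M[comp]
        try:
            members = threshold_membership(w, seed=seed)
        except DegenerateWeightsError:
            members = set(w.index[w.to_numpy() != 0])
            warnings.warn(
                f"{comp}: degenerate weights; falling back to nonzero membership", stacklevel=2
            )
        if not members:
            warnings.warn(f"{comp}: empty member set after thresholding; dropped", stacklevel=2)
            continue
        threshold = float(np.min(np.abs(w.loc[sorted(members)].to_numpy())))
        ev = explained_variance(X, robust.M, subset=[comp])
        out.append(
            IModulon(id=str(comp), members=members, weights=w, threshold=threshold,
                     explained_variance=ev)
        )
    out.sort(key=lambda im: (-im.explained_variance, im.id))
    return out


def annotate_imodulons(imodulons, categories: dict) -> None:
    """Apply a user-supplied annotation table (iModulon id -> (category,
    regulator)) in place; ids absent from the table keep their defaults."""
    for im in imodulons:
        if im.id in categories:
            cat, reg = categories[im.id]
            im.category = cat
            if reg:
                im.regulator = reg


def category_explained_variance(X, M, imodulons) -> pd.Series:
    """Combined explained variance per category: subset-refit EV over each
    category's components (categories overlap-free by construction)."""
    by_cat: dict[str, list] = {}
    for im in imodulons:
        by_cat.setdefault(im.category, []).append(im.id)
    out = {cat: explained_variance(X, M, subset=ids) for cat, ids in sorted(by_cat.items())}
    return pd.Series(out, name="explained_variance")
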