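"""iModulon activity analysis and regulon reconstitution.

Covers: activity-to-gene expression correlation, hierarchical clustering of
activity profiles (average linkage on 1 - rho), permutation tests for
differential activity between condition groups, hypergeometric enrichment of
iModulon members against known regulons, and assembly of a putative
transcriptional regulatory network (TRN) from known plus iModulon-derived
edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom, pearsonr
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentResult",
    "activity_correlation",
    "cluster_activities",
    "differential_activity",
    "regulon_enrichment",
    "assign_regulators",
    "build_trn",
]

ASSIGN_Q_MAX = 0.01   # regulator assignment: best F1 among q < 0.01 hits


@dataclass
class EnrichmentResult:
    imodulon: str
    regulator: str
    overlap: int
    precision: float
    recall: float
    f1: float
    pvalue: float
    qvalue: float = float("nan")


def activity_correlation(A: pd.DataFrame, component: str, X: pd.DataFrame, gene: str) -> float:
    """Pearson r between one component's activity and one gene's expression
    over the shared samples."""
    if component not in A.index:
        raise KeyError(f"unknown component {component!r}")
    if gene not in X.index:
        raise KeyError(f"unknown gene {gene!r}")
    shared = A.columns.intersection(X.columns)
    a = A.loc[component, shared].to_numpy(dtype=float)
    g = X.loc[gene, shared].to_numpy(dtype=float)
    if np.std(a) == 0 or np.std(g) == 0:
        raise ValueError("zero-variance series; correlation undefined")
    return float(pearsonr(a, g).statistic)


def cluster_activities(A: pd.DataFrame) -> tuple[np.ndarray, list]:
    """Average-linkage hierarchical clustering of components on the distance
    1 - rho between activity profiles.

    Anti-correlated components land at distance 2, so opposing programs (e.g.
    iron- vs phosphate-driven regimes) separate instead of merging.  Returns
    the scipy linkage matrix and the deterministic leaf-order component list.
    """
    if A.shape[0] < 2:
        raise ValueError("need at least two components to cluster")
    vals = A.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValueError(f"constant activity row(s): {list(A.index[flat])}")
    corr = np.corrcoef(vals)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    order = [A.index[i] for i in leaves_list(Z)]
    return Z, order


def differential_activity(
    A: pd.DataFrame,
    component: str,
    group1,
    group2,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean activity difference between two disjoint sample groups with a
    two-sided label-permutation p-value (add-one corrected)."""
    g1 = list(group1)
    g2 = list(group2)
    if set(g1) & set(g2):
        raise ValueError("groups must be disjoint")
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs >= 2 samples")
    a1 = A.loc[component, g1].to_numpy(dtype=float)
    a2 = A.loc[component, g2].to_numpy(dtype=float)
    delta = float(a1.mean() - a2.mean())
    pooled = np.concatenate([a1, a2])
    n1 = len(a1)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        d = perm[:n1].mean() - perm[n1:].mean()
        if abs(d) >= abs(delta) - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return delta, float(p)


def regulon_enrichment(
    members: set,
    regulons: dict,
    universe: int,
) -> list[EnrichmentResult]:
    """Hypergeometric upper-tail enrichment of an iModulon's members against
    every known regulon, with Benjamini-Hochberg adjustment across regulators.

    ``universe`` is the total number of genes the memberships were drawn from.
    Results are sorted by descending F1 (ties by regulator label).
    """
    members = set(members)
    if not members:
        return []
    results: list[EnrichmentResult] = []
    for reg in sorted(regulons):
        targets = set(regulons[reg])
        ov = len(members & targets)
        prec = ov / len(members)
        rec = ov / len(targets) if targets else 0.0
        f1 = 2 * prec * rec / (prec + rec) if (prec + rec) else 0.0
        # P(overlap >= ov) drawing |members| genes from a universe containing |targets|
        p = float(hypergeom.sf(ov - 1, universe, len(targets), len(members)))
        results.append(
            EnrichmentResult(
                imodulon="", regulator=reg, overlap=ov, precision=prec, recall=rec,
                f1=f1, pvalue=p,
            )
        )
    if results:
        qvals = multipletests([r.pvalue for r in results], method="fdr_bh")[1]
        for r, q in zip(results, qvals):
            r.qvalue = float(q)
    results.sort(key=lambda r: (-r.f1, r.regulator))
    return results


def assign_regulators(
    imodulons,
    regulons: dict,
    universe: int,
    q_max: float = ASSIGN_Q_MAX,
) -> dict:
    """Best-F1 regulator with q < q_max per iModulon (None if no hit); also
    stamps the regulator onto each IModulon record."""
    out = {}
    for im in imodulons:
        hits = regulon_enrichment(im.members, regulons, universe)
        best = next((h for h in hits if h.qvalue < q_max and h.overlap > 0), None)
        im.regulator = best.regulator if best else None
        out[im.id] = im.regulator
    return out


def build_trn(
    imodulons,
    known: dict,
    assignments: dict | None = None,
) -> pd.DataFrame:
    """Union TRN edge list: every known regulator->gene edge plus, for each
    iModulon with an assigned regulator, regulator->member edges not already
    known.  Edges carry a provenance tag ('known' or 'imodulon')."""
    rows = []
    known_edges = set()
    for reg in sorted(known):
        for g in sorted(known[reg]):
            rows.append({"regulator": reg, "target": g, "provenance": "known"})
            known_edges.add((reg, g))
    if assignments is None:
        assignments = {im.id: im.regulator for im in imodulons}
    for im in imodulons:
        reg = assignments.get(im.id)
        if reg is None:
            continue
        for g in sorted(im.members):
            if (reg, g) not in known_edges:
                rows.append({"regulator": reg, "target": g, "provenance": "imodulon"})
                known_edges.add((reg, g))
    return pd.DataFrame(rows, columns=["regulator", "target", "provenance"])
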