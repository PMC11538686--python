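"""ICA dimensionality selection.

The decomposition is repeated over a grid of dimensions.  At each dimension
D the scan records the number of robust components, how many of them are
single-gene (thresholded membership of exactly one gene), and how many are
conserved — matched one-to-one at |Pearson r| > 0.7 against the components
found at the largest scanned dimension ("final components").  The optimal
dimension is the smallest D where the number of non-single-gene components
equals the number of conserved components; if no dimension satisfies this,
the largest is returned with a warning flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decomposition import RobustComponentSet, robust_decomposition
from .membership import DegenerateWeightsError, threshold_membership

__all__ = [
    "DimensionScan",
    "scan_dimensions",
    "count_single_gene",
    "conserved_components",
    "select_optimal_dimension",
]

CONSERVED_R_MIN = 0.7


@dataclass
class DimensionScan:
    dimensions: list[int]
    component_sets: dict                     # D -> RobustComponentSet
    table: pd.DataFrame                      # per-D counts
    selected_dimension: int
    criterion_met: bool


def count_single_gene(components: RobustComponentSet, seed: int = 0) -> int:
    """Number of robust components whose thresholded member set has one gene."""
    n = 0
    for comp in components.M.columns:
        try:
            members = threshold_membership(components.M[comp], seed=seed)
        except DegenerateWeightsError:
            members = set(components.M.index[components.M[comp].to_numpy() != 0])
        if len(members) == 1:
            n += 1
    return n


def conserved_components(
    at_D: RobustComponentSet, at_Dmax: RobustComponentSet, r_min: float = CONSERVED_R_MIN
) -> int:
    """Greedy one-to-one matching of weight columns by descending |Pearson r|;
    pairs with |r| > r_min count as conserved."""
    ka, kb = at_D.k, at_Dmax.k
    if ka == 0 or kb == 0:
        return 0
    Ma = at_D.M.to_numpy()
    Mb = at_Dmax.M.to_numpy()
    # |corr| between all column pairs
    Za = (Ma - Ma.mean(axis=0)) / Ma.std(axis=0)
    Zb = (Mb - Mb.mean(axis=0)) / Mb.std(axis=0)
    C = np.abs(Za.T @ Zb) / Ma.shape[0]
    pairs = sorted(
        ((C[i, j], i, j) for i in range(ka) for j in range(kb)),
        key=lambda t: (-t[0], t[1], t[2]),
    )
    used_a: set[int] = set()
    used_b: set[int] = set()
    n = 0
    for r, i, j in pairs:
        if r <= r_min:
            break
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        n += 1
    return n


def scan_dimensions(
    X,
    dimensions,
    n_runs: int = 100,
    seed: int = 0,
    **ica_kwargs,
) -> DimensionScan:
    """Run the robust decomposition at every dimension of the grid and apply
    the selection rule.  ``dimensions`` must be strictly increasing."""
    dims = [int(d) for d in dimensions]
    if not dims:
        raise ValueError("empty dimension grid")
    if any(b <= a for a, b in zip(dims, dims[1:])):
        raise ValueError("dimension grid must be strictly increasing")
    n_samples = X.shape[1]
    n_genes = X.shape[0]
    if dims[-1] > min(n_genes, n_samples):
        raise ValueError("largest dimension exceeds min(genes, samples)")

    rng = np.random.default_rng(seed)
    per_dim_seeds = {d: int(s) for d, s in zip(dims, rng.integers(0, 2**31 - 1, len(dims)))}
    sets = {d: robust_decomposition(X, d, n_runs=n_runs, base_seed=per_dim_seeds[d], **ica_kwargs)
            for d in dims}

    ref = sets[dims[-1]]
    rows = []
    for d in dims:
        rcs = sets[d]
        n_single = count_single_gene(rcs, seed=per_dim_seeds[d])
        n_cons = conserved_components(rcs, ref)
        rows.append(
            {"dimension": d, "n_robust": rcs.k, "n_single_gene": n_single, "n_conserved": n_cons}
        )
    table = pd.DataFrame(rows).set_index("dimension")
    selected, met = select_optimal_dimension_from_table(table)
    table["selected"] = table.index == selected
    return DimensionScan(
        dimensions=dims,
        component_sets=sets,
        table=table,
        selected_dimension=selected,
        criterion_met=met,
    )


def select_optimal_dimension_from_table(table: pd.DataFrame) -> tuple[int, bool]:
    ok = table.index[
        (table["n_robust"] - table["n_single_gene"]) == table["n_conserved"]
    ]
    if len(ok):
        return int(ok[0]), True
    warnings.warn(
        "no dimension satisfies the non-single-gene == conserved criterion; "
        "falling back to the largest scanned dimension",
        stacklevel=2,
    )
    return int(table.index[-1]), False


def select_optimal_dimension(scan: DimensionScan) -> int:
    """Smallest dimension where non-single-gene component count equals the
    conserved-component count (largest grid point if never satisfied)."""
    return scan.selected_dimension
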