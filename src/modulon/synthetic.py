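"""Synthetic expression compendia with planted module structure.

Generates genes x samples compendia of the form ``X = M @ A + baseline + noise``
with sparse gene-weight modules (the ground truth iModulons), condition-block
activities shared across biological replicates, planted regulons and planted
genomically contiguous biosynthetic gene cluster (BGC) blocks.  A raw count
matrix is back-computed through the inverse of the TPM + log2 transform so the
preprocessing stage can be exercised end to end without any external dataset.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GroundTruth",
    "SampleDesign",
    "SyntheticCompendium",
    "generate_ground_truth",
    "generate_design",
    "synthesize_compendium",
    "simulate_compendium",
    "corrupt_replicate",
]

#: genome layout constants: consecutive non-overlapping ORFs, 1-based inclusive
GENE_LENGTH_NT = 900
GENE_GAP_NT = 100
LIBRARY_SIZE = 5_000_000


@dataclass
class GroundTruth:
    """Planted low-rank structure of a synthetic compendium.

    ``true_activities`` is filled in by :func:`synthesize_compendium`, since
    activities only exist once a sample design is available.
    """

    true_weights: pd.DataFrame            # genes x k_true, sparse
    module_members: list[set]             # k_true gene-id sets
    regulon_map: dict                     # regulator label -> gene-id set
    genome_layout: pd.DataFrame           # gene_id, length_nt, start, end, strand
    bgc_blocks: list                      # (module idx, (first,last) 1-based gene-order interval, core gene ids)
    noise_sd: float
    seed: int
    true_activities: pd.DataFrame | None = None   # k_true x samples

    @property
    def k_true(self) -> int:
        return self.true_weights.shape[1]

    @property
    def gene_ids(self) -> pd.Index:
        return self.true_weights.index


@dataclass
class SampleDesign:
    sample_id: str
    project: str
    condition: str
    replicate_group: str
    is_reference: bool


@dataclass
class SyntheticCompendium:
    """Bundle returned by :func:`synthesize_compendium`."""

    log_expression: pd.DataFrame   # genes x samples, uncentered log2 scale
    counts: pd.DataFrame           # genes x samples, non-negative integers
    genes: pd.DataFrame            # gene table (gene_id index)
    truth: GroundTruth
    design: pd.DataFrame           # sample table (sample_id index)


def _design_frame(design: list[SampleDesign]) -> pd.DataFrame:
    df = pd.DataFrame([dataclasses.asdict(s) for s in design]).set_index("sample_id")
    return df


def generate_ground_truth(
    n_genes: int,
    k_true: int,
    module_size_range: tuple[int, int] = (8, 40),
    weight_scale: float = 1.0,
    sparsity_overlap: float = 0.05,
    seed: int = 0,
    *,
    weight_spread: tuple[float, float] = (0.5, 2.0),
    n_single_gene: int = 0,
    n_bgc: int = 0,
    bgc_size: int = 15,
    regulon_coverage: float = 0.8,
    noise_sd: float = 0.25,
) -> GroundTruth:
    """Plant ``k_true`` sparse gene-weight modules over ``n_genes`` genes.

    Parameters
    ----------
    module_size_range
        Inclusive (min, max) member count for ordinary modules.
    weight_scale
        Member weight magnitudes are ``weight_scale * U(*weight_spread)``
        with one consistent sign per module.
    weight_spread
        Relative magnitude range of member weights, default (0.5, 2.0).  The
        several-fold spread mirrors real regulons, where effect sizes vary
        with promoter strength and operon position; it is also what makes
        the three-cluster membership rule well-posed (near-identical member
        weights collapse two of the three clusters onto the noise floor).
    sparsity_overlap
        Fraction of each module's members drawn from genes already belonging
        to one other module (no gene belongs to more than two).
    n_single_gene
        Number of planted single-gene modules (appended last).
    n_bgc
        Number of modules whose members form contiguous genome blocks; each
        block's central third is marked as core biosynthetic genes.
    regulon_coverage
        Each module's planted regulon keeps members independently with this
        probability (at least one member is always kept).
    """
    if k_true < 0 or n_genes < 0:
        raise ValueError("n_genes and k_true must be non-negative")
    if k_true > 0 and module_size_range[0] < 1:
        raise ValueError("module_size_range minimum must be >= 1")
    if n_single_gene + n_bgc > k_true:
        raise ValueError("n_single_gene + n_bgc cannot exceed k_true")

    rng = np.random.default_rng(seed)
    gene_ids = pd.Index([f"G{i:04d}" for i in range(n_genes)], name="gene_id")

    starts = np.arange(n_genes) * (GENE_LENGTH_NT + GENE_GAP_NT) + 1
    layout = pd.DataFrame(
        {
            "length_nt": GENE_LENGTH_NT,
            "start": starts,
            "end": starts + GENE_LENGTH_NT - 1,
            "strand": rng.choice(["+", "-"], size=n_genes),
        },
        index=gene_ids,
    )

    W = np.zeros((n_genes, k_true))
    members: list[set] = []
    assignments = np.zeros(n_genes, dtype=int)   # modules per gene, capped at 2
    bgc_blocks: list[tuple[int, tuple[int, int], set]] = []

    n_ordinary = k_true - n_single_gene - n_bgc

    # contiguous BGC blocks first, spaced apart so blocks stay disjoint
    block_starts: list[int] = []
    for b in range(n_bgc):
        for _ in range(200):
            s = int(rng.integers(0, max(1, n_genes - bgc_size)))
            if all(abs(s - t) >= bgc_size + 3 for t in block_starts):
                block_starts.append(s)
                break
        else:  # pragma: no cover - only on absurdly dense layouts
            raise ValueError("cannot place disjoint BGC blocks; too few genes")
    block_starts.sort()

    def _fill_module(idx: int, member_pos: np.ndarray) -> None:
        sign = rng.choice([-1.0, 1.0])
        W[member_pos, idx] = sign * weight_scale * rng.uniform(*weight_spread, member_pos.size)
        assignments[member_pos] += 1
        members.append(set(gene_ids[member_pos]))

    mod = 0
    for s in block_starts:
        pos = np.arange(s, s + bgc_size)
        _fill_module(mod, pos)
        core_lo = s + bgc_size // 3
        core_hi = s + 2 * bgc_size // 3
        core = set(gene_ids[np.arange(core_lo, core_hi + 1)])
        bgc_blocks.append((mod, (s + 1, s + bgc_size), core))
        mod += 1

    for _ in range(n_ordinary):
        size = int(rng.integers(module_size_range[0], module_size_range[1] + 1))
        n_overlap = int(round(sparsity_overlap * size))
        once = np.flatnonzero(assignments == 1)
        n_overlap = min(n_overlap, once.size)
        fresh_pool = np.flatnonzero(assignments == 0)
        n_fresh = min(size - n_overlap, fresh_pool.size)
        pos = np.concatenate(
            [
                rng.choice(once, size=n_overlap, replace=False) if n_overlap else np.empty(0, int),
                rng.choice(fresh_pool, size=n_fresh, replace=False),
            ]
        ).astype(int)
        _fill_module(mod, pos)
        mod += 1

    for _ in range(n_single_gene):
        fresh_pool = np.flatnonzero(assignments == 0)
        pos = rng.choice(fresh_pool, size=1, replace=False)
        _fill_module(mod, pos)
        mod += 1

    regulon_map: dict[str, set] = {}
    for i, mset in enumerate(members):
        keep = {g for g in sorted(mset) if rng.random() < regulon_coverage}
        if not keep:
            keep = {sorted(mset)[0]}
        regulon_map[f"Reg{i:02d}"] = keep

    weights = pd.DataFrame(W, index=gene_ids, columns=[f"mod{i:02d}" for i in range(k_true)])
    return GroundTruth(
        true_weights=weights,
        module_members=members,
        regulon_map=regulon_map,
        genome_layout=layout,
        bgc_blocks=bgc_blocks,
        noise_sd=noise_sd,
        seed=seed,
    )


def generate_design(
    n_conditions: int,
    replicates_per_condition: int = 3,
    n_projects: int = 1,
    seed: int = 0,
) -> list[SampleDesign]:
    """Build a sample sheet: one replicate group per condition, condition 0 is
    the reference (glucose-like baseline) and must have >= 3 replicates."""
    if replicates_per_condition < 2:
        raise ValueError("replicates_per_condition must be >= 2")
    if replicates_per_condition < 3:
        raise ValueError("reference condition requires >= 3 replicates")
    if n_conditions < 1:
        raise ValueError("need at least one (reference) condition")
    design = []
    for c in range(n_conditions):
        cond = "reference" if c == 0 else f"cond{c:02d}"
        for r in range(replicates_per_condition):
            design.append(
                SampleDesign(
                    sample_id=f"C{c:02d}_R{r + 1}",
                    project=f"P{c % max(1, n_projects)}",
                    condition=cond,
                    replicate_group=f"grp{c:02d}",
                    is_reference=(c == 0),
                )
            )
    return design


#: per-condition activity scale (log2 units) and identifiability guard
ACTIVITY_SCALE = 2.0
MAX_ACTIVITY_CORR = 0.35


def _condition_activities(
    truth: GroundTruth,
    conditions: list,
    rng,
    activity_scale: float = ACTIVITY_SCALE,
    max_corr: float = MAX_ACTIVITY_CORR,
):
    """Per-condition module activities: zero at the reference condition,
    ``N(0, activity_scale^2)`` elsewhere.

    Rows whose Pearson correlation with an earlier module's activities
    exceeds ``max_corr`` in magnitude are redrawn: planted modules with
    near-collinear activities are unidentifiable by any decomposition, so
    the generator enforces the independence the planted model asserts.
    """
    k = truth.k_true
    A = np.zeros((k, len(conditions)))
    free = [c for c, cond in enumerate(conditions) if cond != "reference"]
    if not free:
        return A
    for i in range(k):
        row = rng.normal(0.0, activity_scale, len(free))
        if len(free) > 2:
            for _ in range(200):
                if all(
                    abs(np.corrcoef(row, A[j, free])[0, 1]) <= max_corr for j in range(i)
                ):
                    break
                row = rng.normal(0.0, activity_scale, len(free))
        A[i, free] = row
    return A


def synthesize_compendium(
    truth: GroundTruth,
    design: list[SampleDesign] | pd.DataFrame,
    seed: int = 0,
    condition_activities: np.ndarray | None = None,
) -> SyntheticCompendium:
    """Realize ``X = M @ A + baseline + N(0, noise_sd)`` over a sample design.

    Activities are drawn per condition and shared across replicates; the
    per-sample Gaussian noise is the replicate-to-replicate jitter.  A count
    matrix is back-computed at a fixed library size so that TPM + log2
    preprocessing reproduces the log-expression up to rounding and a
    per-sample compositional offset (TPM columns are renormalized to 1e6).

    ``condition_activities`` (k_true x n_conditions, condition order as first
    encountered in the design) overrides the random activity draw, e.g. to
    plant a condition-specific module.
    """
    design_df = design if isinstance(design, pd.DataFrame) else _design_frame(design)
    rng = np.random.default_rng(seed)

    conditions = list(dict.fromkeys(design_df["condition"]))
    if condition_activities is not None:
        A_cond = np.asarray(condition_activities, dtype=float)
        if A_cond.shape != (truth.k_true, len(conditions)):
            raise ValueError(
                f"condition_activities must be {truth.k_true} x {len(conditions)}"
            )
    else:
        A_cond = _condition_activities(truth, conditions, rng)
    cond_pos = {c: j for j, c in enumerate(conditions)}
    cols = [cond_pos[c] for c in design_df["condition"]]
    A = A_cond[:, cols]
    activities = pd.DataFrame(A, index=truth.true_weights.columns, columns=design_df.index)
    truth = dataclasses.replace(truth, true_activities=activities)

    n_genes = truth.true_weights.shape[0]
    baseline = rng.uniform(2.0, 10.0, n_genes)
    signal = truth.true_weights.to_numpy() @ A
    noise = (
        rng.normal(0.0, truth.noise_sd, signal.shape) if truth.noise_sd > 0 else np.zeros_like(signal)
    )
    Y = signal + baseline[:, None] + noise
    log_expr = pd.DataFrame(Y, index=truth.gene_ids, columns=design_df.index)

    # invert log2(TPM+1); clip so low expression cannot produce negative counts
    tpm_like = np.maximum(2.0**Y - 1.0, 0.0)
    lengths = truth.genome_layout["length_nt"].to_numpy()[:, None]
    raw = tpm_like * lengths
    counts = np.rint(raw / raw.sum(axis=0, keepdims=True) * LIBRARY_SIZE).astype(int)
    counts_df = pd.DataFrame(counts, index=truth.gene_ids, columns=design_df.index)

    genes = truth.genome_layout.copy()
    return SyntheticCompendium(
        log_expression=log_expr, counts=counts_df, genes=genes, truth=truth, design=design_df
    )


def simulate_compendium(
    n_genes: int = 2000,
    k_true: int = 12,
    n_conditions: int = 20,
    replicates_per_condition: int = 3,
    n_projects: int = 2,
    module_size_range: tuple[int, int] = (8, 40),
    noise_sd: float = 0.25,
    seed: int = 0,
    **truth_kwargs,
) -> SyntheticCompendium:
    """One-call generator with the package's default study conditions."""
    ss = np.random.SeedSequence(seed)
    s_truth, s_design, s_expr = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3))
    truth = generate_ground_truth(
        n_genes,
        k_true,
        module_size_range=module_size_range,
        seed=s_truth,
        noise_sd=noise_sd,
        **truth_kwargs,
    )
    design = generate_design(n_conditions, replicates_per_condition, n_projects, seed=s_design)
    return synthesize_compendium(truth, design, seed=s_expr)


def corrupt_replicate(
    X: pd.DataFrame, sample_id: str, corruption_sd: float, seed: int = 0
) -> pd.DataFrame:
    """Return a copy of ``X`` with heavy independent noise on one sample column,
    pushing its correlation to replicate partners below the QC threshold."""
    if sample_id not in X.columns:
        raise KeyError(f"unknown sample id: {sample_id!r}")
    if corruption_sd < 0:
        raise ValueError("corruption_sd must be non-negative")
    out = X.copy()
    if corruption_sd == 0:
        return out
    rng = np.random.default_rng(seed)
    out[sample_id] = out[sample_id] + rng.normal(0.0, corruption_sd, X.shape[0])
    return out
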