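"""Counts -> centered log2-TPM preprocessing for ICA.

Pipeline: filter genes (ORF length > 100 nt and max raw count > 10, both
strict), compute TPM per sample, log2(TPM + 1), drop samples whose replicate
correlation fails Pearson r > 0.95, and center every gene to its mean in the
reference-condition replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "compute_tpm",
    "log_transform",
    "filter_genes",
    "qc_replicates",
    "center_to_reference",
    "preprocess_counts",
    "QCReport",
]

MIN_ORF_LENGTH = 100   # nt, strict: kept genes have length > 100
MIN_MAX_COUNT = 10     # strict: kept genes have max raw count > 10
DEFAULT_R_MIN = 0.95   # replicate QC Pearson threshold, strict


@dataclass
class QCReport:
    """Replicate-QC log: removed sample ids and the correlations that caused it."""

    removed: list = field(default_factory=list)
    details: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"removed": list(self.removed), "details": self.details}


def compute_tpm(counts: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Transcripts per million per sample: length-normalized count rates
    rescaled so every column sums to 1e6."""
    missing = counts.index.difference(genes.index)
    if len(missing):
        raise KeyError(f"genes missing from gene table: {list(missing[:5])}")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    lengths = genes.loc[counts.index, "length_nt"].to_numpy(dtype=float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rates = counts.to_numpy(dtype=float) / lengths[:, None]
    colsum = rates.sum(axis=0)
    dead = np.flatnonzero(colsum == 0)
    if dead.size:
        raise ValueError(f"all-zero sample column(s): {list(counts.columns[dead])}")
    tpm = rates / colsum * 1e6
    return pd.DataFrame(tpm, index=counts.index, columns=counts.columns)


def log_transform(tpm: pd.DataFrame | np.ndarray):
    """log2(TPM + 1); the pseudocount keeps zero expression at exactly 0."""
    values = tpm.to_numpy() if isinstance(tpm, pd.DataFrame) else np.asarray(tpm, dtype=float)
    if (values < 0).any():
        raise ValueError("TPM values must be non-negative")
    out = np.log2(values + 1.0)
    if isinstance(tpm, pd.DataFrame):
        return pd.DataFrame(out, index=tpm.index, columns=tpm.columns)
    return out


def filter_genes(counts: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Keep genes with ORF length > 100 nt AND max raw count > 10 (strict)."""
    lengths = genes.loc[counts.index, "length_nt"]
    keep = (lengths > MIN_ORF_LENGTH) & (counts.max(axis=1) > MIN_MAX_COUNT)
    out = counts.loc[keep]
    if out.empty:
        warnings.warn("gene filtering removed every gene", stacklevel=2)
    return out


def _pairwise_r(X: np.ndarray) -> np.ndarray:
    # columns = samples; corrcoef over genes
    return np.corrcoef(X, rowvar=False)


def qc_replicates(
    X: pd.DataFrame, design: pd.DataFrame, r_min: float = DEFAULT_R_MIN
) -> tuple[pd.DataFrame, QCReport]:
    """Drop samples until, within each replicate group, all pairwise Pearson
    correlations exceed ``r_min``.

    The worst sample (lowest mean pairwise r) is removed iteratively; a group
    whittled below two samples is removed entirely, since an unreplicated
    sample cannot demonstrate the required correlation.
    """
    report = QCReport()
    keep: list[str] = []
    for group, rows in design.groupby("replicate_group", sort=False):
        samples = [s for s in rows.index if s in X.columns]
        if len(samples) < 2:
            report.removed.extend(samples)
            if samples:
                report.details[group] = {"reason": "group smaller than 2 samples"}
            continue
        current = list(samples)
        dropped_here: list[str] = []
        while len(current) >= 2:
            R = _pairwise_r(X[current].to_numpy())
            off = R[np.triu_indices(len(current), k=1)]
            if (off > r_min).all():
                break
            mean_r = (R.sum(axis=0) - 1.0) / (len(current) - 1)
            worst = int(np.argmin(mean_r))
            dropped_here.append(current.pop(worst))
        if len(current) < 2:
            dropped_here.extend(current)
            current = []
        if dropped_here:
            report.removed.extend(dropped_here)
            report.details[group] = {
                "removed": dropped_here,
                "retained": list(current),
            }
        keep.extend(current)
    return X[keep], report


def center_to_reference(X: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Subtract, per gene, the mean expression over the reference-condition
    replicates, so reference columns average to zero for every gene."""
    ref = design.index[design["is_reference"].astype(bool)]
    ref = [s for s in ref if s in X.columns]
    if len(ref) < 3:
        raise ValueError("reference replicate group must retain >= 3 samples")
    mean_ref = X[ref].mean(axis=1)
    return X.sub(mean_ref, axis=0)


def preprocess_counts(
    counts: pd.DataFrame,
    genes: pd.DataFrame,
    design: pd.DataFrame,
    r_min: float = DEFAULT_R_MIN,
) -> tuple[pd.DataFrame, QCReport]:
    """Full pipeline: filter -> TPM -> log2 -> replicate QC -> center.

    Returns the centered log2-TPM matrix restricted to QC-passing samples,
    plus the QC report.
    """
    filtered = filter_genes(counts, genes)
    logx = log_transform(compute_tpm(filtered, genes))
    logx, report = qc_replicates(logx, design, r_min=r_min)
    centered = center_to_reference(logx, design.loc[design.index.intersection(logx.columns)])
    return centered, report
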