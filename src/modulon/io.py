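"""Plain-text readers and writers for the pipeline's tables.

All matrices are TSV with row ids in the first column; metadata tables are
TSV with a header; ground truth and QC reports are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_gene_table",
    "read_sample_table",
    "write_sample_table",
    "read_regulons",
    "write_truth_json",
    "read_truth_json",
    "write_imodulons_json",
    "read_bgc_regions",
    "read_category_table",
]


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_gene_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    required = {"length_nt", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    return df


def read_sample_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    df["is_reference"] = df["is_reference"].astype(bool)
    return df


def write_sample_table(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t")


def read_regulons(path) -> dict:
    """Regulon TSV (columns: regulator, target_gene) -> {regulator: gene set}."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, set] = {}
    for reg, grp in df.groupby("regulator"):
        out[str(reg)] = set(grp["target_gene"])
    return out


def write_truth_json(truth, path) -> None:
    payload = {
        "seed": truth.seed,
        "noise_sd": truth.noise_sd,
        "module_members": [sorted(m) for m in truth.module_members],
        "regulons": {k: sorted(v) for k, v in truth.regulon_map.items()},
        "bgc_blocks": [
            {"module": m, "first_gene": int(iv[0]), "last_gene": int(iv[1]),
             "core_genes": sorted(core)}
            for m, iv, core in truth.bgc_blocks
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth_json(path) -> dict:
    return json.loads(Path(path).read_text())


def write_imodulons_json(imodulons, path) -> None:
    payload = [
        {
            "id": im.id,
            "members": sorted(im.members),
            "threshold": im.threshold,
            "explained_variance": im.explained_variance,
            "category": im.category,
            "regulator": im.regulator,
        }
        for im in imodulons
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_bgc_regions(path):
    """BGC regions TSV (region_id, first_gene, last_gene, core_genes
    semicolon-separated, product) -> list of BGCRegion."""
    from .bgc import BGCRegion

    df = pd.read_csv(path, sep="\t")
    regions = []
    for _, row in df.iterrows():
        cores = set(str(row["core_genes"]).split(";")) if pd.notna(row["core_genes"]) else set()
        regions.append(
            BGCRegion(
                region_id=str(row["region_id"]),
                first_gene=int(row["first_gene"]),
                last_gene=int(row["last_gene"]),
                core_genes=cores,
                product=str(row.get("product", "")),
            )
        )
    return regions


def read_category_table(path) -> dict:
    """Annotation TSV (imodulon, category, regulator) -> {id: (category, regulator)}."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for _, row in df.iterrows():
        reg = row.get("regulator")
        out[str(row["imodulon"])] = (
            str(row["category"]),
            None if pd.isna(reg) else str(reg),
        )
    return out
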