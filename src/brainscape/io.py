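"""Readers and writers for the pipeline's interchange formats.

Everything is plain TSV/JSON: expression matrices (genes as rows, first
column the gene id, header row of sample ids), sample metadata, MAF-like
mutation tables, fusion tables, GISTIC-thresholded copy-number matrices,
landscape coordinates, and JSON run manifests.  Gene and sample
identifiers are opaque strings matched exactly — symbol aliasing is a
data-curation concern upstream of this pipeline.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .landscape import Landscape
from .matrix import ExpressionMatrix, SampleMetadata

FUSION_CONFIDENCE_VOCAB = ("high", "medium", "low")
CNV_VOCAB = (-2, -1, 0, 1, 2)


# ---------------------------------------------------------------- expression

def write_expression(m: ExpressionMatrix, path) -> None:
    df = m.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_expression(path, unit: str) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df, unit)


# ------------------------------------------------------------------ metadata

def write_metadata(meta: SampleMetadata, path) -> None:
    t = meta.table.copy()
    t.index.name = "sample_id"
    t.to_csv(path, sep="\t", float_format="%.17g")


def read_metadata(path) -> SampleMetadata:
    t = pd.read_csv(path, sep="\t", index_col="sample_id", dtype={"sample_id": str})
    return SampleMetadata(t)


# ------------------------------------------------------------------ overlays

def read_mutations(path) -> pd.DataFrame:
    """MAF-like table: sample_id, gene_id, variant_class; extras ignored.

    Rows are canonicalized to the three required columns; fully duplicated
    rows are collapsed.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "gene_id", "variant_class"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: mutation table missing columns {missing}")
    out = df[required].drop_duplicates().reset_index(drop=True)
    return out


def read_fusions(path, retain: tuple[str, ...] = ("high",)) -> tuple[pd.DataFrame, int]:
    """Fusion table with a confidence filter; returns (kept rows, n removed)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "gene_5prime", "gene_3prime", "confidence"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: fusion table missing columns {missing}")
    bad = ~df["confidence"].isin(FUSION_CONFIDENCE_VOCAB)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based incl. header
        raise ValueError(
            f"{path}: row {row}: confidence {df.loc[bad].iloc[0]['confidence']!r} "
            f"not in {FUSION_CONFIDENCE_VOCAB}"
        )
    keep = df["confidence"].isin(retain)
    removed = int((~keep).sum())
    return df[keep][required].reset_index(drop=True), removed


def read_cnv(paths) -> pd.DataFrame:
    """GISTIC-thresholded gene x sample integer matrix in {-2..2}.

    Accepts one path or several (column-concatenated; duplicate samples or
    conflicting gene sets are errors).
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    frames = []
    for p in paths:
        df = pd.read_csv(p, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        vals = df.to_numpy()
        bad = ~np.isin(vals, CNV_VOCAB)
        if bad.any():
            gi, si = np.argwhere(bad)[0]
            raise ValueError(
                f"{p}: invalid copy-number value {vals[gi, si]!r} "
                f"for gene {df.index[gi]!r}, sample {df.columns[si]!r}"
            )
        frames.append(df.astype(int))
    out = pd.concat(frames, axis=1)
    if out.columns.has_duplicates:
        dups = out.columns[out.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate samples across copy-number inputs: {dups[:5]}")
    if out.isna().any().any():
        raise ValueError("copy-number inputs cover different gene sets")
    return out


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.17g")


# ------------------------------------------------------------------- burdens

def burden_per_sample(table: pd.DataFrame, sample_ids=None) -> pd.Series:
    """Row count per sample (point mutations or fusions per tumor).

    ``sample_ids`` extends the result with explicit zeros for samples
    absent from the table.
    """
    counts = table.groupby("sample_id").size()
    if sample_ids is not None:
        counts = counts.reindex(list(sample_ids), fill_value=0)
    return counts.rename("burden").astype(int)


def cnv_burden_per_sample(cnv: pd.DataFrame) -> pd.DataFrame:
    """Per-sample count of genes gained (value >= 1) and lost (value <= -1)."""
    gained = (cnv >= 1).sum(axis=0)
    lost = (cnv <= -1).sum(axis=0)
    return pd.DataFrame({"n_genes_gained": gained, "n_genes_lost": lost}).rename_axis(
        "sample_id"
    )


def overlay_gene(
    L: Landscape,
    gene: str,
    m: ExpressionMatrix,
    mutations: pd.DataFrame | None = None,
    fusions: pd.DataFrame | None = None,
    cnv: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join expression, mutation, fusion and copy-number status for one gene.

    One row per landscape sample.  A sample missing from an overlay input —
    or an overlay not provided at all — gets an explicit null for that
    column; a gene matches a fusion when it appears as either partner.
    """
    if gene not in m.gene_ids:
        raise ValueError(f"gene {gene!r} not in the expression matrix")
    expr = m.values.loc[gene]
    rows = {}
    mut_pairs = None
    if mutations is not None:
        mut_pairs = set(zip(mutations["sample_id"], mutations["gene_id"]))
    fus_samples = None
    if fusions is not None:
        hit = fusions[(fusions["gene_5prime"] == gene) | (fusions["gene_3prime"] == gene)]
        fus_samples = set(hit["sample_id"])
    for sid in L.sample_ids:
        rows[sid] = {
            "expression": float(expr[sid]) if sid in expr.index else np.nan,
            "mutated": None if mut_pairs is None else (sid, gene) in mut_pairs,
            "fusion": None if fus_samples is None else sid in fus_samples,
            "cn_level": (
                None
                if cnv is None or gene not in cnv.index or sid not in cnv.columns
                else int(cnv.at[gene, sid])
            ),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out


# ----------------------------------------------------------------- landscape

def write_landscape(L: Landscape, path_tsv, path_json=None) -> None:
    df = L.to_frame().copy()
    df["method"] = L.method
    df["seed"] = L.seed
    df.to_csv(path_tsv, sep="\t", float_format="%.17g")
    if path_json is not None:
        payload = {
            "method": L.method,
            "seed": L.seed,
            "provenance": L.provenance,
            "d": L.d,
            "n_samples": len(L.sample_ids),
        }
        Path(path_json).write_text(json.dumps(payload, sort_keys=True, indent=1))


def read_landscape(path_tsv, path_json=None) -> Landscape:
    df = pd.read_csv(path_tsv, sep="\t", index_col="sample_id")
    coord_cols = [c for c in ("x", "y", "z") if c in df.columns]
    method = str(df["method"].iloc[0])
    seed = int(df["seed"].iloc[0])
    provenance = ""
    if path_json is not None:
        provenance = json.loads(Path(path_json).read_text())["provenance"]
    return Landscape(
        sample_ids=[str(s) for s in df.index],
        coordinates=df[coord_cols].to_numpy(dtype=float),
        method=method,
        seed=seed,
        provenance=provenance,
    )


# ------------------------------------------------------------------ genesets

def write_gmt(sets: dict[str, tuple[str, ...]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


# ----------------------------------------------------------------- manifests

def file_digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path, stage: str, inputs: dict, outputs: dict, params: dict, seed) -> None:
    """JSON run manifest: stage, parameter values, seed, and file digests."""
    from . import __version__

    payload = {
        "stage": stage,
        "version": __version__,
        "seed": seed,
        "params": params,
        "inputs": {k: file_digest(v) for k, v in inputs.items()},
        "outputs": {k: file_digest(v) for k, v in outputs.items()},
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1))
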