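"""Readers and writers for the pipeline's interchange formats.

TSV is canonical throughout: OTU tables carry samples in rows and OTU ids
(kingdom-prefixed ``b_`` / ``f_``) in the header; function tables carry a
companion direction row file or a sidecar mapping.  BIOM-style JSON (dense
or sparse, observations x samples per that format's convention) is supported
read-only.  Networks are written as edge-list TSV and GraphML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import BENEFIT, LOSS, FunctionTable, OtuTable, SupportMap


# ---------------------------------------------------------------- OTU tables
def write_otu_table(table: OtuTable, path, meta_path=None) -> None:
    table.abundance.to_csv(path, sep="\t", index_label="sample")
    if meta_path is not None and table.sample_meta is not None:
        table.sample_meta.to_csv(meta_path, sep="\t", index_label="sample")


def read_otu_table(path, fmt: str = "tsv", meta_path=None,
                   kingdom: pd.Series | None = None) -> OtuTable:
    """Read an OTU table from TSV or BIOM-style JSON.

    Orientation is auto-detected for TSV: if the header looks like OTU ids
    (``b_`` / ``f_`` prefixes) samples are taken to be rows, otherwise the
    matrix is transposed.  Kingdoms come from id prefixes unless an explicit
    mapping is given.
    """
    if fmt == "tsv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
        dup = pd.Index(header)[pd.Index(header).duplicated()].unique().tolist()
        if dup:
            raise ValueError(f"{path}: duplicate OTU id(s) {dup}")
        df = pd.read_csv(path, sep="\t", index_col=0)
        cols_look_like_otus = all(
            str(c).startswith(("b_", "f_")) for c in df.columns)
        rows_look_like_otus = all(
            str(r).startswith(("b_", "f_")) for r in df.index)
        if not cols_look_like_otus and rows_look_like_otus:
            df = df.T
        elif not cols_look_like_otus and kingdom is None:
            raise ValueError(
                f"{path}: cannot orient table — neither axis carries "
                "kingdom-prefixed OTU ids and no kingdom mapping was given")
    elif fmt == "biom-json":
        df = _read_biom_json(path)
    else:
        raise ValueError(f"unknown OTU table format {fmt!r}")
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate OTU id(s) {dups}")
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        missing = df.index.difference(meta.index)
        if len(missing):
            raise ValueError(
                f"metadata missing for sample(s): {missing.tolist()}")
        meta = meta.reindex(df.index)
    return OtuTable(df, kingdom=kingdom, sample_meta=meta)


def _read_biom_json(path) -> pd.DataFrame:
    """Minimal BIOM 1.0 JSON reader (dense and sparse matrix types);
    observations are rows in the file, returned transposed to samples x
    OTUs."""
    with open(path) as fh:
        doc = json.load(fh)
    obs = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    shape = tuple(doc["shape"])
    mat = np.zeros(shape)
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    else:
        mat[:] = np.asarray(doc["data"], dtype=float)
    out = pd.DataFrame(mat, index=obs, columns=samples).T
    out.index.name = "sample"
    return out


# ----------------------------------------------------------- function tables
def write_function_table(functions: FunctionTable, path, direction_path) -> None:
    functions.values.to_csv(path, sep="\t", index_label="sample")
    functions.direction.rename("direction").to_csv(
        direction_path, sep="\t", index_label="function")


def read_function_table(path, direction_path=None, loss_functions=()) -> FunctionTable:
    vals = pd.read_csv(path, sep="\t", index_col=0)
    if direction_path is not None:
        direction = pd.read_csv(direction_path, sep="\t", index_col=0)["direction"]
    else:
        direction = pd.Series(
            {c: (LOSS if c in set(loss_functions) else BENEFIT)
             for c in vals.columns})
    return FunctionTable(vals, direction)


# ------------------------------------------------------------------ networks
def write_network(results, edge_path, graphml_path=None,
                  instability_path=None) -> None:
    results.edge_list().to_csv(edge_path, sep="\t", index=False)
    if graphml_path is not None:
        import networkx as nx

        nx.write_graphml(results.graph(), graphml_path)
    if instability_path is not None:
        pd.DataFrame(
            {
                "lambda": results.lambda_path,
                "instability": results.instability_path,
                "monotone_instability": results.monotone_instability,
            }
        ).to_csv(instability_path, sep="\t", index=False)


# --------------------------------------------------------------- support map
def write_support_map(support_map: SupportMap, tsv_path, json_path=None) -> None:
    support_map.to_frame().to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        doc = {
            f: {
                "alpha": e.alpha,
                "lambda": e.lam,
                "cv_mse": e.cv_mse,
                "coefficients": {
                    k: float(v) for k, v in
                    e.coefficients[e.coefficients != 0].items()
                },
            }
            for f, e in support_map.entries.items()
        }
        Path(json_path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def read_support_map(tsv_path) -> SupportMap:
    from .containers import SupportEntry

    df = pd.read_csv(tsv_path, sep="\t")
    entries = {}
    for f, grp in df.groupby("function", sort=False):
        coefs = pd.Series(grp["coefficient"].to_numpy(),
                          index=pd.Index(grp["otu_id"]), name=f)
        entries[f] = SupportEntry(
            function=f,
            coefficients=coefs,
            alpha=float(grp["alpha"].iloc[0]),
            lam=float(grp["lambda"].iloc[0]),
            cv_mse=float(grp["cv_mse"].iloc[0]),
        )
    return SupportMap(entries)


# --------------------------------------------------------------------- truth
def write_truth(truth, path) -> None:
    doc = {
        "true_edges": sorted([sorted(e) for e in truth.true_edges]),
        "supporter_sets": {f: dict(s) for f, s in truth.supporter_sets.items()},
        "effect_weights": {f: dict(w) for f, w in truth.effect_weights.items()},
    }
    if truth.level_masks is not None:
        doc["level_masks"] = {
            str(lv): truth.level_masks.columns[row.to_numpy()].tolist()
            for lv, row in truth.level_masks.iterrows()
        }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


__all__ = [
    "read_otu_table",
    "write_otu_table",
    "read_function_table",
    "write_function_table",
    "write_network",
    "write_support_map",
    "read_support_map",
    "write_truth",
]
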