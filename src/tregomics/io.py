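"""Readers and writers for the pipeline's plain-text interchange formats.

Conventions: TSV matrices with genes in rows and samples in columns
(first column = gene id), TSV design tables, GMT gene-set catalogs,
TSV edge lists (node_a, node_b, weight, support) and MatrixMarket (MTX)
as an alternative count container.  All round trips are lossless on
valid files; malformed rows raise :class:`ParseError` with a line number.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datamodel import CountMatrix, ProteinQuant, SampleDesign, ValidationError


class ParseError(ValueError):
    pass


def read_counts(path, gene_meta_path=None) -> CountMatrix:
    """Read a gene x sample count TSV (or MTX given sidecar row/col files)."""
    path = Path(path)
    if path.suffix == ".mtx":
        mat = scipy.io.mmread(path)
        genes = Path(str(path) + ".rows").read_text().split()
        samples = Path(str(path) + ".cols").read_text().split()
        values = pd.DataFrame(
            np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat),
            index=genes,
            columns=samples,
        )
    else:
        values = pd.read_csv(path, sep="\t", index_col=0)
    arr = values.to_numpy()
    if not np.isfinite(arr).all():
        bad = int(np.where(~np.isfinite(arr).all(axis=1))[0][0]) + 2
        raise ParseError(f"{path}: non-finite count at line {bad}")
    meta = None
    if gene_meta_path is not None:
        meta = pd.read_csv(gene_meta_path, sep="\t", index_col=0)
    return CountMatrix(values, gene_meta=meta)


def write_counts(counts: CountMatrix, path, mtx: bool = False) -> None:
    path = Path(path)
    if mtx:
        scipy.io.mmwrite(str(path), scipy.sparse.csr_matrix(counts.values.to_numpy()))
        Path(str(path) + ".rows").write_text("\n".join(counts.gene_ids) + "\n")
        Path(str(path) + ".cols").write_text("\n".join(counts.sample_ids) + "\n")
    else:
        counts.values.to_csv(path, sep="\t", index_label="gene_id")
    if counts.gene_meta is not None and not mtx:
        counts.gene_meta.to_csv(
            path.with_suffix(".gene_meta.tsv"), sep="\t", index_label="gene_id"
        )


def read_design(path) -> SampleDesign:
    table = pd.read_csv(path, sep="\t", index_col=0)
    try:
        return SampleDesign(table)
    except ValidationError as err:
        raise ParseError(f"{path}: {err}") from err


def write_design(design: SampleDesign, path) -> None:
    design.table.to_csv(path, sep="\t", index_label="sample_id")


def read_gmt(path) -> dict[str, dict]:
    """Read a GMT catalog: one set per line, name TAB description TAB genes."""
    catalog: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >= 3 tab fields")
            name, desc, *genes = fields
            if name in catalog:
                raise ParseError(f"{path}: line {lineno}: duplicated set name {name!r}")
            catalog[name] = {"description": desc, "genes": [g for g in genes if g]}
    return catalog


def write_gmt(catalog: dict[str, dict], path) -> None:
    with open(path, "w") as fh:
        for name, entry in catalog.items():
            genes = entry["genes"] if isinstance(entry, dict) else list(entry)
            desc = entry.get("description", "") if isinstance(entry, dict) else ""
            fh.write("\t".join([name, desc, *genes]) + "\n")


EDGE_COLUMNS = ("node_a", "node_b", "weight", "support")


def read_edges(path) -> pd.DataFrame:
    edges = pd.read_csv(path, sep="\t")
    missing = [c for c in EDGE_COLUMNS if c not in edges.columns]
    if missing:
        raise ParseError(f"{path}: missing edge columns {missing}")
    return edges


def write_edges(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_protein_matrix(path) -> ProteinQuant:
    """Protein-level log2R TSV (proteins x samples); NA marks not quantified."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    return ProteinQuant(values)


def write_protein_matrix(pq: ProteinQuant, path) -> None:
    pq.log2r.to_csv(path, sep="\t", index_label="protein_id")


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.ndarray, pd.Index)):
            return list(o)
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=1, default=_default) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
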