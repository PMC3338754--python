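"""Readers and writers for the plain-text interchange formats.

* expression TSV: samples in rows, first column ``sample``, header lists
  gene ids;
* labels TSV: ``sample_id<TAB>label`` with an optional third ``er``
  column;
* GMT: one gene set per line, ``name<TAB>description<TAB>gene...``;
* edge list: two tab-separated gene ids per line, ``#`` comments ignored.

Round-tripping write -> read reproduces the in-memory object up to float
formatting at 10 significant digits.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import ExpressionDataset, GeneSetCollection, Network

__all__ = [
    "write_expression",
    "read_expression",
    "write_labels",
    "read_labels",
    "read_dataset",
    "write_dataset",
    "read_gmt",
    "write_gmt",
    "read_edge_list",
    "write_edge_list",
]

_FLOAT_FMT = "%.10g"


def write_expression(ds: ExpressionDataset, path) -> None:
    df = pd.DataFrame(ds.values, index=ds.sample_ids, columns=ds.gene_ids)
    df.index.name = "sample"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_expression(path):
    """Read an expression TSV; returns (sample_ids, gene_ids, values)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    genes = header[1:]
    dup = {g for g in genes if genes.count(g) > 1} if len(set(genes)) != len(genes) else set()
    if dup:
        raise ValueError(f"duplicate gene in header: {sorted(dup)}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    return [str(s) for s in df.index], genes, df.to_numpy(dtype=float)


def write_labels(ds: ExpressionDataset, path) -> None:
    cols = {"sample": ds.sample_ids, "label": ds.labels}
    if ds.er_status is not None:
        cols["er"] = ds.er_status
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_labels(path):
    """Read a labels TSV; returns (sample_ids, labels, er_status_or_None)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("labels file needs at least two columns")
    samples = [str(s) for s in df.iloc[:, 0]]
    labels = df.iloc[:, 1].to_numpy(dtype=int)
    er = df["er"].to_numpy(dtype=int) if "er" in df.columns else None
    return samples, labels, er


def write_dataset(ds: ExpressionDataset, expr_path, labels_path) -> None:
    write_expression(ds, expr_path)
    write_labels(ds, labels_path)


def read_dataset(expr_path, labels_path, name: str = "") -> ExpressionDataset:
    samples, genes, values = read_expression(expr_path)
    lab_samples, labels, er = read_labels(labels_path)
    if lab_samples != samples:
        order = {s: i for i, s in enumerate(lab_samples)}
        missing = [s for s in samples if s not in order]
        if missing:
            raise ValueError(f"labels missing for samples: {missing[:10]}")
        idx = [order[s] for s in samples]
        labels = labels[idx]
        er = None if er is None else er[idx]
    return ExpressionDataset(samples, genes, values, labels, er, name=name)


def read_gmt(path) -> GeneSetCollection:
    sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description "
                    "and at least one gene"
                )
            name, genes = parts[0], [g for g in parts[2:] if g]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            if not genes:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = genes
    return GeneSetCollection(sets)


def write_gmt(coll: GeneSetCollection, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in coll.sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_edge_list(path) -> Network:
    nodes, edges = set(), []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ValueError(
                    f"{path}:{lineno}: expected two tab-separated gene ids"
                )
            a, b = parts
            if a == b:
                raise ValueError(f"{path}:{lineno}: self-loop on {a!r}")
            nodes.update((a, b))
            edges.append((a, b))
    return Network(nodes, edges)


def write_edge_list(net: Network, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(net.edges):
            fh.write(f"{a}\t{b}\n")
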