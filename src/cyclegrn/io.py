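"""Readers and writers for the plain-text formats the pipeline touches.

Expression matrices travel as genes x cells TSV (first column gene ids,
header row cell ids) or as a MatrixMarket coordinate triplet with
``genes.tsv`` / ``barcodes.tsv`` sidecars (10x-style layout). Networks are
TSV edge lists with a ``source target weight sign`` header; ground-truth
references are two-column ``source target`` lists. Cell metadata is a
``cell_id time`` TSV and cycle-gene lists are one identifier per line.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import io as sio
from scipy import sparse

from .benchmark import GroundTruth
from .containers import CellClock, ExpressionMatrix, WeightedNetwork

logger = logging.getLogger(__name__)


def read_expression(path: str | Path, format: str = "tsv", layer: str = "counts") -> ExpressionMatrix:
    """Load an expression matrix from TSV or MatrixMarket triplet.

    TSV: genes in rows, cells in columns, first column gene ids, header
    row cell ids. MTX: ``path`` is the ``.mtx`` file; ``genes.tsv`` and
    ``barcodes.tsv`` sidecars are expected next to it (one id per line).
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers in {path}: {dups}")
    elif format == "mtx":
        mat = sio.mmread(path)
        genes = _read_id_list(path.parent / "genes.tsv")
        cells = _read_id_list(path.parent / "barcodes.tsv")
        if mat.shape != (len(genes), len(cells)):
            raise ValueError(
                f"dimension mismatch: matrix is {mat.shape[0]}x{mat.shape[1]} but "
                f"sidecars list {len(genes)} genes and {len(cells)} barcodes"
            )
        dense = mat.toarray() if sparse.issparse(mat) else np.asarray(mat)
        df = pd.DataFrame(dense, index=genes, columns=cells)
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers in sidecar: {dups}")
    else:
        raise ValueError(f"unknown expression format {format!r}")
    if (df.to_numpy() < 0).any():
        raise ValueError(f"negative expression values in {path}")
    return ExpressionMatrix(df, layer=layer)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    """Write genes x cells TSV (round-trips bit-identically through
    :func:`read_expression` for exactly-representable values)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    expr.values.to_csv(path, sep="\t", index_label="gene")


def write_expression_mtx(expr: ExpressionMatrix, path: str | Path) -> None:
    """Write MatrixMarket triplet plus genes.tsv / barcodes.tsv sidecars."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(path, sparse.coo_matrix(expr.values.to_numpy()))
    (path.parent / "genes.tsv").write_text("\n".join(expr.genes) + "\n")
    (path.parent / "barcodes.tsv").write_text("\n".join(expr.cells) + "\n")


def _read_id_list(path: Path) -> list[str]:
    if not path.exists():
        raise FileNotFoundError(f"sidecar file missing: {path}")
    ids = [ln.split("\t")[0].strip() for ln in path.read_text().splitlines() if ln.strip()]
    return ids


def read_cycle_genes(path: str | Path) -> list[str]:
    """One gene identifier per line, blanks and '#' comments ignored."""
    out = []
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if ln and not ln.startswith("#"):
            out.append(ln)
    return out


def read_cell_metadata(path: str | Path) -> pd.DataFrame:
    """TSV with columns ``cell_id`` and ``time`` (hours)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    required = {"cell_id", "time"}
    if not required <= set(df.columns):
        raise ValueError(f"cell metadata must have columns {sorted(required)}")
    if df["cell_id"].duplicated().any():
        raise ValueError("duplicate cell_id in metadata")
    return df


def write_cell_metadata(clock: CellClock, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    clock.to_frame().to_csv(path, sep="\t", index=False)


def read_network(path: str | Path, directed: bool = True, method_tag: str = "") -> WeightedNetwork:
    """Edge-list TSV with header ``source target weight [sign]``.

    A missing sign column defaults to 0. Malformed rows are reported with
    their line number.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path} is empty")
    header = lines[0].split("\t")
    if header[:3] != ["source", "target", "weight"]:
        raise ValueError(f"{path}: expected header 'source\\ttarget\\tweight[\\tsign]'")
    has_sign = len(header) > 3 and header[3] == "sign"
    records = []
    for lineno, ln in enumerate(lines[1:], start=2):
        if not ln.strip():
            continue
        parts = ln.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}: malformed row at line {lineno}: {ln!r}")
        try:
            w = float(parts[2])
        except ValueError:
            raise ValueError(
                f"{path}: non-numeric weight at line {lineno}: {parts[2]!r}"
            ) from None
        sign = 0
        if has_sign and len(parts) > 3 and parts[3] != "":
            try:
                sign = int(parts[3])
            except ValueError:
                raise ValueError(
                    f"{path}: non-integer sign at line {lineno}: {parts[3]!r}"
                ) from None
        records.append((parts[0], parts[1], w, sign))
    return WeightedNetwork.from_records(records, directed=directed, method_tag=method_tag)


def write_network(net: WeightedNetwork, path: str | Path) -> None:
    """Write edges in descending weight; read-write-read is identity."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = net.sorted_edges()
    with open(path, "w") as fh:
        fh.write("source\ttarget\tweight\tsign\n")
        for s, t, w, sg in zip(df["source"], df["target"], df["weight"], df["sign"]):
            fh.write(f"{s}\t{t}\t{w!r}\t{sg}\n")


def read_ground_truth(
    path: str | Path,
    directed: bool = False,
    gene_universe: Optional[list[str]] = None,
) -> GroundTruth:
    """Two-column ``source target`` TSV (header optional).

    The gene universe defaults to the genes appearing in the file; pass
    the full analyzed gene set explicitly so the density reflects all
    candidate pairs.
    """
    path = Path(path)
    edges = set()
    genes_seen: list[str] = []
    for lineno, ln in enumerate(path.read_text().splitlines(), start=1):
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}: malformed row at line {lineno}: {ln!r}")
        if lineno == 1 and parts[0] == "source" and parts[1] == "target":
            continue
        edges.add((parts[0], parts[1]))
        genes_seen.extend(parts[:2])
    universe = gene_universe if gene_universe is not None else sorted(set(genes_seen))
    return GroundTruth(gene_universe=universe, true_edges=edges, directed=directed)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("source\ttarget\n")
        for s, t in sorted(truth.true_edges):
            fh.write(f"{s}\t{t}\n")
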