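"""Core in-memory containers shared across the pipeline.

Three objects travel between stages:

* :class:`ExpressionMatrix` — a genes x cells matrix with a layer tag
  distinguishing raw counts from log-normalized values.
* :class:`CellClock` — per-cell temporal coordinates: experimental time in
  hours, cycle phase theta in [0, 2*pi), the integrated-theta hybrid
  coordinate, and the ordinal bin index used by temporal inference.
* :class:`WeightedNetwork` — a ranked edge list (source, target, weight,
  sign), the universal output of every inference method.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

TWO_PI = 2.0 * np.pi

LAYER_COUNTS = "counts"
LAYER_LOGNORM = "lognorm"

ORDERING_MODES = ("real", "tricycle", "theta")


@dataclass
class ExpressionMatrix:
    """Genes x cells expression values.

    Parameters
    ----------
    values
        DataFrame with gene identifiers as index and cell identifiers as
        columns. Values must be finite and non-negative for the counts
        layer.
    layer
        ``"counts"`` for raw counts or ``"lognorm"`` for depth-scaled
        log(1+x) values.
    """

    values: pd.DataFrame
    layer: str = LAYER_COUNTS

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.layer not in (LAYER_COUNTS, LAYER_LOGNORM):
            raise ValueError(f"unknown layer tag {self.layer!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate cell identifiers: {dups}")
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite")
        if self.layer == LAYER_COUNTS and (arr < 0).any():
            raise ValueError("counts layer contains negative values")

    @property
    def genes(self) -> list[str]:
        return [str(g) for g in self.values.index]

    @property
    def cells(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes not present in matrix: {missing}")
        return ExpressionMatrix(self.values.loc[list(genes)].copy(), layer=self.layer)


@dataclass
class CellClock:
    """Per-cell temporal coordinates and the active ordering.

    ``theta`` is the circular cell-cycle position; ``integrated_theta``
    places consecutive experimental time points 2*pi apart with
    within-point ordering given by theta. ``bin_index`` is the ordinal
    discretization actually consumed by temporal inference and is a
    non-decreasing function of the active ordering's coordinate.
    """

    cell_ids: np.ndarray
    real_time: np.ndarray
    theta: Optional[np.ndarray] = None
    integrated_theta: Optional[np.ndarray] = None
    bin_index: Optional[np.ndarray] = None
    ordering_mode: Optional[str] = None

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.real_time = np.asarray(self.real_time, dtype=float)
        n = self.cell_ids.shape[0]
        if self.real_time.shape[0] != n:
            raise ValueError("real_time length does not match cell_ids")
        if len(set(self.cell_ids.tolist())) != n:
            raise ValueError("duplicate cell identifiers in clock")
        if self.theta is not None:
            self.theta = np.asarray(self.theta, dtype=float)
            if self.theta.shape[0] != n:
                raise ValueError("theta length does not match cell_ids")
            if np.any((self.theta < 0) | (self.theta >= TWO_PI)):
                raise ValueError("theta must lie in [0, 2*pi)")
        if self.integrated_theta is not None:
            self.integrated_theta = np.asarray(self.integrated_theta, dtype=float)
            if self.integrated_theta.shape[0] != n:
                raise ValueError("integrated_theta length does not match cell_ids")
        if self.bin_index is not None:
            self.bin_index = np.asarray(self.bin_index, dtype=int)
            if self.bin_index.shape[0] != n:
                raise ValueError("bin_index length does not match cell_ids")
        if self.ordering_mode is not None and self.ordering_mode not in ORDERING_MODES:
            raise ValueError(f"unknown ordering mode {self.ordering_mode!r}")

    @property
    def n_cells(self) -> int:
        return self.cell_ids.shape[0]

    @property
    def n_bins(self) -> int:
        if self.bin_index is None:
            raise ValueError("no binning has been applied")
        return int(self.bin_index.max()) + 1

    def with_(self, **kwargs) -> "CellClock":
        return replace(self, **kwargs)

    def to_frame(self) -> pd.DataFrame:
        data = {"cell_id": self.cell_ids, "time": self.real_time}
        if self.theta is not None:
            data["theta"] = self.theta
        if self.integrated_theta is not None:
            data["integrated_theta"] = self.integrated_theta
        if self.bin_index is not None:
            data["bin_index"] = self.bin_index
        return pd.DataFrame(data)


_EDGE_COLUMNS = ["source", "target", "weight", "sign"]


@dataclass
class WeightedNetwork:
    """Ranked edge list produced by an inference method.

    Undirected networks store each pair once with ``source < target``
    lexicographically. Weights are finite and non-negative; the canonical
    edge order is descending weight with lexicographic (source, target)
    tie-breaking.
    """

    edges: pd.DataFrame
    directed: bool
    method_tag: str = ""
    ordering_mode: Optional[str] = None

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.edges)
        if df.empty and not set(_EDGE_COLUMNS) <= set(df.columns):
            df = pd.DataFrame(columns=_EDGE_COLUMNS)
        if "sign" not in df.columns:
            df = df.assign(sign=0)
        df = df[_EDGE_COLUMNS].copy()
        df["source"] = df["source"].astype(str)
        df["target"] = df["target"].astype(str)
        df["weight"] = df["weight"].astype(float)
        df["sign"] = df["sign"].astype(int)
        if not df["sign"].isin([-1, 0, 1]).all():
            raise ValueError("edge sign must be -1, 0 or +1")
        if not np.all(np.isfinite(df["weight"].to_numpy())):
            raise ValueError("edge weights must be finite")
        if (df["weight"].to_numpy() < 0).any():
            raise ValueError("edge weights must be non-negative")
        if (df["source"] == df["target"]).any():
            raise ValueError("self-loops are not allowed")
        if not self.directed:
            flip = df["source"] > df["target"]
            if flip.any():
                src = df["source"].where(~flip, df["target"])
                tgt = df["target"].where(~flip, df["source"])
                df["source"], df["target"] = src, tgt
        if df.duplicated(subset=["source", "target"]).any():
            dups = df[df.duplicated(subset=["source", "target"])]
            pairs = list(zip(dups["source"], dups["target"]))
            raise ValueError(f"duplicate edges: {pairs[:5]}")
        df = df.sort_values(
            by=["weight", "source", "target"], ascending=[False, True, True]
        ).reset_index(drop=True)
        self.edges = df

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def genes(self) -> list[str]:
        return sorted(set(self.edges["source"]) | set(self.edges["target"]))

    def sorted_edges(self) -> pd.DataFrame:
        """Edges in descending weight, lexicographic tie-break (canonical order)."""
        return self.edges.copy()

    def weight_lookup(self) -> dict[tuple[str, str], float]:
        return {
            (s, t): w
            for s, t, w in zip(self.edges["source"], self.edges["target"], self.edges["weight"])
        }

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple],
        directed: bool,
        method_tag: str = "",
        ordering_mode: Optional[str] = None,
    ) -> "WeightedNetwork":
        """Build from (source, target, weight[, sign]) tuples."""
        rows = []
        for rec in records:
            if len(rec) == 3:
                s, t, w = rec
                sg = 0
            else:
                s, t, w, sg = rec
            rows.append({"source": s, "target": t, "weight": w, "sign": sg})
        df = pd.DataFrame(rows, columns=_EDGE_COLUMNS)
        return cls(df, directed=directed, method_tag=method_tag, ordering_mode=ordering_mode)
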