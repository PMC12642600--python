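"""Scoring inferred networks against a reference edge set.

The headline metric is the density-normalized area under the
precision–recall curve:

    AUPR_ratio = AUPR / rho,      rho = #true edges / #candidate edges.

Under random edge scoring the expected AUPR equals rho, so the ratio has
a convenient baseline of 1. The candidate set is the full set of ordered
(directed) or unordered (undirected) gene pairs over the reference's gene
universe, self-loops excluded; candidate pairs the prediction does not
score enter as one tie block at weight 0, so the area reflects the whole
candidate space.

Tie handling: a group of equal-weight candidates collapses to a single
operating point and precision is interpolated linearly in recall between
operating points (trapezoidal area). This makes the degenerate all-tied
prediction score exactly rho (ratio 1) and the perfect ranking score
exactly 1 (ratio 1/rho).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .containers import WeightedNetwork

logger = logging.getLogger(__name__)


@dataclass
class GroundTruth:
    """Reference network: gene universe plus a binary edge set.

    Undirected references store each pair sorted lexicographically.
    """

    gene_universe: list[str]
    true_edges: set[tuple[str, str]]
    directed: bool

    def __post_init__(self) -> None:
        self.gene_universe = [str(g) for g in self.gene_universe]
        if len(set(self.gene_universe)) != len(self.gene_universe):
            raise ValueError("duplicate genes in universe")
        uni = set(self.gene_universe)
        norm = set()
        for s, t in self.true_edges:
            s, t = str(s), str(t)
            if s == t:
                raise ValueError(f"self-loop in ground truth: {s}")
            if s not in uni or t not in uni:
                raise ValueError(f"edge ({s}, {t}) outside gene universe")
            norm.add((s, t) if self.directed else tuple(sorted((s, t))))
        self.true_edges = norm
        if not self.true_edges:
            raise ValueError("ground truth has no edges")

    @property
    def n_candidates(self) -> int:
        n = len(self.gene_universe)
        return n * (n - 1) if self.directed else n * (n - 1) // 2

    @property
    def rho(self) -> float:
        """Density: true edges over candidate edges."""
        return len(self.true_edges) / self.n_candidates

    def has_edge(self, source: str, target: str) -> bool:
        e = (source, target) if self.directed else tuple(sorted((source, target)))
        return e in self.true_edges


@dataclass
class PRResult:
    """Precision–recall summary for one prediction/reference pair."""

    recall: np.ndarray
    precision: np.ndarray
    aupr: float
    rho: float

    @property
    def aupr_ratio(self) -> float:
        return self.aupr / self.rho


def _candidate_scores(
    pred: WeightedNetwork, truth: GroundTruth
) -> tuple[list[tuple[str, str]], np.ndarray, np.ndarray]:
    """Align prediction weights with the full candidate edge set."""
    uni = truth.gene_universe
    uniset = set(uni)
    stray = [g for g in pred.genes if g not in uniset]
    if stray:
        raise ValueError(f"predicted genes outside the reference universe: {stray[:5]}")

    lut: dict[tuple[str, str], float] = {}
    if truth.directed and not pred.directed:
        logger.info("undirected prediction vs directed reference: scoring both orientations")
        for s, t, w in zip(pred.edges["source"], pred.edges["target"], pred.edges["weight"]):
            lut[(s, t)] = w
            lut[(t, s)] = w
    elif not truth.directed and pred.directed:
        logger.info("directed prediction vs undirected reference: symmetrizing by max weight")
        for s, t, w in zip(pred.edges["source"], pred.edges["target"], pred.edges["weight"]):
            key = tuple(sorted((s, t)))
            lut[key] = max(lut.get(key, 0.0), w)
    else:
        lut = pred.weight_lookup()

    if truth.directed:
        cands = [(a, b) for a in uni for b in uni if a != b]
    else:
        su = sorted(uni)
        cands = [(su[i], su[j]) for i in range(len(su)) for j in range(i + 1, len(su))]
    cands.sort()
    weights = np.array([lut.get(e, 0.0) for e in cands])
    labels = np.array([truth.has_edge(*e) for e in cands], dtype=bool)
    return cands, weights, labels


def aupr(pred: WeightedNetwork, truth: GroundTruth) -> PRResult:
    """Density-normalizable AUPR of a weighted prediction.

    Candidates are ranked by descending weight with lexicographic
    tie-breaking; equal-weight groups are scored as one block (see module
    docstring for the tie convention).
    """
    cands, weights, labels = _candidate_scores(pred, truth)
    # lexicographic order is already in place; stable sort by weight only
    order = np.argsort(-weights, kind="mergesort")
    w_sorted = weights[order]
    l_sorted = labels[order]

    n_true = int(labels.sum())
    # block boundaries where the weight strictly drops
    boundaries = np.flatnonzero(np.diff(w_sorted)) + 1
    block_ends = np.append(boundaries, w_sorted.shape[0]) - 1

    tp_cum = np.cumsum(l_sorted)
    n_cum = np.arange(1, w_sorted.shape[0] + 1)
    tp = tp_cum[block_ends]
    n = n_cum[block_ends]
    recall = tp / n_true
    precision = tp / n

    # anchor at recall 0 with the first block's precision
    R = np.concatenate([[0.0], recall])
    P = np.concatenate([[precision[0]], precision])
    area = float(np.trapezoid(P, R))
    return PRResult(recall=R, precision=P, aupr=area, rho=truth.rho)


def top_edges(pred: WeightedNetwork, gene: str, k: int = 10) -> pd.DataFrame:
    """The k heaviest edges incident to ``gene`` (either endpoint).

    Descending weight with deterministic lexicographic tie-breaking; if
    fewer than k edges touch the gene, all of them are returned.
    """
    df = pred.sorted_edges()
    if gene not in set(df["source"]) | set(df["target"]):
        raise KeyError(f"gene {gene!r} has no edges in this network")
    hit = (df["source"] == gene) | (df["target"] == gene)
    return df[hit].head(k).reset_index(drop=True)


def edge_support(
    edges: pd.DataFrame | Iterable[tuple[str, str]], reference: GroundTruth
) -> tuple[float, pd.DataFrame]:
    """Fraction of edges present in the reference, plus per-edge flags.

    Orientation-insensitive when the reference is undirected. Returns
    (supported fraction, table with a boolean ``supported`` column).
    """
    if isinstance(edges, pd.DataFrame):
        pairs = list(zip(edges["source"], edges["target"]))
    else:
        pairs = [(s, t) for s, t in edges]
    flags = [
        all(g in set(reference.gene_universe) for g in e) and reference.has_edge(*e)
        for e in pairs
    ]
    table = pd.DataFrame(
        {"source": [e[0] for e in pairs], "target": [e[1] for e in pairs], "supported": flags}
    )
    frac = float(np.mean(flags)) if flags else 0.0
    return frac, table


def centralities(pred: WeightedNetwork) -> pd.DataFrame:
    """Hub-gene table: in-strength, closeness and betweenness per gene.

    In-strength is the sum of incoming edge weights (all incident weights
    for undirected networks) — the primary hub ranking. Closeness and
    betweenness are computed on the graph with edge length 1/weight
    (zero-weight edges excluded); unreachable genes get closeness 0 under
    the standard reachable-set convention.
    """
    df = pred.sorted_edges()
    if df.empty:
        raise ValueError("cannot compute centralities of an empty network")
    G: nx.Graph = nx.DiGraph() if pred.directed else nx.Graph()
    for s, t, w in zip(df["source"], df["target"], df["weight"]):
        if w > 0:
            G.add_edge(s, t, weight=w, length=1.0 / w)

    if pred.directed:
        strength = dict(G.in_degree(weight="weight"))
        for g in G.nodes:
            strength.setdefault(g, 0.0)
    else:
        strength = dict(G.degree(weight="weight"))
    closeness = nx.closeness_centrality(G, distance="length")
    betweenness = nx.betweenness_centrality(G, weight="length", normalized=True)
    out = pd.DataFrame(
        {
            "gene": list(G.nodes),
            "in_strength": [strength.get(g, 0.0) for g in G.nodes],
            "closeness": [closeness.get(g, 0.0) for g in G.nodes],
            "betweenness": [betweenness.get(g, 0.0) for g in G.nodes],
        }
    )
    return out.sort_values(
        by=["in_strength", "gene"], ascending=[False, True]
    ).reset_index(drop=True)


def random_baseline_aupr_ratio(
    n_genes: int = 100,
    density: float = 0.03,
    n_reps: int = 100,
    directed: bool = True,
    seed: int = 0,
) -> float:
    """Mean AUPR ratio of uniform-random edge scores against a fixed
    random ground truth — the calibration check that the ratio baselines
    at 1 under uninformative scoring."""
    rng = np.random.default_rng(int(seed))
    genes = [f"G{i:03d}" for i in range(n_genes)]
    if directed:
        cands = [(a, b) for a in genes for b in genes if a != b]
    else:
        cands = [(genes[i], genes[j]) for i in range(n_genes) for j in range(i + 1, n_genes)]
    n_true = round(density * len(cands))
    idx = rng.choice(len(cands), size=n_true, replace=False)
    truth = GroundTruth(
        gene_universe=genes,
        true_edges={cands[i] for i in idx},
        directed=directed,
    )
    ratios = []
    for _ in range(n_reps):
        w = rng.uniform(size=len(cands))
        pred = WeightedNetwork.from_records(
            [(s, t, float(wi)) for (s, t), wi in zip(cands, w)],
            directed=directed,
            method_tag="random",
        )
        ratios.append(aupr(pred, truth).aupr_ratio)
    return float(np.mean(ratios))
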