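"""Network inference: mutual-information pruning, tree-ensemble
importances, and binned Granger causality on distributional distances.

Three method families cover the static/temporal and directed/undirected
design space:

* :func:`aracne_infer` — static, undirected, unsigned. All-pairs mutual
  information followed by data-processing-inequality (DPI) pruning: in a
  Markov chain X -> Y -> Z, MI(X,Z) <= min(MI(X,Y), MI(Y,Z)), so the
  weakest edge of a fully connected triplet is presumed indirect and
  removed.
* :func:`genie3_infer` — static, directed, unsigned. Each gene is
  regressed on all other genes with a randomized tree ensemble; the edge
  weight regulator -> target is the regulator's total variance-reduction
  importance.
* :func:`sincerities_infer` — temporal, directed, signed. Stage 1
  computes, per gene, the Kolmogorov–Smirnov distance between its
  expression distributions in consecutive temporal bins; stage 2 fits a
  one-step-lagged ridge regression of each target's distributional
  changes on all genes' changes (Granger structure), with the penalty
  chosen per target by leave-one-out cross-validation; stage 3 signs each
  edge by the partial Spearman correlation between regulator and target
  across cells.

All methods consume the log-normalized layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import ExtraTreesRegressor

from .containers import CellClock, ExpressionMatrix, LAYER_LOGNORM, WeightedNetwork

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# mutual information
# ---------------------------------------------------------------------------

def default_mi_bins(n_samples: int) -> int:
    """Default marginal bin count: floor(sqrt(n/5)) clipped to [4, 16]."""
    return int(np.clip(np.floor(np.sqrt(n_samples / 5)), 4, 16))


def mutual_information_from_counts(table: np.ndarray) -> float:
    """Plug-in mutual information (nats) of a joint count table.

    MI = sum_ij p_ij * log(p_ij / (p_i. * p_.j)) over non-empty cells.
    """
    table = np.asarray(table, dtype=float)
    total = table.sum()
    if total <= 0:
        raise ValueError("joint count table is empty")
    p = table / total
    pi = p.sum(axis=1, keepdims=True)
    pj = p.sum(axis=0, keepdims=True)
    mask = p > 0
    mi = float(np.sum(p[mask] * (np.log(p[mask]) - np.log((pi @ pj)[mask]))))
    return max(mi, 0.0)


def _equal_frequency_labels(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Rank-based equal-frequency bin labels in 0..n_bins-1."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(x.shape[0])
    return (ranks * n_bins) // x.shape[0]


def mutual_information(
    x: np.ndarray, y: np.ndarray, n_mi_bins: Optional[int] = None
) -> float:
    """Plug-in mutual information (nats) between two sample vectors.

    Marginals are discretized into equal-frequency bins (robust to the
    skewed marginals of log counts); MI is the plug-in estimate from the
    joint histogram. Symmetric in (x, y) and non-negative.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape[0] != y.shape[0]:
        raise ValueError("sample vectors must have equal length")
    if n_mi_bins is None:
        n_mi_bins = default_mi_bins(x.shape[0])
    if x.shape[0] < 2 * n_mi_bins:
        raise ValueError(
            f"need >= {2 * n_mi_bins} samples for {n_mi_bins} marginal bins"
        )
    bx = _equal_frequency_labels(x, n_mi_bins)
    by = _equal_frequency_labels(y, n_mi_bins)
    table = np.zeros((n_mi_bins, n_mi_bins))
    np.add.at(table, (bx, by), 1.0)
    return mutual_information_from_counts(table)


def aracne_infer(
    expr: ExpressionMatrix,
    dpi_tolerance: float = 0.0,
    n_mi_bins: Optional[int] = None,
) -> WeightedNetwork:
    """All-pairs MI network with DPI triplet pruning (undirected, unsigned).

    For every gene triplet whose three edges all survive, the edge with
    ``MI < (1 - dpi_tolerance) * min(other two MIs)`` is marked indirect;
    marked edges are removed in one sweep after scanning all triplets.
    Tolerance 0 is strict pruning; tolerance 1 disables pruning.
    """
    if expr.layer != LAYER_LOGNORM:
        raise ValueError("aracne_infer expects the log-normalized layer")
    if not (0.0 <= dpi_tolerance <= 1.0):
        raise ValueError("dpi_tolerance must lie in [0, 1]")
    genes = expr.genes
    if len(genes) < 2:
        raise ValueError("need >= 2 genes")
    X = expr.values.to_numpy()
    mi = {}
    for i, j in combinations(range(len(genes)), 2):
        mi[(i, j)] = mutual_information(X[i], X[j], n_mi_bins)

    doomed: set[tuple[int, int]] = set()
    if len(genes) >= 3:
        for i, j, k in combinations(range(len(genes)), 3):
            trip = [(i, j), (i, k), (j, k)]
            vals = [mi[e] for e in trip]
            lo = int(np.argmin(vals))
            others = [vals[m] for m in range(3) if m != lo]
            if vals[lo] < (1.0 - dpi_tolerance) * min(others):
                doomed.add(trip[lo])

    records = [
        (genes[i], genes[j], w)
        for (i, j), w in mi.items()
        if (i, j) not in doomed and w > 0
    ]
    logger.info(
        "aracne: %d/%d edges survive DPI (tolerance=%g)",
        len(records), len(mi), dpi_tolerance,
    )
    return WeightedNetwork.from_records(records, directed=False, method_tag="aracne")


# ---------------------------------------------------------------------------
# tree-ensemble importances
# ---------------------------------------------------------------------------

def genie3_infer(
    expr: ExpressionMatrix,
    regulators: Optional[Sequence[str]] = None,
    n_trees: int = 100,
    feature_subset_size: str | int | float = "sqrt",
    seed: int = 0,
) -> WeightedNetwork:
    """Tree-ensemble regulator importances (directed, unsigned).

    For each target gene an ensemble of randomized regression trees
    predicts the target from the candidate regulators (all other genes by
    default), each gene standardized to unit variance first. The weight
    of regulator -> target is the regulator's importance averaged over
    trees, measured as total variance reduction, so per-target importances
    sum to the ensemble's overall variance reduction.
    """
    if expr.layer != LAYER_LOGNORM:
        raise ValueError("genie3_infer expects the log-normalized layer")
    genes = expr.genes
    if len(genes) < 3:
        raise ValueError("need >= 3 genes")
    if expr.n_cells < 10:
        raise ValueError("need >= 10 cells")
    reg_list = list(regulators) if regulators is not None else genes
    missing = [g for g in reg_list if g not in genes]
    if missing:
        raise KeyError(f"regulators not in matrix: {missing}")

    # canonical cell order so importances are invariant to column order
    X = expr.values.iloc[:, np.argsort(expr.cells, kind="mergesort")].to_numpy().astype(float)
    sd = X.std(axis=1)
    keep_scale = np.where(sd > 0, sd, 1.0)
    Xs = (X - X.mean(axis=1, keepdims=True)) / keep_scale[:, None]

    gene_idx = {g: i for i, g in enumerate(genes)}
    records = []
    rng = np.random.default_rng(int(seed))
    for target in genes:
        t_i = gene_idx[target]
        if sd[t_i] == 0:
            logger.warning("genie3: target %s has zero variance; skipped", target)
            continue
        preds = [g for g in reg_list if g != target]
        if not preds:
            continue
        P = Xs[[gene_idx[g] for g in preds]].T  # cells x predictors
        y = Xs[t_i]
        est = ExtraTreesRegressor(
            n_estimators=n_trees,
            max_features=feature_subset_size,
            random_state=int(rng.integers(0, 2**31 - 1)),
            n_jobs=1,
        )
        est.fit(P, y)
        # unnormalized importance: mean over trees of the summed
        # impurity (variance) decrease attributed to each feature
        imp = np.mean(
            [t.tree_.compute_feature_importances(normalize=False) for t in est.estimators_],
            axis=0,
        )
        for g, w in zip(preds, imp):
            if w > 0:
                records.append((g, target, float(w)))
    return WeightedNetwork.from_records(records, directed=True, method_tag="genie3")


def genie3_total_variance_reduction(est: ExtraTreesRegressor) -> float:
    """Mean over trees of (root impurity - weighted leaf impurity).

    Equals the sum of unnormalized feature importances of the same trees;
    exposed for the accounting check of importance bookkeeping.
    """
    totals = []
    for t in est.estimators_:
        tree = t.tree_
        w = tree.weighted_n_node_samples / tree.weighted_n_node_samples[0]
        leaves = tree.children_left == -1
        totals.append(tree.impurity[0] - np.sum(w[leaves] * tree.impurity[leaves]))
    return float(np.mean(totals))


# ---------------------------------------------------------------------------
# KS / Granger
# ---------------------------------------------------------------------------

def ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample Kolmogorov–Smirnov statistic: sup |ECDF_a - ECDF_b|."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("ks_statistic requires non-empty samples")
    return float(stats.ks_2samp(a, b, method="asymp").statistic)


@dataclass
class DDMatrix:
    """Distributional-distance matrix.

    ``values[b, g]`` is the KS statistic between gene g's expression in
    temporal bin b and bin b+1, for b = 0..B-2. ``deltas[b]`` is the width
    of the step from bin b to b+1 in the active ordering's coordinate
    (1 for quantile orderings, hours for real time).
    """

    values: np.ndarray  # (B-1) x genes, in [0, 1]
    genes: list[str]
    bin_sizes: np.ndarray  # length B
    deltas: np.ndarray  # length B-1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("KS statistics must lie in [0, 1]")
        self.bin_sizes = np.asarray(self.bin_sizes, dtype=int)
        self.deltas = np.asarray(self.deltas, dtype=float)
        if self.values.shape[0] != self.bin_sizes.shape[0] - 1:
            raise ValueError("row count must be n_bins - 1")
        if self.deltas.shape[0] != self.values.shape[0]:
            raise ValueError("deltas length must be n_bins - 1")

    @property
    def n_bins(self) -> int:
        return self.bin_sizes.shape[0]


def distributional_distance_matrix(
    expr: ExpressionMatrix, clock: CellClock
) -> DDMatrix:
    """Per-gene KS distance between consecutive temporal bins.

    Requires ``clock.bin_index`` filled with every bin non-empty and at
    least 3 bins. For the real-time ordering the step widths are the hour
    gaps between consecutive time points; quantile orderings use unit
    steps.
    """
    if clock.bin_index is None:
        raise ValueError("clock has no bin_index; run make_ordering first")
    if clock.n_cells != expr.n_cells:
        raise ValueError("clock and expression matrix disagree on cell count")
    bins = clock.bin_index
    n_bins = int(bins.max()) + 1
    if n_bins < 3:
        raise ValueError("need >= 3 temporal bins")
    sizes = np.bincount(bins, minlength=n_bins)
    empty = np.where(sizes == 0)[0]
    if empty.size:
        raise ValueError(f"empty temporal bin(s): {empty.tolist()}")

    X = expr.values.to_numpy()
    by_bin = [np.where(bins == b)[0] for b in range(n_bins)]
    dd = np.zeros((n_bins - 1, expr.n_genes))
    for b in range(n_bins - 1):
        A, B = X[:, by_bin[b]], X[:, by_bin[b + 1]]
        for g in range(expr.n_genes):
            if np.ptp(A[g]) == 0 and np.ptp(B[g]) == 0 and A[g, 0] == B[g, 0]:
                continue  # constant gene across both bins -> distance 0
            dd[b, g] = ks_statistic(A[g], B[g])

    if clock.ordering_mode == "real":
        uniq = np.unique(clock.real_time)
        deltas = np.diff(uniq)
    else:
        deltas = np.ones(n_bins - 1)
    return DDMatrix(values=dd, genes=expr.genes, bin_sizes=sizes, deltas=deltas)


def _loo_ridge_cv(X: np.ndarray, y: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Ridge coefficients at the penalty minimizing closed-form LOO error.

    X and y are centered by the caller. Uses the hat-matrix identity
    e_loo_i = e_i / (1 - h_ii) per penalty value.
    """
    n, p = X.shape
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    Uy = U.T @ y
    best = (np.inf, None)
    for lam in grid:
        d = s / (s**2 + lam)
        coef = Vt.T @ (d * Uy)
        h = np.einsum("ij,j,ij->i", U, s * d, U)
        resid = y - X @ coef
        denom = np.clip(1.0 - h, 1e-12, None)
        press = float(np.mean((resid / denom) ** 2))
        if press < best[0] - 1e-15:
            best = (press, coef)
    return best[1]


def partial_spearman_signs(expr: ExpressionMatrix, ridge_frac: float = 1e-6) -> np.ndarray:
    """Sign matrix of partial Spearman correlations between all gene pairs.

    Expression is rank-transformed and Gaussianized, then partial
    correlations are read off the precision matrix (with a small diagonal
    ridge for stability). Falls back to pairwise Spearman signs if the
    correlation matrix is not invertible.
    """
    X = expr.values.to_numpy()
    n_genes, n_cells = X.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, X)
    gauss = stats.norm.ppf(ranks / (n_cells + 1))
    sd = gauss.std(axis=1)
    ok = sd > 0
    Z = gauss.copy()
    Z[~ok] = 0.0
    Z[ok] = (Z[ok] - Z[ok].mean(axis=1, keepdims=True)) / sd[ok][:, None]
    C = (Z @ Z.T) / n_cells
    C[~ok, :] = 0.0
    C[:, ~ok] = 0.0
    np.fill_diagonal(C, 1.0)
    C_r = C + np.eye(n_genes) * (ridge_frac * np.trace(C) / n_genes)
    try:
        P = np.linalg.inv(C_r)
        with np.errstate(invalid="ignore"):
            pc = -P / np.sqrt(np.outer(np.diag(P), np.diag(P)))
    except np.linalg.LinAlgError:
        logger.warning("partial correlation singular; falling back to pairwise Spearman")
        pc = C
    signs = np.sign(pc)
    signs[~ok, :] = 0
    signs[:, ~ok] = 0
    np.fill_diagonal(signs, 0)
    return signs.astype(int)


DEFAULT_RIDGE_GRID = tuple(np.logspace(-3, 2, 10))


def sincerities_infer(
    expr: ExpressionMatrix,
    clock: CellClock,
    ridge_grid: Sequence[float] = DEFAULT_RIDGE_GRID,
) -> WeightedNetwork:
    """Granger-style regression on distributional distances (directed, signed).

    Stage 1 builds the distributional-distance matrix (KS statistic
    between consecutive bins, normalized by the step width). Stage 2, for
    each target j, regresses DD[1..B-2, j] on DD[0..B-3, all genes] — a
    one-bin time lag — with an L2 penalty chosen per target by
    leave-one-out cross-validation over ``ridge_grid``; the weight of
    g -> j is |coefficient of g|. Stage 3 signs each edge by the partial
    Spearman correlation between g and j across all cells.

    Requires at least 5 temporal bins so the lagged regression has at
    least 3 observations.
    """
    if len(ridge_grid) == 0:
        raise ValueError("ridge_grid must be non-empty")
    dd = distributional_distance_matrix(expr, clock)
    if dd.n_bins < 5:
        raise ValueError(
            f"insufficient temporal bins: {dd.n_bins} < 5 required for the "
            "lagged regression"
        )
    V = dd.values / dd.deltas[:, None]  # rate of distributional change
    Xlag, Y = V[:-1], V[1:]
    Xc = Xlag - Xlag.mean(axis=0, keepdims=True)
    # standardize predictors (glmnet-style) so the penalty and the
    # resulting importances are comparable across genes; coefficients are
    # kept on the per-SD scale for ranking
    xsd = Xc.std(axis=0)
    Xs = Xc / np.where(xsd > 0, xsd, 1.0)
    grid = np.asarray(sorted(ridge_grid), dtype=float)

    genes = dd.genes
    coefs = np.zeros((len(genes), len(genes)))  # [source, target]
    for j in range(len(genes)):
        y = Y[:, j]
        yc = y - y.mean()
        if np.allclose(Xs, 0) or np.allclose(yc, 0):
            continue
        coefs[:, j] = _loo_ridge_cv(Xs, yc, grid)
    coefs[xsd == 0, :] = 0.0  # constant predictors carry no signal

    signs = partial_spearman_signs(expr)
    records = []
    for si, s in enumerate(genes):
        for ti, t in enumerate(genes):
            if si == ti:
                continue
            w = abs(coefs[si, ti])
            if w > 0:
                records.append((s, t, float(w), int(signs[si, ti])))
    return WeightedNetwork.from_records(
        records,
        directed=True,
        method_tag="sincerities",
        ordering_mode=clock.ordering_mode,
    )
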