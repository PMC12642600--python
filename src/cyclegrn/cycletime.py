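"""Cell-cycle position estimation and the three time orderings.

Temporal network inference needs an ordinal coordinate per cell. Three
orderings are supported:

* ``real`` — the raw experimental time points; bins are the distinct
  hours in order.
* ``tricycle`` — a circular cell-cycle position theta in [0, 2*pi)
  estimated from a user-supplied cycle-gene list, discretized into
  quantile bins.
* ``theta`` — the integrated-theta hybrid coordinate placing consecutive
  experimental time points 2*pi apart with within-point ordering given by
  theta, discretized into quantile bins.

The phase estimator is reference-free: cells are projected onto the top
two principal axes of the centered, gene-standardized cycle-gene
submatrix and theta is the polar angle of the scores. A cycling population traces an ellipse in this
plane, so the angle recovers the cycle position up to a global rotation
and possible reflection — an ambiguity that is irrelevant downstream
because only the ordering within bins is used.
"""

from __future__ import annotations

import numpy as np

from .containers import TWO_PI, CellClock, ExpressionMatrix, LAYER_LOGNORM


def estimate_cycle_position(
    expr: ExpressionMatrix, cycle_genes: list[str]
) -> CellClock:
    """Assign each cell a cycle phase theta in [0, 2*pi).

    Restricts to the cycle-gene submatrix (>= 3 genes required), centers
    and unit-variance scales each gene, projects cells onto the top two
    principal axes, and sets
    ``theta = atan2(PC2 score, PC1 score)`` mapped into [0, 2*pi). Each
    principal axis is oriented so its largest-magnitude gene loading is
    positive, which makes the result deterministic.

    Returns a :class:`CellClock` with ``theta`` filled (``real_time`` is
    NaN; merge with experiment metadata via :func:`attach_real_time` or
    construct the clock directly when times are known).
    """
    if expr.layer != LAYER_LOGNORM:
        raise ValueError("estimate_cycle_position expects the log-normalized layer")
    present = [g for g in cycle_genes if g in expr.values.index]
    missing = [g for g in cycle_genes if g not in expr.values.index]
    if len(present) < 3:
        raise ValueError(
            f"need >= 3 cycle genes in the matrix, found {len(present)}; "
            f"missing: {missing}"
        )
    X = expr.values.loc[present].to_numpy().T  # cells x cycle genes
    X = X - X.mean(axis=0, keepdims=True)
    if np.allclose(X, 0):
        raise ValueError("cycle-gene submatrix has zero variance")
    # scale each gene to unit variance so every cycle gene contributes
    # equally to the manifold regardless of its expression magnitude
    sd = X.std(axis=0)
    X = X / np.where(sd > 0, sd, 1.0)
    # principal axes of the cell cloud in cycle-gene space
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    axes = vt[:2]
    for k in range(2):
        # orient each axis so its largest-magnitude loading is positive;
        # near-ties resolved to the lowest gene index so the convention is
        # stable under floating-point jitter
        mags = np.abs(axes[k])
        j = int(np.flatnonzero(mags >= mags.max() - 1e-9)[0])
        if axes[k, j] < 0:
            axes[k] = -axes[k]
    scores = X @ axes.T  # cells x 2
    theta = np.mod(np.arctan2(scores[:, 1], scores[:, 0]), TWO_PI)
    # guard against the half-open-interval edge at exactly 2*pi
    theta[theta >= TWO_PI] = 0.0
    return CellClock(
        cell_ids=np.array(expr.cells, dtype=object),
        real_time=np.full(expr.n_cells, np.nan),
        theta=theta,
    )


def attach_real_time(clock: CellClock, times: dict[str, float] | np.ndarray) -> CellClock:
    """Fill ``real_time`` from a cell_id -> hours mapping or aligned array."""
    if isinstance(times, dict):
        missing = [c for c in clock.cell_ids if c not in times]
        if missing:
            raise KeyError(f"no time recorded for cells: {missing[:10]}")
        rt = np.array([times[c] for c in clock.cell_ids], dtype=float)
    else:
        rt = np.asarray(times, dtype=float)
        if rt.shape[0] != clock.n_cells:
            raise ValueError("time vector length does not match clock")
    return clock.with_(real_time=rt)


def integrate_theta(clock: CellClock, theta_weight: float = 1.0) -> CellClock:
    """Build the integrated-theta coordinate.

    With k(i) the 0-based rank of cell i's real time among the sorted
    distinct time points, ``integrated_theta(i) = 2*pi*k(i) +
    theta_weight * theta(i)``. With the default weight of 1 each time
    point's interior spans exactly one cycle [0, 2*pi), so two cells with
    equal theta at consecutive time points differ by exactly 2*pi.
    """
    if clock.theta is None:
        raise ValueError("theta missing: estimate cycle positions first")
    if np.any(~np.isfinite(clock.real_time)):
        raise ValueError("real_time missing for some cells")
    if not (0 < theta_weight <= 1.0):
        raise ValueError("theta_weight must lie in (0, 1]")
    uniq = np.unique(clock.real_time)
    rank = np.searchsorted(uniq, clock.real_time)
    integrated = TWO_PI * rank + theta_weight * clock.theta
    return clock.with_(integrated_theta=integrated)


def quantile_bin(values: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Discretize into ``n_bins`` equal-frequency bins labeled 0..n_bins-1.

    Bin edges are the i/n_bins quantiles; labels are non-decreasing in
    value and ties fall in the lower bin. Requires at least ``n_bins``
    distinct values.
    """
    values = np.asarray(values, dtype=float)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    n_distinct = np.unique(values).size
    if n_distinct < n_bins:
        raise ValueError(
            f"cannot form {n_bins} quantile bins from {n_distinct} distinct values"
        )
    edges = np.quantile(values, np.arange(1, n_bins) / n_bins)
    labels = np.searchsorted(edges, values, side="left")
    return labels.astype(int)


def make_ordering(clock: CellClock, mode: str, n_bins: int = 10) -> CellClock:
    """Fill ``bin_index`` and ``ordering_mode`` for the requested ordering.

    ``real`` bins are the distinct experimental time points in order (no
    quantile binning); ``tricycle`` and ``theta`` apply
    :func:`quantile_bin` to theta and integrated theta respectively.
    """
    if mode == "real":
        if np.any(~np.isfinite(clock.real_time)):
            raise ValueError("real_time missing for some cells")
        uniq = np.unique(clock.real_time)
        bins = np.searchsorted(uniq, clock.real_time).astype(int)
    elif mode == "tricycle":
        if clock.theta is None:
            raise ValueError("theta missing: estimate cycle positions first")
        bins = quantile_bin(clock.theta, n_bins)
    elif mode == "theta":
        if clock.integrated_theta is None:
            raise ValueError("integrated_theta missing: run integrate_theta first")
        bins = quantile_bin(clock.integrated_theta, n_bins)
    else:
        raise ValueError(f"unknown ordering mode {mode!r}")
    return clock.with_(bin_index=bins, ordering_mode=mode)


def circular_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Fisher–Lee circular correlation between two angle vectors.

    Invariant under rotation of either variable; changes sign under
    reflection. Used to assess phase recovery against a known theta.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("angle vectors must have equal length")
    abar = np.angle(np.mean(np.exp(1j * a)))
    bbar = np.angle(np.mean(np.exp(1j * b)))
    sa = np.sin(a - abar)
    sb = np.sin(b - bbar)
    denom = np.sqrt(np.sum(sa**2) * np.sum(sb**2))
    if denom == 0:
        return 0.0
    return float(np.sum(sa * sb) / denom)
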