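"""Synthetic single-cell snapshot data from a known oscillatory network.

The generator emulates the statistical structure of a developmental
scRNA-seq time course: cells are destructively sampled at a small set of
discrete experimental times (hours), each cell carries a latent cell-cycle
phase theta in [0, 2*pi), a subset of "driver" genes oscillates in theta,
and downstream target genes respond to their regulators with phase lags.
Counts are negative-binomial (overdispersed) around an exponentiated
log-mean.

Model
-----
For cell i with phase theta_i and experimental time t_i:

* driver g:   lambda_g(i) = baseline + A_g * cos(theta_i - phi_g)
* target j:   lambda_j(i) = baseline
                + sum_g W_jg * cos(theta_i - phi_g^eff - delta_jg)
                + gamma_j * (t_i - t_min)

where phi_g^eff is the effective oscillation phase of regulator g (its
sampled phase if g is a driver, otherwise the weight-averaged circular
phase it inherited from its own regulators), W_jg is the signed regulatory
weight, delta_jg the response lag, and gamma_j a slow linear drift in real
time. Counts ~ NegBin(mean=exp(lambda), size=r).

The planted network is acyclic apart from the implicit theta-cycle driving
all drivers: edges run only from earlier to later genes in a fixed
topological order with drivers first, and every edge source is a driver or
a gene that itself received edges earlier in that order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .containers import TWO_PI, CellClock, ExpressionMatrix, LAYER_COUNTS, LAYER_LOGNORM

#: the experimental sampling schedule (hours) emulated by default
DEFAULT_TIME_POINTS = (11.0, 12.0, 14.0, 16.0, 18.0, 20.0, 22.0, 25.0, 28.0)

#: geometric decay ratio for time-point sampling weights (earliest heaviest)
TIME_WEIGHT_DECAY = 0.7


@dataclass
class SimConfig:
    """Configuration of the synthetic-data generator.

    Defaults define the reference simulation regime: 500 cells over the
    9-point hour schedule, 50 genes of which 30 are cycle drivers with
    oscillation amplitude 2, planted edge density 0.05, negative-binomial
    dispersion (size) 10.
    """

    n_cells: int = 500
    n_genes: int = 50
    n_cycle_drivers: int = 30
    edge_density: float = 0.05
    time_points: tuple[float, ...] = DEFAULT_TIME_POINTS
    amplitude_range: tuple[float, float] = (2.0, 2.0)
    phase_lag_range: tuple[float, float] = (0.1 * math.pi, 0.3 * math.pi)
    weight_range: tuple[float, float] = (0.5, 1.5)
    trend_scale: float = 0.02
    dispersion: float = 10.0
    baseline_log_mean: float = 1.5
    time_weights: Optional[tuple[float, ...]] = None
    noise: str = "nb"  # "nb" or "gaussian" (debugging aid)
    couple_cycle_speed: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0 or self.n_genes <= 0:
            raise ValueError("n_cells and n_genes must be positive")
        if not (0 < self.n_cycle_drivers <= self.n_genes):
            raise ValueError("n_cycle_drivers must be in (0, n_genes]")
        if not (0 < self.edge_density < 1):
            raise ValueError("edge_density must lie in (0, 1)")
        tp = tuple(float(t) for t in self.time_points)
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("time_points must be strictly increasing")
        self.time_points = tp
        lo, hi = self.amplitude_range
        if lo < 0 or hi < lo:
            raise ValueError("amplitude_range must satisfy 0 <= lo <= hi")
        lo, hi = self.phase_lag_range
        if not (0 < lo <= hi < math.pi):
            raise ValueError("phase_lag_range must lie within (0, pi)")
        if self.trend_scale < 0:
            raise ValueError("trend_scale must be >= 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.noise not in ("nb", "gaussian"):
            raise ValueError("noise must be 'nb' or 'gaussian'")
        if self.time_weights is not None and len(self.time_weights) != len(tp):
            raise ValueError("time_weights length must match time_points")

    @property
    def n_planted_edges(self) -> int:
        """Planted directed edge count: round-half-even of density * n(n-1)."""
        return round(self.edge_density * self.n_genes * (self.n_genes - 1))

    def gene_names(self) -> list[str]:
        width = len(str(self.n_genes - 1))
        return [f"G{i:0{width}d}" for i in range(self.n_genes)]

    def sampling_weights(self) -> np.ndarray:
        if self.time_weights is not None:
            w = np.asarray(self.time_weights, dtype=float)
        else:
            w = TIME_WEIGHT_DECAY ** np.arange(len(self.time_points))
        return w / w.sum()


@dataclass
class SimTruth:
    """The planted network and all latent simulation parameters.

    ``true_theta`` (filled by :func:`simulate_expression`) is reserved for
    evaluation; inference never sees it.
    """

    genes: list[str]
    cycle_gene_list: list[str]
    edges: list[tuple[str, str]]
    weights: dict[tuple[str, str], float]
    response_lags: dict[tuple[str, str], float]
    driver_phases: dict[str, float]
    effective_phases: dict[str, float]
    amplitudes: dict[str, float]
    trend_coeffs: dict[str, float]
    true_theta: Optional[np.ndarray] = None

    @property
    def adjacency(self) -> set[tuple[str, str]]:
        return set(self.edges)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def generate_random_truth(cfg: SimConfig) -> SimTruth:
    """Plant a random directed regulatory network consistent with ``cfg``.

    Exactly ``round(edge_density * n_genes * (n_genes - 1))`` directed
    edges (round-half-even), no self-loops. Drivers (the first
    ``n_cycle_drivers`` genes) receive phases phi_g ~ Uniform[0, 2*pi);
    every edge runs from an earlier to a later gene in the fixed
    driver-first topological order, so the graph is acyclic apart from
    the implicit theta-cycle driving all drivers. Deterministic given
    ``cfg.seed``.
    """
    n_edges = cfg.n_planted_edges
    if n_edges == 0:
        raise ValueError("empty truth network: edge_density rounds to 0 edges")
    genes = cfg.gene_names()
    drivers = genes[: cfg.n_cycle_drivers]
    targets = genes[cfg.n_cycle_drivers :]

    # candidate edges run from earlier to later genes in the fixed
    # topological order (drivers first), so every source is a driver or a
    # previously generated gene and the graph stays acyclic
    candidates = [
        (genes[i], genes[j]) for j in range(1, cfg.n_genes) for i in range(j)
    ]
    if n_edges > len(candidates):
        raise ValueError(
            f"cannot plant {n_edges} edges: only {len(candidates)} "
            "topologically ordered pairs exist; lower edge_density"
        )
    rng = np.random.default_rng([int(cfg.seed), 0])
    idx = rng.choice(len(candidates), size=n_edges, replace=False)
    edges = sorted(candidates[i] for i in sorted(idx))

    phases = {g: float(p) for g, p in zip(drivers, rng.uniform(0, TWO_PI, len(drivers)))}
    amplitudes = {
        g: float(a)
        for g, a in zip(drivers, rng.uniform(*cfg.amplitude_range, len(drivers)))
    }
    weights = {}
    lags = {}
    for e in edges:
        mag = float(rng.uniform(*cfg.weight_range))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        weights[e] = sign * mag
        lags[e] = float(rng.uniform(*cfg.phase_lag_range))
    trend = {
        g: float(t)
        for g, t in zip(targets, rng.normal(0.0, cfg.trend_scale, len(targets)))
    }

    # effective phase: drivers carry their own; targets inherit the
    # |W|-weighted circular mean of (source effective phase + lag), in
    # topological order so every source is already resolved.
    eff: dict[str, float] = dict(phases)
    incoming: dict[str, list[tuple[str, str]]] = {}
    for e in edges:
        incoming.setdefault(e[1], []).append(e)
    for j in targets:
        ins = incoming.get(j, [])
        resolved = [e for e in ins if e[0] in eff]
        if resolved:
            w = np.array([abs(weights[e]) for e in resolved])
            ang = np.array([eff[e[0]] + lags[e] for e in resolved])
            eff[j] = float(np.angle(np.sum(w * np.exp(1j * ang)))) % TWO_PI

    return SimTruth(
        genes=genes,
        cycle_gene_list=list(drivers),
        edges=edges,
        weights=weights,
        response_lags=lags,
        driver_phases=phases,
        effective_phases=eff,
        amplitudes=amplitudes,
        trend_coeffs=trend,
    )


def _log_means(truth: SimTruth, cfg: SimConfig, theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Genes x cells matrix of log-means lambda."""
    n_genes, n_cells = len(truth.genes), theta.shape[0]
    lam = np.full((n_genes, n_cells), cfg.baseline_log_mean, dtype=float)
    gene_index = {g: i for i, g in enumerate(truth.genes)}
    t_min = min(cfg.time_points)
    for g in truth.cycle_gene_list:
        i = gene_index[g]
        lam[i] += truth.amplitudes[g] * np.cos(theta - truth.driver_phases[g])
    for (src, tgt), w in truth.weights.items():
        j = gene_index[tgt]
        phi = truth.effective_phases.get(src)
        if phi is None:
            continue  # source never oscillates; contributes no cyclic term
        lam[j] += w * np.cos(theta - phi - truth.response_lags[(src, tgt)])
    for g, gamma in truth.trend_coeffs.items():
        lam[gene_index[g]] += gamma * (t - t_min)
    if not np.all(np.isfinite(lam)):
        bad = np.where(~np.all(np.isfinite(lam), axis=1))[0]
        names = [truth.genes[i] for i in bad[:5]]
        raise ValueError(f"non-finite log-mean for genes {names}")
    return lam


def simulate_expression(truth: SimTruth, cfg: SimConfig) -> tuple[ExpressionMatrix, CellClock]:
    """Draw snapshot count data from the planted model.

    Each cell receives an experimental time sampled from
    ``cfg.time_points`` (geometrically decaying weights, earliest point
    heaviest, unless ``cfg.time_weights`` overrides) and a latent phase
    theta ~ Uniform[0, 2*pi), independent of time by default. Counts are
    negative-binomial with mean exp(lambda) and size ``cfg.dispersion``.

    The true theta is recorded on ``truth.true_theta`` for evaluation; the
    returned :class:`CellClock` carries real time only.
    """
    rng = np.random.default_rng([int(cfg.seed), 1])
    tp = np.asarray(cfg.time_points)
    t_idx = rng.choice(len(tp), size=cfg.n_cells, p=cfg.sampling_weights())
    t = tp[t_idx]
    if cfg.couple_cycle_speed:
        # later time points -> slower cycling -> phases drawn with a mild
        # concentration toward 0; keeps theta marginally non-uniform late.
        theta = np.empty(cfg.n_cells)
        span = max(tp) - min(tp)
        for i in range(cfg.n_cells):
            kappa = 2.0 * (t[i] - min(tp)) / span
            theta[i] = rng.vonmises(0.0, kappa) % TWO_PI
    else:
        theta = rng.uniform(0.0, TWO_PI, cfg.n_cells)

    lam = _log_means(truth, cfg, theta, t)
    mu = np.exp(lam)
    if cfg.noise == "nb":
        r = cfg.dispersion
        counts = rng.negative_binomial(r, r / (r + mu)).astype(float)
    else:
        counts = np.maximum(0.0, rng.normal(mu, np.sqrt(mu)))

    width = len(str(cfg.n_cells - 1))
    cells = [f"C{i:0{width}d}" for i in range(cfg.n_cells)]
    expr = ExpressionMatrix(
        pd.DataFrame(counts, index=truth.genes, columns=cells), layer=LAYER_COUNTS
    )
    truth.true_theta = theta
    clock = CellClock(cell_ids=np.array(cells, dtype=object), real_time=t)
    return expr, clock


def lognormalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Depth-scale each cell to the median depth, then log(1+x).

    Shape and identifiers are unchanged; the layer tag flips to
    log-normalized. Cells with zero total count are rejected.
    """
    if expr.layer != LAYER_COUNTS:
        raise ValueError("lognormalize expects the raw counts layer")
    depths = expr.values.sum(axis=0).to_numpy()
    zero = depths == 0
    if zero.any():
        bad = [expr.cells[i] for i in np.where(zero)[0][:10]]
        raise ValueError(f"cells with zero total count: {bad}")
    scale = np.median(depths) / depths
    out = np.log1p(expr.values.to_numpy() * scale[np.newaxis, :])
    return ExpressionMatrix(
        pd.DataFrame(out, index=expr.values.index, columns=expr.values.columns),
        layer=LAYER_LOGNORM,
    )


def simulate_dataset(cfg: SimConfig) -> tuple[ExpressionMatrix, CellClock, SimTruth]:
    """Convenience wrapper: plant a truth network and simulate counts."""
    truth = generate_random_truth(cfg)
    expr, clock = simulate_expression(truth, cfg)
    return expr, clock, truth
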