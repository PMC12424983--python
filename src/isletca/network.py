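"""Functional beta-cell networks from trace cross-correlations.

Within a condition's time window, the zero-lag Pearson correlation of each
ROI pair's de-bleached traces is computed; ROI pairs whose correlation is
at least a threshold (0.7 by default, at which the correlation explains
about half the variance, R^2 > 0.49) are joined by an undirected,
unweighted edge.  Three summary metrics describe each network: mean node
degree, average (local) clustering, and global efficiency — the mean over
ordered node pairs of the inverse shortest-path length, with disconnected
pairs contributing zero, which keeps the metric defined for the sparse,
fragmented networks seen under some conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .segmentation import TraceSet

logger = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    """Symmetric pairwise trace correlations within a time window."""

    matrix: np.ndarray
    roi_ids: np.ndarray
    window_s: tuple[float, float]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("matrix must be square")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if np.any(np.abs(m) > 1 + 1e-9):
            raise ValueError("correlations must lie in [-1, 1]")
        self.matrix = m


@dataclass
class NetworkMetrics:
    """Summary metrics of a functional network."""

    mean_node_degree: float
    average_clustering: float
    mean_efficiency: float


@dataclass
class FunctionalNetwork:
    """Undirected unweighted graph over ROI nodes, from thresholded correlations."""

    graph: nx.Graph
    threshold: float


def correlation_matrix(
    traces: TraceSet,
    window_s: tuple[float, float] | None = None,
    max_lag_s: float = 0.0,
) -> CorrelationMatrix:
    """Pairwise Pearson correlation of traces restricted to a time window.

    ``max_lag_s > 0`` takes, for each pair, the maximum correlation over
    integer-frame lags within ``+/-max_lag_s`` (off by default: zero-lag).
    Zero-variance traces get zero off-diagonal entries with a logged
    warning; the diagonal stays 1.
    """
    if traces.n_rois < 2:
        raise ValueError("correlation requires at least 2 ROIs")
    n = traces.traces.shape[1]
    if window_s is None:
        lo, hi = 0, n
        window_s = (0.0, n / traces.rate_hz)
    else:
        lo = int(round(window_s[0] * traces.rate_hz))
        hi = int(round(window_s[1] * traces.rate_hz))
        lo, hi = max(lo, 0), min(hi, n)
    if (hi - lo) / traces.rate_hz < 30.0:
        raise ValueError("correlation window must span at least 30 s")
    x = traces.traces[:, lo:hi]
    sd = x.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning(
            "zero-variance traces in window for ROIs %s; correlations set to 0",
            list(np.asarray(traces.roi_ids)[degenerate]),
        )
    safe = x.copy()
    # placeholder with non-zero variance; these rows are zeroed below
    safe[degenerate] = np.arange(hi - lo, dtype=float)
    if max_lag_s > 0:
        m = _max_lag_corr(safe, traces.rate_hz, max_lag_s)
    else:
        m = np.corrcoef(safe)
    m[degenerate, :] = 0.0
    m[:, degenerate] = 0.0
    np.fill_diagonal(m, 1.0)
    m = np.clip((m + m.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(m, 1.0)
    return CorrelationMatrix(m, np.asarray(traces.roi_ids), window_s)


def _max_lag_corr(x: np.ndarray, rate_hz: float, max_lag_s: float) -> np.ndarray:
    max_lag = int(round(max_lag_s * rate_hz))
    k = x.shape[0]
    out = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            best = -1.0
            for lag in range(-max_lag, max_lag + 1):
                if lag >= 0:
                    a, b = x[i, lag:], x[j, : x.shape[1] - lag]
                else:
                    a, b = x[i, :lag], x[j, -lag:]
                if a.size < 2:
                    continue
                r = np.corrcoef(a, b)[0, 1]
                best = max(best, r)
            out[i, j] = out[j, i] = best
    return out


def build_network(corr: CorrelationMatrix, threshold: float = 0.7) -> FunctionalNetwork:
    """Edge between ROIs i != j iff correlation(i, j) >= threshold (inclusive)."""
    g = nx.Graph()
    ids = [int(r) for r in corr.roi_ids]
    g.add_nodes_from(ids)
    k = len(ids)
    for i in range(k):
        for j in range(i + 1, k):
            if corr.matrix[i, j] >= threshold:
                g.add_edge(ids[i], ids[j])
    return FunctionalNetwork(g, threshold)


def network_metrics(net: FunctionalNetwork) -> NetworkMetrics:
    """Mean node degree, average local clustering, and global efficiency.

    Nodes of degree < 2 contribute 0 to the clustering average; pairs in
    different components contribute 0 to the efficiency.
    """
    g = net.graph
    k = g.number_of_nodes()
    if k == 0:
        raise ValueError("network has no nodes")
    mean_degree = 2.0 * g.number_of_edges() / k
    clustering = nx.average_clustering(g) if k else 0.0
    efficiency = nx.global_efficiency(g) if k > 1 else 0.0
    return NetworkMetrics(mean_degree, clustering, efficiency)


__all__ = [
    "CorrelationMatrix",
    "FunctionalNetwork",
    "NetworkMetrics",
    "correlation_matrix",
    "build_network",
    "network_metrics",
]
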