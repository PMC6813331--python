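"""Sparse microbial association networks by neighborhood selection with
StARS stability selection.

The meta-network over all fungal and bacterial OTUs is estimated by
lasso-regressing each OTU on all others (Meinshausen–Bühlmann neighborhood
selection) over a log-spaced path of penalties, and the penalty is chosen by
the Stability Approach to Regularization Selection (StARS): the graph is
re-estimated on many random subsamples, per-edge selection variability is
summarized as ``2 * theta * (1 - theta)``, and the densest graph whose
monotonized average instability stays below a threshold is retained.

The model/results split follows the statsmodels convention:
``MetaNetworkModel(data).fit()`` returns a :class:`MetaNetworkResults`
holding the adjacency, per-edge stability scores, the penalty path and the
instability profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._solvers import neighborhood_coefs, neighborhood_graph_path
from .containers import OtuTable

_CD_TOL = 1e-9
_CD_MAX_ITER = 10_000
_PATH_TOL = 1e-5     # StARS path fits need selection patterns, not precise
_PATH_MAX_ITER = 100  # coefficients; saturation-truncated per node


@dataclass
class NetworkConfig:
    """StARS / neighborhood-selection settings.

    The penalty path has ``n_lambda`` log-spaced values running from the
    maximum absolute off-diagonal correlation down by ``lambda_min_ratio``.
    ``n_subsamples`` subsamples of ``min(floor(10*sqrt(n)),
    floor(subsample_fraction * n))`` samples — the stability method's
    canonical b(n) = 10*sqrt(n) rule, capped by the fraction so that small
    designs (where 10*sqrt(n) would exceed n) still leave held-out samples —
    are drawn without replacement for the stability criterion; 0.05 is the
    published StARS instability default.
    """

    n_lambda: int = 50
    lambda_min_ratio: float = 0.01
    n_subsamples: int = 100
    subsample_fraction: float = 0.8
    instability_threshold: float = 0.05
    symmetrization: str = "OR"
    seed: int = 0

    def __post_init__(self):
        if self.n_lambda < 2:
            raise ValueError("n_lambda must be >= 2")
        if not (0.0 < self.lambda_min_ratio < 1.0):
            raise ValueError("lambda_min_ratio must lie in (0, 1)")
        if not (0.0 < self.subsample_fraction < 1.0):
            raise ValueError("subsample_fraction must lie in (0, 1)")
        if self.symmetrization not in ("OR", "AND"):
            raise ValueError("symmetrization must be 'OR' or 'AND'")


def _as_matrix(data):
    if isinstance(data, OtuTable):
        return data.abundance.to_numpy(dtype=float), data.otu_ids, data.kingdom
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), data.columns, None
    arr = np.asarray(data, dtype=float)
    return arr, pd.RangeIndex(arr.shape[1]), None


def _correlation_gram(X: np.ndarray) -> np.ndarray:
    """Column correlation matrix with zero-variance columns zeroed out."""
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        G = np.corrcoef(X, rowvar=False)
    G = np.where(np.isfinite(G), G, 0.0)
    np.fill_diagonal(G, 1.0)
    if (sd == 0).any():
        dead = np.flatnonzero(sd == 0)
        G[dead, :] = 0.0
        G[:, dead] = 0.0
        G[dead, dead] = 1.0
    return np.ascontiguousarray(G)


def lambda_path(data, n_lambda: int = 50, lambda_min_ratio: float = 0.01) -> np.ndarray:
    """Log-spaced penalty path from the empirical lambda_max.

    ``lambda_max`` is the largest absolute off-diagonal entry of the sample
    correlation matrix — the smallest penalty at which every neighborhood is
    empty.
    """
    X, _, _ = _as_matrix(data)
    G = _correlation_gram(X)
    off = np.abs(G - np.diag(np.diag(G)))
    lam_max = float(off.max())
    if lam_max <= 0:
        raise ValueError("degenerate data: all off-diagonal correlations are zero")
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)


def mb_neighborhoods(data, lam: float):
    """Per-node lasso neighborhoods at a single penalty.

    Columns are standardized internally so that a single-predictor solution
    equals the soft-thresholded sample correlation ``sign(r)*max(|r|-lam,0)``.
    Returns ``(selected, coefs)``: a directed boolean DataFrame whose row j
    flags the neighborhood of node j, and the matching coefficient matrix.
    """
    X, ids, _ = _as_matrix(data)
    G = _correlation_gram(X)
    coefs = neighborhood_coefs(G, float(lam), _CD_TOL, _CD_MAX_ITER)
    sel = coefs != 0.0
    return (
        pd.DataFrame(sel, index=ids, columns=ids),
        pd.DataFrame(coefs, index=ids, columns=ids),
    )


def _symmetrize(sel: np.ndarray, rule: str) -> np.ndarray:
    return (sel | sel.swapaxes(-1, -2)) if rule == "OR" else (sel & sel.swapaxes(-1, -2))


@dataclass
class Connectedness:
    """Realized links as a share of possible links, ordered-pair convention:
    percent = 100 * ordered_links / n_otus**2."""

    n_otus: int
    ordered_links: int
    unordered_links: int
    possible_links: int
    percent: float


def connectedness(network_or_links, n_otus: int | None = None) -> Connectedness:
    """Connectedness of a network, or of printed link counts.

    Accepts either a :class:`MetaNetworkResults` or an ordered (directed)
    link count together with ``n_otus``.  The denominator is ``n_otus**2``
    (ordered pairs including self-pairs), with both ordered and unordered
    counts reported.
    """
    if isinstance(network_or_links, MetaNetworkResults):
        p = len(network_or_links.otu_ids)
        unordered = int(network_or_links.adjacency.to_numpy().sum() // 2)
        ordered = 2 * unordered
    else:
        ordered = int(network_or_links)
        if n_otus is None:
            raise ValueError("n_otus required when passing a raw link count")
        p = int(n_otus)
        unordered = ordered // 2
    if p == 0:
        raise ValueError("connectedness undefined for an empty OTU set")
    possible = p * p
    return Connectedness(p, ordered, unordered, possible, 100.0 * ordered / possible)


@dataclass
class MetaNetworkResults:
    """Fitted meta-network: adjacency, per-edge stability and the StARS path."""

    otu_ids: pd.Index
    kingdom: pd.Series | None
    adjacency: pd.DataFrame
    edge_stability: pd.DataFrame
    selected_lambda: float
    selected_index: int
    lambda_path: np.ndarray
    instability_path: np.ndarray
    monotone_instability: np.ndarray
    config: NetworkConfig
    threshold_met: bool = True

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.to_numpy().sum() // 2)

    def connectedness(self) -> Connectedness:
        return connectedness(self)

    def edge_list(self) -> pd.DataFrame:
        adj = self.adjacency.to_numpy()
        stab = self.edge_stability.to_numpy()
        iu, ju = np.triu_indices(len(self.otu_ids), k=1)
        keep = adj[iu, ju]
        return pd.DataFrame(
            {
                "otu_a": self.otu_ids[iu[keep]],
                "otu_b": self.otu_ids[ju[keep]],
                "stability": stab[iu[keep], ju[keep]],
            }
        )

    def graph(self):
        """networkx Graph with kingdom node attributes and stability edge
        weights."""
        import networkx as nx

        g = nx.Graph()
        for o in self.otu_ids:
            g.add_node(
                o,
                kingdom="" if self.kingdom is None else str(self.kingdom[o]),
            )
        for _, row in self.edge_list().iterrows():
            g.add_edge(row["otu_a"], row["otu_b"], stability=float(row["stability"]))
        return g

    def summary(self) -> str:
        c = self.connectedness()
        lines = [
            "Meta-network (MB neighborhood selection + StARS)",
            "=" * 48,
            f"OTUs:                  {len(self.otu_ids)}",
            f"Edges (unordered):     {self.n_edges}",
            f"Connectedness:         {c.percent:.2f}% "
            f"({c.ordered_links} / {c.possible_links} ordered links)",
            f"Selected lambda:       {self.selected_lambda:.6f} "
            f"(index {self.selected_index} of {len(self.lambda_path)})",
            f"Instability at lambda: {self.monotone_instability[self.selected_index]:.4f} "
            f"(threshold {self.config.instability_threshold})",
            f"Threshold met:         {self.threshold_met}",
        ]
        return "\n".join(lines)


class MetaNetworkModel:
    """Association-network estimator over a standardized OTU matrix.

    Parameters
    ----------
    data : OtuTable or DataFrame
        Standardized samples x OTUs matrix (both kingdoms combined).
    config : NetworkConfig, optional
    """

    def __init__(self, data, config: NetworkConfig | None = None):
        self.X, self.otu_ids, self.kingdom = _as_matrix(data)
        if self.X.shape[0] < 10:
            raise ValueError("StARS needs at least 10 samples")
        self.config = config or NetworkConfig()

    def fit(self, seed: int | None = None) -> MetaNetworkResults:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
        n, p = self.X.shape
        lams = lambda_path(self.X, cfg.n_lambda, cfg.lambda_min_ratio)
        b = min(int(np.floor(10.0 * np.sqrt(n))),
                int(np.floor(cfg.subsample_fraction * n)))
        counts = np.zeros((cfg.n_lambda, p, p), dtype=np.uint16)
        max_act_sub = min(p - 1, (9 * b) // 10)
        for _ in range(cfg.n_subsamples):
            rows = rng.choice(n, size=b, replace=False)
            G = _correlation_gram(self.X[rows])
            sel = neighborhood_graph_path(G, lams, _PATH_TOL, _PATH_MAX_ITER,
                                          max_act_sub)
            counts += _symmetrize(sel, cfg.symmetrization)
        theta = counts.astype(float) / cfg.n_subsamples
        xi = 2.0 * theta * (1.0 - theta)
        iu, ju = np.triu_indices(p, k=1)
        instability = xi[:, iu, ju].mean(axis=1)
        mono = np.maximum.accumulate(instability)
        ok = np.flatnonzero(mono <= cfg.instability_threshold)
        if len(ok):
            sel_idx = int(ok[-1])  # densest graph still below the threshold
            met = True
        else:
            sel_idx = int(np.argmin(mono))
            met = False
            warnings.warn(
                "no penalty met the StARS instability threshold "
                f"{cfg.instability_threshold}; falling back to the minimal-"
                "instability penalty"
            )
        G_full = _correlation_gram(self.X)
        sel_full = neighborhood_graph_path(G_full, lams, _PATH_TOL,
                                           _PATH_MAX_ITER,
                                           min(p - 1, (9 * n) // 10))
        adj = _symmetrize(sel_full, cfg.symmetrization)[sel_idx]
        np.fill_diagonal(adj, False)
        stab = theta[sel_idx].copy()
        np.fill_diagonal(stab, 0.0)
        return MetaNetworkResults(
            otu_ids=pd.Index(self.otu_ids),
            kingdom=self.kingdom,
            adjacency=pd.DataFrame(adj, index=self.otu_ids, columns=self.otu_ids),
            edge_stability=pd.DataFrame(stab, index=self.otu_ids,
                                        columns=self.otu_ids),
            selected_lambda=float(lams[sel_idx]),
            selected_index=sel_idx,
            lambda_path=lams,
            instability_path=instability,
            monotone_instability=mono,
            config=cfg,
            threshold_met=met,
        )


def stars_select(data, config: NetworkConfig | None = None) -> MetaNetworkResults:
    """Convenience wrapper: fit the meta-network with StARS selection."""
    return MetaNetworkModel(data, config).fit()


__all__ = [
    "NetworkConfig",
    "MetaNetworkModel",
    "MetaNetworkResults",
    "Connectedness",
    "lambda_path",
    "mb_neighborhoods",
    "stars_select",
    "connectedness",
]
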