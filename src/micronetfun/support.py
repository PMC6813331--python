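"""Function-supporting taxa by elastic-net feature selection.

For every ecosystem function, all OTUs enter a penalized regression jointly:
the elastic net mixes lasso (l1) and ridge (l2) penalties through a mixing
parameter alpha, evaluated over a grid alpha = 0, 0.01, ..., 1 with a
100-value lambda path per alpha and leave-one-out cross-validation.  The
(alpha, lambda) pair with minimum CV mean squared error is refit on all
samples; OTUs with nonzero coefficients are classified as supporting
(positive coefficient after direction adjustment) or inhibiting (negative).
Loss-type functions (leaching, N2O emission) are negated before fitting so
"supporting" always means improving functioning.

A per-taxon randomization test — observed abundance–function correlation
against a permutation null with a central 95% range — is provided as the
independent single-taxon cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._solvers import enet_coef_gram, loo_mse_grid
from .containers import BENEFIT, LOSS, FunctionTable, OtuTable, SupportEntry, SupportMap

_RIDGE_ALPHA_ANCHOR = 1e-3  # lambda_max at alpha=0 anchored at alpha=0.001's
_LOO_TOL = 1e-4      # CV-surface fits: locating the MSE minimum needs far
_LOO_MAX_ITER = 60   # less precision than the final refit
_FIT_TOL = 1e-10
_MAX_ITER = 10_000


@dataclass
class ElasticNetConfig:
    """Selection-grid settings: alpha from 0 to 1 in steps of 0.01,
    a 100-value log-spaced lambda path per alpha (ratio 1e-3), and
    leave-one-out CV with minimum-MSE selection."""

    alpha_step: float = 0.01
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.alpha_step <= 1.0):
            raise ValueError("alpha_step must lie in (0, 1]")
        if self.n_lambda < 2 or not (0.0 < self.lambda_min_ratio < 1.0):
            raise ValueError("invalid lambda path settings")

    @property
    def alpha_grid(self) -> np.ndarray:
        n = int(round(1.0 / self.alpha_step))
        return np.round(np.linspace(0.0, 1.0, n + 1), 10)


def _center_scale(X: np.ndarray):
    """Center columns and scale to unit second moment (x'x/n = 1)."""
    mu = X.mean(axis=0)
    Xc = X - mu
    sd = np.sqrt((Xc**2).mean(axis=0))
    sd_safe = np.where(sd > 0, sd, 1.0)
    return Xc / sd_safe, sd_safe


def _check_kkt(G, c, beta, alpha, lam, tol=1e-6, context="elastic net"):
    """Warn if the stationarity conditions of the penalized objective are
    violated beyond ``tol`` (reported non-convergence)."""
    grad = G @ beta - c + lam * (1.0 - alpha) * beta
    l1 = lam * alpha
    nz = beta != 0
    viol = 0.0
    if nz.any():
        viol = np.max(np.abs(grad[nz] + l1 * np.sign(beta[nz])))
    if (~nz).any():
        viol = max(viol, float(np.max(np.maximum(np.abs(grad[~nz]) - l1, 0.0))))
    if viol > tol:
        warnings.warn(
            f"{context} solution did not reach stationarity "
            f"(KKT violation {viol:.2e} > {tol:g})")


def fit_elastic_net(X, y, alpha: float, lam: float) -> np.ndarray:
    """Elastic-net coefficients at one (alpha, lambda).

    Minimizes ``(1/2n)||y - X b||^2 + lam*(alpha*||b||_1 +
    (1-alpha)/2*||b||^2)``.  ``X`` is expected standardized and ``y``
    centered; both are centered defensively.  With unit-second-moment
    columns the single-predictor solution is the soft-thresholded (alpha=1)
    or shrunken (alpha=0: r/(1+lam)) sample correlation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    n = X.shape[0]
    G = Xc.T @ Xc / n
    c = Xc.T @ yc / n
    beta = enet_coef_gram(G, c, float(alpha), float(lam), tol=_FIT_TOL,
                          max_iter=_MAX_ITER)
    _check_kkt(G, c, beta, float(alpha), float(lam))
    return beta


def _lambda_paths(c: np.ndarray, alphas: np.ndarray, cfg: ElasticNetConfig):
    lam_ceiling = np.abs(c).max()
    paths = np.empty((len(alphas), cfg.n_lambda))
    for i, a in enumerate(alphas):
        lam_max = lam_ceiling / max(a, _RIDGE_ALPHA_ANCHOR)
        paths[i] = np.geomspace(lam_max, lam_max * cfg.lambda_min_ratio,
                                cfg.n_lambda)
    return paths


def select_support(
    X,
    y,
    config: ElasticNetConfig | None = None,
    direction: str = BENEFIT,
    function: str = "function",
    otu_ids=None,
) -> SupportEntry:
    """Minimum-LOO-MSE elastic-net selection for one function.

    MSE ties across the grid resolve to the larger alpha, then the larger
    lambda (the sparser model).  Returns a :class:`SupportEntry` whose
    coefficients are on the direction-adjusted scale.
    """
    config = config or ElasticNetConfig()
    if isinstance(X, OtuTable):
        otu_ids = X.otu_ids
        X = X.abundance
    if isinstance(X, pd.DataFrame):
        otu_ids = X.columns if otu_ids is None else otu_ids
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if otu_ids is None:
            otu_ids = pd.RangeIndex(X.shape[1])
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < 10:
        raise ValueError("need at least 10 samples for LOO-CV selection")
    if direction == LOSS:
        y = -y
    elif direction != BENEFIT:
        raise ValueError(f"unknown direction {direction!r}")
    Xs, sd = _center_scale(X)
    yc = y - y.mean()
    c_full = Xs.T @ yc / n
    alphas = config.alpha_grid
    paths = _lambda_paths(c_full, alphas, config)
    mse = loo_mse_grid(Xs, yc, alphas, paths, _LOO_TOL, _LOO_MAX_ITER)
    best = mse.min()
    ties = np.argwhere(mse <= best + 1e-12)
    # parsimony tie-break: larger alpha, then larger lambda
    ia, il = max(ties.tolist(), key=lambda t: (alphas[t[0]], -t[1]))
    alpha_hat, lam_hat = float(alphas[ia]), float(paths[ia, il])
    G = Xs.T @ Xs / n
    beta_int = enet_coef_gram(G, c_full, alpha_hat, lam_hat, tol=_FIT_TOL,
                              max_iter=_MAX_ITER)
    _check_kkt(G, c_full, beta_int, alpha_hat, lam_hat,
               context=f"final refit for {function!r}")
    beta = beta_int / sd  # back to the input column scale
    coefs = pd.Series(beta, index=pd.Index(otu_ids), name=function)
    if not (coefs != 0).any():
        warnings.warn(f"elastic net selected the empty model for {function!r}")
    return SupportEntry(
        function=function,
        coefficients=coefs,
        alpha=alpha_hat,
        lam=lam_hat,
        cv_mse=float(mse[ia, il]),
    )


@dataclass
class SupportResults:
    """Fitted support map plus per-function selection diagnostics."""

    support_map: SupportMap
    cv_table: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return self.support_map.to_frame()

    def summary(self) -> str:
        lines = ["Function-supporting taxa (elastic net, LOO-CV)", "=" * 48]
        for f, e in self.support_map.entries.items():
            lines.append(
                f"{f:<20s} alpha={e.alpha:4.2f} lambda={e.lam:9.5f} "
                f"cv_mse={e.cv_mse:8.4f}  support={len(e.supporting):3d} "
                f"inhibit={len(e.inhibiting):3d}"
            )
        return "\n".join(lines)


class FunctionSupportModel:
    """Joint-taxa predictor selection for a table of ecosystem functions.

    ``data`` is the standardized OTU matrix; ``functions`` a
    :class:`FunctionTable` whose loss-type columns are negated before
    fitting.
    """

    def __init__(self, data, functions: FunctionTable,
                 config: ElasticNetConfig | None = None):
        self.data = data
        self.functions = functions
        self.config = config or ElasticNetConfig()

    def fit(self, subset=None) -> SupportResults:
        names = list(self.functions.names if subset is None else subset)
        entries = {}
        rows = []
        for nm in names:
            entry = select_support(
                self.data,
                self.functions.values[nm].to_numpy(dtype=float),
                config=self.config,
                direction=str(self.functions.direction[nm]),
                function=nm,
            )
            entries[nm] = entry
            rows.append(
                {"function": nm, "alpha": entry.alpha, "lambda": entry.lam,
                 "cv_mse": entry.cv_mse, "n_support": len(entry.supporting),
                 "n_inhibit": len(entry.inhibiting)}
            )
        return SupportResults(
            support_map=SupportMap(entries),
            cv_table=pd.DataFrame(rows).set_index("function"),
        )


def randomization_test(
    X,
    y,
    n_perm: int = 999,
    level: float = 0.95,
    direction: str = BENEFIT,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-taxon permutation test of abundance–function association.

    The observed effect is the Pearson correlation of each taxon's abundance
    with the direction-adjusted function; the null distribution comes from
    ``n_perm`` permutations of the function values.  A taxon is flagged when
    its observed effect falls outside the central ``level`` range of its own
    null.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if isinstance(X, OtuTable):
        X = X.abundance
    ids = X.columns if isinstance(X, pd.DataFrame) else pd.RangeIndex(
        np.asarray(X).shape[1])
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.std(y) == 0:
        raise ValueError("constant function values")
    if direction == LOSS:
        y = -y
    n = X.shape[0]
    Xs, _ = _center_scale(X)
    ys = (y - y.mean()) / y.std()
    obs = Xs.T @ ys / n
    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm, X.shape[1]))
    for b in range(n_perm):
        perms[b] = Xs.T @ ys[rng.permutation(n)] / n
    tail = (1.0 - level) / 2.0
    lo = np.quantile(perms, tail, axis=0)
    hi = np.quantile(perms, 1.0 - tail, axis=0)
    flagged = (obs < lo) | (obs > hi)
    return pd.DataFrame(
        {
            "effect": obs,
            "null_lo": lo,
            "null_hi": hi,
            "flagged": flagged,
            "role": np.where(~flagged, "none",
                             np.where(obs > 0, "support", "inhibit")),
        },
        index=ids,
    )


@dataclass
class OverlapResult:
    jaccard_percent: float
    overlap_coefficient: float
    n_intersection: int
    n_union: int


def support_overlap(set_a, set_b) -> OverlapResult:
    """Jaccard overlap of two supporter sets, in percent, with the overlap
    coefficient (|A∩B| / min(|A|, |B|)) alongside.  Undefined (NaN) when both
    sets are empty."""
    a, b = set(set_a), set(set_b)
    inter, union = len(a & b), len(a | b)
    if union == 0:
        return OverlapResult(float("nan"), float("nan"), 0, 0)
    oc = inter / min(len(a), len(b)) if min(len(a), len(b)) else float("nan")
    return OverlapResult(100.0 * inter / union, oc, inter, union)


__all__ = [
    "ElasticNetConfig",
    "FunctionSupportModel",
    "SupportResults",
    "fit_elastic_net",
    "select_support",
    "randomization_test",
    "support_overlap",
    "OverlapResult",
]
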