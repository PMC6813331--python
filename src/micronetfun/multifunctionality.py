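"""Ecosystem multifunctionality indices.

Two per-sample aggregates of the ten measured functions, both computed on
direction-adjusted values (loss-type functions — N and P leaching, N2O
emission — are negated first, since high values there indicate nutrient
losses):

* averaging index — mean of the z-scored functions; grand mean 0 by
  construction.
* multidimensional index — PCA on the z-scored function matrix; per-sample
  score summed over axes with eigenvalue-share weights, each axis oriented
  to correlate non-negatively with the averaging index.  This avoids the
  averaging index's implicit assumption that collinear functions deserve
  their summed weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import FunctionTable


def _adjusted_z(functions: FunctionTable) -> pd.DataFrame:
    vals = functions.adjusted()
    sd = vals.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = sd.index[sd == 0].tolist()
        raise ValueError(f"constant function column(s): {bad}")
    return (vals - vals.mean(axis=0)) / sd


def multifunctionality_avg(functions: FunctionTable) -> pd.Series:
    """Averaging multifunctionality: per-sample mean of normalized,
    direction-adjusted function measures."""
    if functions.values.shape[0] < 2:
        raise ValueError("need at least two samples")
    return _adjusted_z(functions).mean(axis=1).rename("multifun_avg")


def multifunctionality_multidim(
    functions: FunctionTable, n_axes: int | None = None
) -> pd.Series:
    """Multidimensional (PCA-weighted) multifunctionality index.

    All principal axes are retained by default; each axis score is weighted
    by its eigenvalue share and oriented so that it correlates non-negatively
    with the averaging index.
    """
    Z = _adjusted_z(functions)
    avg = Z.mean(axis=1).to_numpy()
    M = Z.to_numpy()
    # PCA via SVD of the centered (already column-centered) matrix
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    eig = s**2
    if n_axes is not None:
        keep = min(n_axes, len(eig))
    else:
        keep = int((eig > 1e-12 * eig.max()).sum())
    scores = U[:, :keep] * s[:keep]
    for k in range(keep):
        if np.dot(scores[:, k], avg) < 0:
            scores[:, k] = -scores[:, k]
    share = eig[:keep] / eig.sum()
    idx = scores @ share
    return pd.Series(idx, index=functions.values.index, name="multifun_multidim")


@dataclass
class MultifunctionalityResults:
    """Both indices plus their Pearson correlation."""

    averaging_index: pd.Series
    multidimensional_index: pd.Series
    correlation_between: float
    correlation_p: float

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([self.averaging_index, self.multidimensional_index],
                         axis=1)

    def summary(self) -> str:
        return "\n".join([
            "Multifunctionality indices",
            "=" * 48,
            f"Samples:                    {len(self.averaging_index)}",
            f"Averaging index grand mean: {self.averaging_index.mean():+.2e}",
            f"Pearson r (avg vs multidim): {self.correlation_between:.3f} "
            f"(P = {self.correlation_p:.3g})",
        ])


class MultifunctionalityModel:
    """Computes both multifunctionality indices from a function table."""

    def __init__(self, functions: FunctionTable, n_axes: int | None = None):
        self.functions = functions
        self.n_axes = n_axes

    def fit(self) -> MultifunctionalityResults:
        avg = multifunctionality_avg(self.functions)
        md = multifunctionality_multidim(self.functions, self.n_axes)
        r, p = sps.pearsonr(avg.to_numpy(), md.to_numpy())
        return MultifunctionalityResults(avg, md, float(r), float(p))


__all__ = [
    "multifunctionality_avg",
    "multifunctionality_multidim",
    "MultifunctionalityModel",
    "MultifunctionalityResults",
]
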