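"""OTU-table filtering and standardization.

The analysis-ready matrix is produced in three steps, in this order: counts
are converted to proportions of total reads per sample; OTUs below a mean
relative-abundance threshold or detected in too few samples are removed
(both criteria evaluated on the unfiltered proportion table); the retained
OTU columns are z-scored to overall mean 0 and unit sample variance.  Rows
are not re-normalized after filtering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import OtuTable


@dataclass
class FilterConfig:
    """OTU retention rules.

    ``mean_abundance_threshold`` is a proportion of total reads.  The default
    is 1e-4 (0.01% mean relative abundance); a literal 1% cutoff is far too
    aggressive to leave a usable community matrix at amplicon scale but
    remains selectable.  ``min_prevalence`` is the minimum number of samples
    an OTU must be detected in (counted over all samples): the default 6
    removes OTUs present in five or fewer replicates.
    """

    mean_abundance_threshold: float = 1e-4
    min_prevalence: int = 6
    standardize: bool = True

    def __post_init__(self):
        if not (0.0 <= self.mean_abundance_threshold < 1.0):
            raise ValueError("mean_abundance_threshold must lie in [0, 1)")
        if self.min_prevalence < 1:
            raise ValueError("min_prevalence must be >= 1")


def to_proportions(table: OtuTable) -> OtuTable:
    """Convert each sample's abundances to proportions of its total reads."""
    ab = table.abundance
    if (ab.to_numpy() < 0).any():
        raise ValueError("abundance values must be non-negative")
    totals = ab.sum(axis=1)
    empty = totals[totals <= 0]
    if len(empty):
        raise ValueError(
            f"empty sample(s) with zero total abundance: {empty.index.tolist()}"
        )
    return table.with_abundance(ab.div(totals, axis=0))


def filter_otus(table: OtuTable, config: FilterConfig | None = None):
    """Remove rare and sparse OTUs.

    Returns ``(filtered_table, report)`` where ``report`` is a per-OTU frame
    with columns ``mean_prop``, ``prevalence`` and ``kept``.  Both criteria
    are computed on the input proportion table, so applying the filter twice
    retains the same set as applying it once.
    """
    config = config or FilterConfig()
    ab = table.abundance
    mean_prop = ab.mean(axis=0)
    prevalence = (ab > 0).sum(axis=0)
    kept = (mean_prop >= config.mean_abundance_threshold) & (
        prevalence >= config.min_prevalence
    )
    report = pd.DataFrame(
        {"mean_prop": mean_prop, "prevalence": prevalence, "kept": kept}
    )
    if not kept.any():
        raise ValueError(
            "filtering removed every OTU; relax mean_abundance_threshold or "
            "min_prevalence"
        )
    return table.select_otus(ab.columns[kept]), report


def standardize(table: OtuTable, strict: bool = False) -> OtuTable:
    """Z-score each OTU column to overall mean 0 and unit sample variance
    (ddof=1).  Constant columns are dropped with a warning, or raise when
    ``strict``."""
    ab = table.abundance
    if ab.shape[0] < 2:
        raise ValueError("standardization needs at least two samples")
    sd = ab.std(axis=0, ddof=1)
    constant = sd.index[sd == 0]
    if len(constant):
        if strict:
            raise ValueError(f"constant OTU column(s): {constant.tolist()}")
        warnings.warn(
            f"dropping {len(constant)} constant OTU column(s) before "
            "standardization"
        )
        table = table.select_otus(sd.index[sd > 0])
        ab = table.abundance
        sd = sd[sd > 0]
    z = (ab - ab.mean(axis=0)) / sd
    return table.with_abundance(z)


def clr(table: OtuTable, pseudocount: float = 0.5) -> OtuTable:
    """Centered log-ratio transform of a count or proportion table.

    Optional compositional correction before network estimation (off by
    default in the pipeline, which feeds standardized proportions to the
    graph estimator).  A pseudocount keeps zeros finite.
    """
    ab = table.abundance + pseudocount
    logp = np.log(ab.div(ab.sum(axis=1), axis=0))
    return table.with_abundance(logp.sub(logp.mean(axis=1), axis=0))


def preprocess(
    table: OtuTable, config: FilterConfig | None = None
) -> tuple[OtuTable, pd.DataFrame]:
    """Proportions -> filter -> (optional) standardization, in the canonical
    order.  Returns the analysis-ready table and the filter report."""
    config = config or FilterConfig()
    props = to_proportions(table)
    filtered, report = filter_otus(props, config)
    if config.standardize:
        filtered = standardize(filtered)
    return filtered, report


__all__ = ["FilterConfig", "to_proportions", "filter_otus", "standardize",
           "clr", "preprocess"]
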