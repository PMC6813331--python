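"""Per-sample community characteristic table.

Assembles, for every microcosm: bacterial / fungal / combined richness,
average number of function-supporting taxa (redundancy), functional
uniqueness, overall linkage densities and functional complexity by kingdom
pairing.  Combined richness is the mean of per-kingdom richness each min–max
scaled to [0, 1] across samples.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import BACTERIA, FUNGI, OtuTable, SupportMap
from .diversity import functional_complexity, redundancy, sample_uniqueness
from .network import MetaNetworkResults
from .subnetworks import PAIRINGS, sample_network_stats, subset_network


def _minmax(v: pd.Series) -> pd.Series:
    lo, hi = v.min(), v.max()
    if hi == lo:
        return pd.Series(0.0, index=v.index)
    return (v - lo) / (hi - lo)


def sample_indices(
    meta: MetaNetworkResults,
    table: OtuTable,
    support_map: SupportMap,
    mode: str = "strict",
) -> pd.DataFrame:
    """Per-sample SampleIndices table.

    ``table`` is the filtered (proportion-scale) OTU table whose nonzero
    entries define detection.  Functional complexity uses ``mode`` link
    counting ('strict': endpoints must support a common function).
    """
    presence = table.presence()
    rich_b = presence.loc[:, table.kingdom == BACTERIA].sum(axis=1)
    rich_f = presence.loc[:, table.kingdom == FUNGI].sum(axis=1)
    combined = (_minmax(rich_b) + _minmax(rich_f)) / 2.0
    out = pd.DataFrame(
        {
            "richness_bacteria": rich_b,
            "richness_fungi": rich_f,
            "richness_combined": combined,
        }
    )
    out["avg_supporters"] = redundancy(presence, support_map)
    out["uniqueness"] = sample_uniqueness(table.abundance, support_map)
    net_stats = sample_network_stats(meta, table)
    for pairing in PAIRINGS:
        out[f"density_{pairing}"] = net_stats[f"density_{pairing}"]
        out[f"links_{pairing}"] = net_stats[f"links_{pairing}"]
    fc = {p: [] for p in PAIRINGS}
    common = [o for o in meta.otu_ids if o in presence.columns]
    for sid in table.sample_ids:
        pres = pd.Series(False, index=meta.otu_ids)
        pres[common] = presence.loc[sid, common].to_numpy()
        sub = subset_network(meta, pres)
        for pairing in PAIRINGS:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fc[pairing].append(
                    functional_complexity(sub, support_map, pairing, mode))
    for pairing in PAIRINGS:
        out[f"functional_complexity_{pairing}"] = np.asarray(fc[pairing])
    if table.sample_meta is not None:
        out = out.join(table.sample_meta)
    return out


__all__ = ["sample_indices"]
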