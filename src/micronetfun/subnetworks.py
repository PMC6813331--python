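"""Per-sample subnetworks and linkage-density complexity.

Each microcosm's network is the subgraph of the meta-network induced on the
OTUs detected in that sample; its "complexity" is linkage density — links
per OTU — computed for four kingdom pairings: bacteria–bacteria (bb),
fungi–fungi (ff), bacteria–fungi (bf) and all OTUs together.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import BACTERIA, FUNGI, OtuTable
from .network import MetaNetworkResults

PAIRINGS = ("bb", "ff", "bf", "all")


@dataclass
class SubNetwork:
    """Induced subgraph of the meta-network on the present OTUs."""

    otu_ids: pd.Index
    adjacency: np.ndarray        # symmetric bool, zero diagonal
    kingdom: pd.Series | None

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def n_links(self) -> int:
        return int(self.adjacency.sum() // 2)


def subset_network(meta: MetaNetworkResults, presence) -> SubNetwork:
    """Induce the subgraph on OTUs flagged present.

    ``presence`` is a boolean vector indexed by the meta-network's OTU ids
    (a pandas Series or an aligned array).
    """
    ids = meta.otu_ids
    if isinstance(presence, pd.Series):
        if not presence.index.equals(pd.Index(ids)):
            presence = presence.reindex(ids)
            if presence.isna().any():
                raise ValueError("presence vector does not cover the meta-network OTU ids")
        mask = presence.to_numpy(dtype=bool)
    else:
        mask = np.asarray(presence, dtype=bool)
        if mask.shape[0] != len(ids):
            raise ValueError(
                f"presence length {mask.shape[0]} != meta-network size {len(ids)}"
            )
    keep = np.flatnonzero(mask)
    adj = meta.adjacency.to_numpy()[np.ix_(keep, keep)].copy()
    np.fill_diagonal(adj, False)
    kd = None if meta.kingdom is None else meta.kingdom.iloc[keep]
    return SubNetwork(otu_ids=ids[keep], adjacency=adj, kingdom=kd)


def _pairing_masks(sub: SubNetwork, pairing: str):
    """Node universe and link mask for a kingdom pairing."""
    if pairing not in PAIRINGS:
        raise ValueError(f"unknown pairing {pairing!r}; expected one of {PAIRINGS}")
    if pairing == "all":
        nodes = np.ones(sub.n_otus, dtype=bool)
        return nodes, np.outer(nodes, nodes)
    if sub.kingdom is None:
        raise ValueError("kingdom labels required for kingdom pairings")
    bac = (sub.kingdom == BACTERIA).to_numpy()
    fun = (sub.kingdom == FUNGI).to_numpy()
    if pairing == "bb":
        return bac, np.outer(bac, bac)
    if pairing == "ff":
        return fun, np.outer(fun, fun)
    # bf: cross-kingdom links over the universe of all present OTUs
    nodes = bac | fun
    return nodes, np.outer(bac, fun) | np.outer(fun, bac)


def link_count(sub: SubNetwork, pairing: str = "all") -> int:
    """Unordered link count restricted to a kingdom pairing."""
    _, pairmask = _pairing_masks(sub, pairing)
    return int((sub.adjacency & pairmask).sum() // 2)


def linkage_density(sub: SubNetwork, pairing: str = "all") -> float:
    """Links per OTU for a pairing.

    Denominators: present bacteria (bb), present fungi (ff), and all present
    OTUs (bf, all).  An empty node universe yields 0 with a warning.
    """
    nodes, _ = _pairing_masks(sub, pairing)
    denom = int(nodes.sum())
    if denom == 0:
        warnings.warn(f"no OTUs in the {pairing!r} universe; linkage density set to 0")
        return 0.0
    return link_count(sub, pairing) / denom


def display_otus(table: OtuTable, treatment, fraction: float = 0.75):
    """Per-treatment OTU sets for network display.

    Returns, for each treatment level, the OTUs detected in at least
    ``fraction`` of that level's replicates.  This is a *display* filter for
    per-treatment network exports; it is never applied to the statistics.
    """
    presence = table.presence()
    groups = pd.Series(np.asarray(treatment).astype(str),
                       index=table.sample_ids)
    out = {}
    for level, samples in groups.groupby(groups).groups.items():
        share = presence.loc[samples].mean(axis=0)
        out[level] = share.index[share >= fraction].tolist()
    return out


def sample_network_stats(meta: MetaNetworkResults, table: OtuTable) -> pd.DataFrame:
    """Per-sample subnetwork statistics table.

    "Present" means nonzero abundance in the (filtered) table.  Columns:
    per-kingdom OTU counts, per-pairing unordered link counts and linkage
    densities.
    """
    presence = table.presence()
    common = [o for o in meta.otu_ids if o in presence.columns]
    rows = []
    for sid in table.sample_ids:
        pres = pd.Series(False, index=meta.otu_ids)
        pres[common] = presence.loc[sid, common].to_numpy()
        sub = subset_network(meta, pres)
        row = {"sample_id": sid, "n_otus": sub.n_otus}
        if sub.kingdom is not None:
            row["n_bacteria"] = int((sub.kingdom == BACTERIA).sum())
            row["n_fungi"] = int((sub.kingdom == FUNGI).sum())
        for pairing in PAIRINGS:
            row[f"links_{pairing}"] = link_count(sub, pairing)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                row[f"density_{pairing}"] = linkage_density(sub, pairing)
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")


__all__ = [
    "PAIRINGS",
    "SubNetwork",
    "subset_network",
    "link_count",
    "linkage_density",
    "display_otus",
    "sample_network_stats",
]
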