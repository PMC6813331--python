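"""Functional redundancy, uniqueness, combination coverage, and functional
complexity.

These indices combine three upstream objects: per-sample detection of taxa,
the per-function supporter sets, and the per-sample subnetworks.

* redundancy — average, over functions, of the number of co-occurring taxa
  supporting the same function.
* functional uniqueness — Rao's quadratic entropy Q (abundance-weighted mean
  pairwise dissimilarity of the taxa's function-support profiles) times the
  inverse Simpson index D; for m equally abundant, maximally distinct taxa
  this equals m - 1.
* combination coverage — the share of the community needed to support every
  function in a k-subset of functions (union of supporter sets / total taxa).
* functional complexity — linkage density among present supporting taxa,
  counting (strict mode) only links whose endpoints support a common
  function.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd

from .containers import SupportMap
from .subnetworks import SubNetwork, _pairing_masks


def redundancy(presence, support_map: SupportMap):
    """Average number of present supporting taxa per function.

    ``presence`` may be a boolean Series (one sample) or DataFrame (samples
    x OTUs); returns a float or a per-sample Series accordingly.
    """
    if len(support_map) == 0:
        raise ValueError("support map is empty")
    if isinstance(presence, pd.DataFrame):
        return pd.Series(
            {s: redundancy(presence.loc[s], support_map) for s in presence.index},
            name="avg_supporters",
        )
    present = set(presence.index[presence.astype(bool)])
    counts = [len(set(e.supporting) & present) for e in support_map]
    return float(np.mean(counts))


def jaccard_dissimilarity(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Jaccard dissimilarity between binary rows (taxa x functions).
    Taxa with identical profiles have distance 0; taxa sharing no function
    have distance 1.  Two all-zero profiles are treated as identical (d=0)."""
    M = profiles.to_numpy(dtype=float)
    inter = M @ M.T
    sizes = M.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - np.where(union > 0, inter / np.where(union > 0, union, 1.0), 1.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=profiles.index, columns=profiles.index)


def functional_uniqueness(rel_abundance, distance) -> float:
    """Rao's quadratic entropy times the inverse Simpson index.

    ``rel_abundance`` are relative abundances summing to 1 over the taxa
    considered; ``distance`` is the matching pairwise dissimilarity matrix
    (zero diagonal).  Q = sum_ij p_i p_j d_ij, D = 1 / sum_i p_i^2.
    """
    p = np.asarray(
        rel_abundance.to_numpy() if isinstance(rel_abundance, pd.Series)
        else rel_abundance, dtype=float)
    if p.size == 0 or p.sum() <= 0:
        raise ValueError("empty community")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("relative abundances must sum to 1")
    d = np.asarray(
        distance.to_numpy() if isinstance(distance, pd.DataFrame) else distance,
        dtype=float)
    q = float(p @ d @ p)
    simpson = float((p**2).sum())
    return q / simpson


def sample_uniqueness(
    abundance: pd.DataFrame, support_map: SupportMap, distance: str = "jaccard"
) -> pd.Series:
    """Per-sample functional uniqueness.

    Abundances are restricted to taxa appearing in the support map's
    supporter sets and renormalized within each sample; the trait distance is
    the Jaccard dissimilarity of binary support profiles.
    """
    if distance != "jaccard":
        raise ValueError("only the 'jaccard' profile distance is implemented")
    profiles = support_map.support_profiles(abundance.columns)
    with_profile = profiles.index[profiles.sum(axis=1) > 0]
    d = jaccard_dissimilarity(profiles.loc[with_profile])
    out = {}
    for sid in abundance.index:
        ab = abundance.loc[sid, with_profile].clip(lower=0)
        total = ab.sum()
        if total <= 0:
            out[sid] = 0.0
            continue
        out[sid] = functional_uniqueness(ab / total, d)
    return pd.Series(out, name="uniqueness")


def combination_coverage(
    support_map: SupportMap,
    total_taxa: int,
    k: int,
    exclude=(),
    max_subsets: int = 500,
    seed: int = 0,
):
    """Proportion of the community needed to support k-function combinations.

    For every k-subset of functions (exhaustive, or ``max_subsets`` seeded
    random subsets when the exhaustive count exceeds it), the proportion is
    the size of the union of the supporter sets over ``total_taxa``.
    Functions listed in ``exclude`` are left out of the candidate pool.
    Returns ``(mean, per_subset_values)``.
    """
    funcs = [f for f in support_map.functions if f not in set(exclude)]
    if not (1 <= k <= len(funcs)):
        raise ValueError(f"k={k} out of range for {len(funcs)} functions")
    if total_taxa < 1:
        raise ValueError("total_taxa must be positive")
    sets = support_map.supporter_sets()
    from math import comb

    n_all = comb(len(funcs), k)
    if n_all <= max_subsets:
        subsets = itertools.combinations(funcs, k)
    else:
        rng = np.random.default_rng(seed)
        subsets = [
            tuple(np.asarray(funcs)[rng.choice(len(funcs), size=k, replace=False)])
            for _ in range(max_subsets)
        ]
    vals = []
    for combo in subsets:
        union = set().union(*(sets[f] for f in combo))
        vals.append(len(union) / total_taxa)
    vals = np.asarray(vals)
    return float(vals.mean()), vals


def functional_complexity(
    sub: SubNetwork,
    support_map: SupportMap,
    pairing: str = "all",
    mode: str = "strict",
) -> float:
    """Linkage density among present taxa that support at least one function.

    In strict mode a link counts only when both endpoints support a common
    function; in relaxed mode any link between supporting taxa counts.  The
    denominator is the number of present supporting taxa in the pairing's
    node universe.
    """
    if mode not in ("strict", "relaxed"):
        raise ValueError("mode must be 'strict' or 'relaxed'")
    profiles = support_map.support_profiles(sub.otu_ids)
    supporting = profiles.sum(axis=1).to_numpy() > 0
    if not supporting.any():
        warnings.warn("no supporting taxa present; functional complexity set to 0")
        return 0.0
    nodes, pairmask = _pairing_masks(sub, pairing)
    nodes = nodes & supporting
    denom = int(nodes.sum())
    if denom == 0:
        warnings.warn(
            f"no supporting taxa in the {pairing!r} universe; functional "
            "complexity set to 0")
        return 0.0
    P = profiles.to_numpy(dtype=bool)
    shared = (P @ P.T.astype(int)) > 0 if mode == "strict" else np.outer(
        supporting, supporting)
    valid = np.outer(supporting, supporting) & shared & pairmask
    links = int((sub.adjacency & valid).sum() // 2)
    return links / denom


def functional_link_count(
    sub: SubNetwork, support_map: SupportMap, pairing: str = "all",
    mode: str = "strict",
) -> int:
    """Unordered link count underlying :func:`functional_complexity`."""
    profiles = support_map.support_profiles(sub.otu_ids)
    supporting = profiles.sum(axis=1).to_numpy() > 0
    _, pairmask = _pairing_masks(sub, pairing)
    P = profiles.to_numpy(dtype=bool)
    shared = (P @ P.T.astype(int)) > 0 if mode == "strict" else np.outer(
        supporting, supporting)
    valid = np.outer(supporting, supporting) & shared & pairmask
    return int((sub.adjacency & valid).sum() // 2)


__all__ = [
    "redundancy",
    "jaccard_dissimilarity",
    "functional_uniqueness",
    "sample_uniqueness",
    "combination_coverage",
    "functional_complexity",
    "functional_link_count",
]
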