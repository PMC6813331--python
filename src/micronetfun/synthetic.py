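"""Synthetic soil-microbiome datasets with known ground truth.

Emulates the experimental design the pipeline targets: a soil-diversity
gradient created by progressively excluding taxa (six nested treatment
levels, the last nearly sterile), two kingdoms of OTUs (bacterial 16S and
fungal ITS) whose latent abundances follow a sparse Gaussian-copula
association graph, compositional sequencing counts, and ten ecosystem
functions generated as noisy weighted sums of planted supporter-taxon
abundances (three of them — N leaching, P leaching, N2O emission — flagged
as loss-type functions).

Every stochastic step is driven by a single integer seed, so identical
configurations reproduce identical tables bit for bit.  The returned
:class:`SyntheticTruth` records the planted association graph, supporter
sets and presence structure, which downstream recovery tests score against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import BENEFIT, LOSS, FunctionTable, OtuTable

DEFAULT_RETENTION = (1.0, 0.8, 0.6, 0.4, 0.2, 0.05)

FUNCTION_NAMES = (
    "forb_N_uptake",
    "forb_P_uptake",
    "legume_N_uptake",
    "legume_P_uptake",
    "grass_N_uptake",
    "grass_P_uptake",
    "decomposition",
    "N_leaching",
    "P_leaching",
    "N2O_emission",
)
LOSS_FUNCTIONS = ("N_leaching", "P_leaching", "N2O_emission")


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study.

    Defaults are sized to the emulated experiment: 60 bacterial + 40 fungal
    OTUs, a six-level taxon-loss gradient with eight replicates per level and
    ten for the sterile control (n = 50 samples), ten ecosystem functions.

    ``retention_fractions`` must be strictly decreasing (nested taxon loss);
    the sterile level keeps a small positive fraction so downstream indices
    stay defined.  ``dropout`` is the per-replicate probability that a
    level-retained taxon goes undetected in a given sample, the free
    within-treatment richness-variance knob.
    """

    n_bacteria: int = 60
    n_fungi: int = 40
    n_levels: int = 6
    reps_per_level: int = 8
    sterile_reps: int = 10
    graph_density: float = 0.02
    retention_fractions: tuple = DEFAULT_RETENTION
    n_functions: int = 10
    supporters_per_function: int = 6
    effect_size: float = 1.0
    noise_sd: float = 0.5
    sequencing_depth: int = 5000
    seed: int = 0
    # association-graph shape
    edge_strength: float = 0.35        # target |partial correlation| per edge
    positive_edge_fraction: float = 0.7
    # abundance heterogeneity and detection noise
    base_log_abundance_sd: float = 1.0
    latent_scale: float = 1.0
    dropout: float = 0.05
    supporter_positive_fraction: float = 0.8
    supporter_pool_level: int = 3      # supporters drawn from taxa retained here

    def __post_init__(self):
        counts = {
            "n_bacteria": self.n_bacteria,
            "n_fungi": self.n_fungi,
            "n_levels": self.n_levels,
            "reps_per_level": self.reps_per_level,
            "sterile_reps": self.sterile_reps,
            "n_functions": self.n_functions,
            "supporters_per_function": self.supporters_per_function,
            "sequencing_depth": self.sequencing_depth,
        }
        for name, v in counts.items():
            if int(v) != v or v < 1:
                raise ValueError(f"{name} must be a count >= 1, got {v!r}")
        if not (0.0 <= self.graph_density < 1.0):
            raise ValueError("graph_density must lie in [0, 1)")
        rf = tuple(self.retention_fractions)
        if len(rf) != self.n_levels:
            raise ValueError("retention_fractions must have n_levels entries")
        if any(b >= a for a, b in zip(rf, rf[1:])):
            raise ValueError("retention_fractions must be strictly decreasing")
        if any(not (0.0 < f <= 1.0) for f in rf):
            raise ValueError("retention_fractions must lie in (0, 1]")
        if self.noise_sd < 0 or self.effect_size < 0:
            raise ValueError("effect_size and noise_sd must be non-negative")
        if not (1 <= self.supporter_pool_level <= self.n_levels):
            raise ValueError("supporter_pool_level out of range")
        self.retention_fractions = rf

    @property
    def n_otus(self) -> int:
        return self.n_bacteria + self.n_fungi

    @property
    def n_samples(self) -> int:
        return (self.n_levels - 1) * self.reps_per_level + self.sterile_reps

    def otu_ids(self) -> pd.Index:
        return pd.Index(
            [f"b_{i + 1:04d}" for i in range(self.n_bacteria)]
            + [f"f_{i + 1:04d}" for i in range(self.n_fungi)]
        )


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generator."""

    true_edges: set
    precision: pd.DataFrame | None = None
    level_masks: pd.DataFrame | None = None     # levels x OTUs, nested
    presence_mask: pd.DataFrame | None = None   # samples x OTUs
    supporter_sets: dict = field(default_factory=dict)   # function -> {otu: +/-1}
    effect_weights: dict = field(default_factory=dict)   # function -> {otu: weight}

    def edge_array(self, otu_ids) -> np.ndarray:
        """Boolean adjacency matrix of the planted graph over ``otu_ids``."""
        idx = {o: i for i, o in enumerate(otu_ids)}
        p = len(idx)
        adj = np.zeros((p, p), dtype=bool)
        for a, b in self.true_edges:
            if a in idx and b in idx:
                adj[idx[a], idx[b]] = adj[idx[b], idx[a]] = True
        return adj


def _rng_for(config: SyntheticConfig, stage: int) -> np.random.Generator:
    """Independent, order-insensitive generator for each pipeline stage."""
    children = np.random.SeedSequence(config.seed).spawn(4)
    return np.random.default_rng(children[stage])


def generate_true_graph(config: SyntheticConfig) -> SyntheticTruth:
    """Plant a sparse association graph and a matching precision matrix.

    Edges receive off-diagonal precision entries of magnitude
    ``edge_strength`` (negative entries yield positive partial correlations).
    The matrix is made positive definite by diagonal loading; if the loading
    required would crush the planted partial correlations below 0.02 the
    density is too high for the dimension and a ``ValueError`` is raised.
    """
    rng = _rng_for(config, 0)
    ids = config.otu_ids()
    p = config.n_otus
    n_pairs = p * (p - 1) // 2
    n_edges = int(round(config.graph_density * n_pairs))
    iu, ju = np.triu_indices(p, k=1)
    chosen = rng.choice(n_pairs, size=n_edges, replace=False) if n_edges else []
    omega = np.eye(p)
    edges = set()
    for e in chosen:
        i, j = int(iu[e]), int(ju[e])
        sign = 1.0 if rng.random() < config.positive_edge_fraction else -1.0
        # negative precision entry <=> positive partial correlation
        omega[i, j] = omega[j, i] = -sign * config.edge_strength
        edges.add((ids[i], ids[j]))
    min_eig = float(np.linalg.eigvalsh(omega)[0])
    if min_eig < 0.05:
        load = 0.05 - min_eig
        omega[np.diag_indices(p)] += load
        # renormalize to unit diagonal; shrinks planted partial correlations
        omega /= 1.0 + load
        if n_edges and config.edge_strength / (1.0 + load) < 0.02:
            raise ValueError(
                "graph density too high for this dimension: diagonal loading "
                "would shrink planted partial correlations below 0.02"
            )
    prec = pd.DataFrame(omega, index=ids, columns=ids)
    return SyntheticTruth(true_edges=edges, precision=prec)


def _generate_presence(config: SyntheticConfig, truth: SyntheticTruth) -> None:
    """Nested level masks plus per-replicate dropout; fills ``truth`` in place
    and attaches ``level_masks`` and ``presence_mask``."""
    rng = _rng_for(config, 1)
    ids = config.otu_ids()
    p = config.n_otus
    order = rng.permutation(p)
    level_masks = np.zeros((config.n_levels, p), dtype=bool)
    for lv, frac in enumerate(config.retention_fractions):
        keep = max(1, int(np.ceil(frac * p)))
        level_masks[lv, order[:keep]] = True
    sample_ids, presence, meta_rows = [], [], []
    for lv in range(config.n_levels):
        sterile = lv == config.n_levels - 1
        reps = config.sterile_reps if sterile else config.reps_per_level
        treatment = "sterile" if sterile else f"L{lv + 1}"
        for r in range(reps):
            mask = level_masks[lv].copy()
            drop = rng.random(p) < config.dropout
            mask &= ~drop
            if not mask.any():  # keep at least one level-retained taxon
                mask[order[0]] = True
            sid = f"{treatment}_r{r + 1:02d}"
            sample_ids.append(sid)
            presence.append(mask)
            meta_rows.append(
                {"treatment": treatment, "level": lv + 1, "replicate": r + 1,
                 "block": r + 1}
            )
    truth.level_masks = pd.DataFrame(
        level_masks, index=pd.RangeIndex(1, config.n_levels + 1, name="level"),
        columns=ids,
    )
    truth.presence_mask = pd.DataFrame(
        np.asarray(presence), index=pd.Index(sample_ids, name="sample"),
        columns=ids,
    )
    truth._sample_meta = pd.DataFrame(
        meta_rows, index=truth.presence_mask.index
    )


def generate_counts(truth: SyntheticTruth, config: SyntheticConfig) -> OtuTable:
    """Draw sequencing counts from the latent Gaussian-copula model.

    Latent log-abundances are multivariate normal with the covariance implied
    by the planted precision matrix; taxa masked out of a sample are removed
    before the logistic-normal multinomial draw, so every row of counts sums
    to ``sequencing_depth`` over the present taxa.
    """
    if config.sequencing_depth < 1:
        raise ValueError("sequencing_depth must be positive")
    if truth.precision is None:
        raise ValueError("truth lacks a precision matrix; run generate_true_graph")
    if truth.presence_mask is None:
        _generate_presence(config, truth)
    rng = _rng_for(config, 2)
    ids = config.otu_ids()
    p = config.n_otus
    cov = np.linalg.inv(truth.precision.to_numpy())
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(p))
    mu = rng.normal(0.0, config.base_log_abundance_sd, size=p)
    n = truth.presence_mask.shape[0]
    z = rng.standard_normal((n, p)) @ chol.T
    loglam = mu + config.latent_scale * z
    counts = np.zeros((n, p), dtype=np.int64)
    mask = truth.presence_mask.to_numpy()
    for s in range(n):
        m = mask[s]
        if not m.any():
            warnings.warn(f"sample {truth.presence_mask.index[s]} has no taxa "
                          "present; counts row is all zero")
            continue
        logits = loglam[s, m]
        prob = np.exp(logits - logits.max())
        prob /= prob.sum()
        counts[s, m] = rng.multinomial(config.sequencing_depth, prob)
    table = pd.DataFrame(counts, index=truth.presence_mask.index, columns=ids)
    return OtuTable(table, sample_meta=truth._sample_meta.copy())


def generate_functions(
    truth: SyntheticTruth, otu_table: OtuTable, config: SyntheticConfig
) -> FunctionTable:
    """Generate ecosystem functions as noisy weighted sums of standardized
    supporter-taxon relative abundances.

    Supporters are drawn from taxa retained at ``supporter_pool_level`` of
    the gradient (detectable across most of the design).  Per-taxon weights
    are proportional to Uniform(0.5, 1.5) draws with random signs and are
    normalized so the planted signal has total standard deviation
    ``effect_size`` (so at the defaults effect_size=1, noise_sd=0.5 an
    oracle regression on the true supporters attains R^2 of about 0.8).
    Weights are defined on the direction-adjusted scale — positive weight
    means the taxon supports functioning — and loss-type functions store the
    negated raw value, mirroring measurements where high leaching / N2O is
    bad.
    """
    rng = _rng_for(config, 3)
    if truth.level_masks is None:
        raise ValueError("truth lacks presence structure; run generate_counts first")
    names = list(FUNCTION_NAMES[: config.n_functions])
    if config.n_functions > len(FUNCTION_NAMES):
        names += [f"function_{k}" for k in range(len(FUNCTION_NAMES) + 1,
                                                 config.n_functions + 1)]
    direction = pd.Series(
        {nm: (LOSS if nm in LOSS_FUNCTIONS else BENEFIT) for nm in names}
    )
    pool = truth.level_masks.columns[
        truth.level_masks.loc[config.supporter_pool_level].to_numpy()
    ]
    k = min(config.supporters_per_function, len(pool))
    ab = otu_table.abundance.to_numpy(dtype=float)
    rowsum = ab.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0] = 1.0
    prop = pd.DataFrame(ab / rowsum, index=otu_table.sample_ids,
                        columns=otu_table.otu_ids)
    values = {}
    for nm in names:
        picked = rng.choice(len(pool), size=k, replace=False)
        otus = [pool[i] for i in picked]
        signs = np.where(rng.random(k) < config.supporter_positive_fraction,
                         1.0, -1.0)
        mags = rng.uniform(0.5, 1.5, size=k)
        norm = np.linalg.norm(mags)
        weights = signs * mags * (config.effect_size / norm if norm > 0 else 0.0)
        y = rng.normal(0.0, config.noise_sd, size=otu_table.n_samples)
        wmap, smap = {}, {}
        for otu, w in zip(otus, weights):
            col = prop[otu].to_numpy()
            sd = col.std(ddof=1)
            if w == 0.0:
                continue
            if sd > 0:
                y = y + w * (col - col.mean()) / sd
            wmap[otu] = float(w)
            smap[otu] = 1 if w > 0 else -1
        truth.effect_weights[nm] = wmap
        truth.supporter_sets[nm] = smap
        values[nm] = y if direction[nm] == BENEFIT else -y
    frame = pd.DataFrame(values, index=otu_table.sample_ids)[names]
    return FunctionTable(frame, direction)


def sample_latent(truth: SyntheticTruth, n: int, seed: int = 0) -> pd.DataFrame:
    """Draw ``n`` multivariate-normal samples from the planted association
    model (correlation implied by the precision matrix), without taxon-loss
    masking or compositional count noise.  The clean-data setting for
    scoring graph-estimator recovery."""
    if truth.precision is None:
        raise ValueError("truth lacks a precision matrix")
    rng = np.random.default_rng(seed)
    prec = truth.precision.to_numpy()
    p = prec.shape[0]
    cov = np.linalg.inv(prec)
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(p))
    z = rng.standard_normal((n, p)) @ chol.T
    return pd.DataFrame(z, columns=truth.precision.columns)


def generate_dataset(config: SyntheticConfig):
    """Full synthetic study: returns ``(otu_table, function_table, truth)``."""
    truth = generate_true_graph(config)
    otu_table = generate_counts(truth, config)
    functions = generate_functions(truth, otu_table, config)
    return otu_table, functions, truth


__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_true_graph",
    "generate_counts",
    "generate_functions",
    "generate_dataset",
    "FUNCTION_NAMES",
    "LOSS_FUNCTIONS",
    "DEFAULT_RETENTION",
]
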