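"""End-to-end pipeline: simulate (or load) -> preprocess -> network ->
support -> indices -> analyze.

Every stage writes its outputs as TSV/JSON into the output directory and a
``manifest.json`` records package and library versions, seeds, parameters
and input digests, so a run is reproducible from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import FunctionTable, OtuTable
from .indices import sample_indices
from .io import (
    read_function_table,
    read_otu_table,
    write_function_table,
    write_network,
    write_otu_table,
    write_support_map,
    write_truth,
)
from .multifunctionality import MultifunctionalityModel
from .network import MetaNetworkModel, NetworkConfig
from .preprocessing import FilterConfig, preprocess
from .stats import detrended_regress, regress, sequential_anova
from .subnetworks import PAIRINGS
from .support import ElasticNetConfig, FunctionSupportModel
from .synthetic import SyntheticConfig, generate_dataset

log = logging.getLogger("micronetfun")

_TABLE1_CHARACTERISTICS = {
    "complexity": "density",
    "functional_complexity": "functional_complexity",
}
_PAIRING_LABELS = {"bb": "Bact-Bact", "ff": "Fungi-Fungi", "bf": "Bact-Fungi",
                   "all": "Among all"}


@dataclass
class PipelineConfig:
    """Everything a run needs; nested stage configs plus file plumbing.

    When ``otu_path`` is unset the synthetic generator provides the data.
    ``seed`` re-seeds every stochastic stage (simulation, StARS subsampling,
    selection) deterministically.
    """

    out_dir: str = "micronetfun_out"
    seed: int = 0
    otu_path: str | None = None
    function_path: str | None = None
    direction_path: str | None = None
    metadata_path: str | None = None
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    elastic_net: ElasticNetConfig = field(default_factory=ElasticNetConfig)
    log_level: str = "INFO"

    def __post_init__(self):
        self.synthetic = _coerce(self.synthetic, SyntheticConfig)
        self.filter = _coerce(self.filter, FilterConfig)
        self.network = _coerce(self.network, NetworkConfig)
        self.elastic_net = _coerce(self.elastic_net, ElasticNetConfig)
        # one seed drives every stochastic stage
        self.synthetic.seed = int(self.seed)
        self.network.seed = (int(self.seed) + 1) % (2**31)
        self.elastic_net.seed = (int(self.seed) + 2) % (2**31)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _coerce(value, cls):
    if isinstance(value, cls):
        return value
    return cls(**(value or {}))


@dataclass
class PipelineResults:
    """All stage outputs of one run."""

    config: PipelineConfig
    otu_raw: OtuTable
    otu_filtered: OtuTable          # proportion scale, filtered
    otu_standardized: OtuTable
    functions: FunctionTable
    network: object                 # MetaNetworkResults
    support: object                 # SupportResults
    indices: pd.DataFrame
    multifunctionality: object      # MultifunctionalityResults
    table1: pd.DataFrame
    table2: dict
    truth: object | None = None
    manifest: dict | None = None


def _digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def analyze_indices(indices: pd.DataFrame, multifun: pd.Series):
    """Table-1-style surface: SES/SE/P/R2 of multifunctionality on each
    network characteristic (4 pairings x {complexity, functional
    complexity}), plain and after detrending both variables for combined
    richness."""
    rows = []
    rich = indices["richness_combined"].to_numpy()
    y = multifun.to_numpy()
    for char, stem in _TABLE1_CHARACTERISTICS.items():
        for pairing in PAIRINGS:
            x = indices[f"{stem}_{pairing}"].to_numpy()
            if np.std(x) == 0:
                continue
            plain = regress(y, x)
            det = detrended_regress(y, x, rich)
            for variant, res in (("plain", plain), ("detrended", det)):
                rows.append(
                    {
                        "characteristic": char,
                        "pairing": _PAIRING_LABELS[pairing],
                        "variant": variant,
                        "SES": res.SES,
                        "SE": res.SE,
                        "P": res.P,
                        "R2": res.R2,
                    }
                )
    return pd.DataFrame(rows)


def analyze_variance_partition(indices: pd.DataFrame, multifun: pd.Series):
    """Table-2-style sequential (Type-I) ANOVA: richness, average number of
    supporting taxa, uniqueness, functional complexity, then the treatment
    factor, for bacteria-only / fungi-only / combined characteristics."""
    out = {}
    variants = {
        "bacteria": ("richness_bacteria", "functional_complexity_bb"),
        "fungi": ("richness_fungi", "functional_complexity_ff"),
        "both": ("richness_combined", "functional_complexity_all"),
    }
    for name, (rich_col, fc_col) in variants.items():
        terms = pd.DataFrame(
            {
                "richness": indices[rich_col],
                "avg_supporters": indices["avg_supporters"],
                "uniqueness": indices["uniqueness"],
                "functional_complexity": indices[fc_col],
            }
        )
        out[name] = sequential_anova(
            multifun.to_numpy(),
            terms,
            treatment=indices["treatment"] if "treatment" in indices else None,
            block=indices["block"] if "block" in indices else None,
        )
    return out


def run_pipeline(config: PipelineConfig) -> PipelineResults:
    """Execute all stages in order, writing intermediates and a manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "micronetfun",
        "version": __version__,
        "seed": config.seed,
        "parameters": config.to_dict(),
        "inputs": {},
        "stages": [],
    }
    for lib in ("numpy", "pandas", "sklearn", "statsmodels", "networkx"):
        mod = __import__(lib)
        manifest.setdefault("library_versions", {})[lib] = mod.__version__

    truth = None
    if config.otu_path is None:
        log.info("simulate: %d OTUs, %d samples, seed %d",
                 config.synthetic.n_otus, config.synthetic.n_samples,
                 config.seed)
        otu_raw, functions, truth = generate_dataset(config.synthetic)
        write_otu_table(otu_raw, out / "otu_counts.tsv", out / "metadata.tsv")
        write_function_table(functions, out / "functions.tsv",
                             out / "function_directions.tsv")
        write_truth(truth, out / "truth.json")
        manifest["stages"].append("simulate")
    else:
        for key, p in (("otu", config.otu_path),
                       ("functions", config.function_path),
                       ("metadata", config.metadata_path)):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{key} table not found: {p}")
        if config.function_path is None:
            raise ValueError("function_path is required with otu_path")
        otu_raw = read_otu_table(config.otu_path, meta_path=config.metadata_path)
        functions = read_function_table(config.function_path,
                                        config.direction_path)
        missing = otu_raw.sample_ids.difference(functions.values.index)
        if len(missing):
            raise ValueError(
                f"samples missing from the function table: {missing.tolist()}")
        functions = FunctionTable(
            functions.values.reindex(otu_raw.sample_ids), functions.direction)
        for key, p in (("otu", config.otu_path),
                       ("functions", config.function_path),
                       ("metadata", config.metadata_path),
                       ("directions", config.direction_path)):
            if p is not None:
                manifest["inputs"][key] = _digest(p)
        manifest["stages"].append("load")

    log.info("preprocess: mean-abundance >= %g, prevalence >= %d",
             config.filter.mean_abundance_threshold,
             config.filter.min_prevalence)
    props, report = preprocess(
        otu_raw, FilterConfig(config.filter.mean_abundance_threshold,
                              config.filter.min_prevalence, standardize=False))
    from .preprocessing import standardize as _std

    standardized = _std(props)
    props = props.select_otus(standardized.otu_ids)
    report.to_csv(out / "filter_report.tsv", sep="\t", index_label="otu_id")
    write_otu_table(props, out / "otu_filtered.tsv")
    write_otu_table(standardized, out / "otu_standardized.tsv")
    manifest["stages"].append("preprocess")

    log.info("network: p=%d, %d lambdas, %d subsamples",
             standardized.n_otus, config.network.n_lambda,
             config.network.n_subsamples)
    net = MetaNetworkModel(standardized, config.network).fit()
    write_network(net, out / "network_edges.tsv", out / "network.graphml",
                  out / "network_instability.tsv")
    manifest["stages"].append("network")

    log.info("support: %d functions, alpha grid step %g",
             functions.n_functions, config.elastic_net.alpha_step)
    support = FunctionSupportModel(standardized, functions,
                                   config.elastic_net).fit()
    write_support_map(support.support_map, out / "support_map.tsv",
                      out / "support_map.json")
    support.cv_table.to_csv(out / "support_cv.tsv", sep="\t")
    manifest["stages"].append("support")

    log.info("indices")
    idx = sample_indices(net, props, support.support_map)
    idx.to_csv(out / "sample_indices.tsv", sep="\t", index_label="sample")
    manifest["stages"].append("indices")

    log.info("analyze")
    mf = MultifunctionalityModel(functions).fit()
    mf.to_frame().to_csv(out / "multifunctionality.tsv", sep="\t",
                         index_label="sample")
    table1 = analyze_indices(idx, mf.multidimensional_index)
    table1.to_csv(out / "table1_regressions.tsv", sep="\t", index=False)
    table2 = analyze_variance_partition(idx, mf.multidimensional_index)
    t2_frames = []
    for name, aov in table2.items():
        frame = aov.table.copy()
        frame.insert(0, "variant", name)
        t2_frames.append(frame)
    pd.concat(t2_frames).to_csv(out / "table2_anova.tsv", sep="\t",
                                index_label="term")
    manifest["stages"].append("analyze")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return PipelineResults(
        config=config,
        otu_raw=otu_raw,
        otu_filtered=props,
        otu_standardized=standardized,
        functions=functions,
        network=net,
        support=support,
        indices=idx,
        multifunctionality=mf,
        table1=table1,
        table2=table2,
        truth=truth,
        manifest=manifest,
    )


__all__ = ["PipelineConfig", "PipelineResults", "run_pipeline",
           "analyze_indices", "analyze_variance_partition"]
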