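"""In-memory containers shared across the pipeline stages.

Abundance matrices are pandas DataFrames with samples in rows and OTUs in
columns; OTU identifiers carry a kingdom prefix (``b_`` for bacterial 16S
OTUs, ``f_`` for fungal ITS OTUs) unless an explicit kingdom mapping is
supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BACTERIA = "bacteria"
FUNGI = "fungi"

#: functions whose high values indicate nutrient loss / dysfunction; they are
#: sign-inverted before any multifunctionality or support calculation
LOSS = "loss"
BENEFIT = "benefit"


def kingdom_from_ids(otu_ids) -> pd.Series:
    """Infer kingdom labels from ``b_`` / ``f_`` id prefixes."""
    out = {}
    for oid in otu_ids:
        if str(oid).startswith("b_"):
            out[oid] = BACTERIA
        elif str(oid).startswith("f_"):
            out[oid] = FUNGI
        else:
            raise ValueError(
                f"cannot infer kingdom for OTU id {oid!r}: expected a 'b_' or "
                "'f_' prefix or an explicit kingdom mapping"
            )
    return pd.Series(out, name="kingdom")


@dataclass
class OtuTable:
    """Samples x OTUs abundance matrix with kingdom labels and metadata.

    Parameters
    ----------
    abundance : DataFrame
        Non-negative counts or proportions, samples in rows.
    kingdom : Series, optional
        Per-OTU label in {"bacteria", "fungi"}; inferred from id prefixes
        when omitted.
    sample_meta : DataFrame, optional
        Per-sample metadata (treatment level, replicate, block), indexed like
        ``abundance``.
    """

    abundance: pd.DataFrame
    kingdom: pd.Series | None = None
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self):
        ab = self.abundance
        if ab.columns.duplicated().any():
            dups = ab.columns[ab.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate OTU ids: {dups}")
        if self.kingdom is None:
            self.kingdom = kingdom_from_ids(ab.columns)
        else:
            self.kingdom = pd.Series(self.kingdom).reindex(ab.columns)
            if self.kingdom.isna().any():
                missing = self.kingdom.index[self.kingdom.isna()].tolist()
                raise ValueError(f"kingdom undefined for OTUs: {missing}")
            bad = set(self.kingdom.unique()) - {BACTERIA, FUNGI}
            if bad:
                raise ValueError(f"unknown kingdom labels: {sorted(bad)}")
        if self.sample_meta is not None:
            self.sample_meta = self.sample_meta.reindex(ab.index)

    # ------------------------------------------------------------------
    @property
    def otu_ids(self) -> pd.Index:
        return self.abundance.columns

    @property
    def sample_ids(self) -> pd.Index:
        return self.abundance.index

    @property
    def n_samples(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_otus(self) -> int:
        return self.abundance.shape[1]

    def values(self) -> np.ndarray:
        return self.abundance.to_numpy(dtype=float)

    def presence(self) -> pd.DataFrame:
        """Boolean samples x OTUs detection matrix (abundance > 0)."""
        return self.abundance > 0

    def select_otus(self, otu_ids) -> "OtuTable":
        return OtuTable(
            self.abundance.loc[:, otu_ids],
            kingdom=self.kingdom.loc[otu_ids],
            sample_meta=self.sample_meta,
        )

    def with_abundance(self, abundance: pd.DataFrame) -> "OtuTable":
        return OtuTable(
            abundance,
            kingdom=self.kingdom.loc[abundance.columns],
            sample_meta=self.sample_meta,
        )

    def copy(self) -> "OtuTable":
        return OtuTable(
            self.abundance.copy(),
            kingdom=self.kingdom.copy(),
            sample_meta=None if self.sample_meta is None else self.sample_meta.copy(),
        )


@dataclass
class FunctionTable:
    """Samples x ecosystem-function measurements with direction flags.

    ``direction`` maps each function name to "benefit" (higher is better) or
    "loss" (higher values indicate nutrient losses / dysfunction, e.g. N and
    P leaching and N2O emission; these are sign-inverted before analysis).
    """

    values: pd.DataFrame
    direction: pd.Series

    def __post_init__(self):
        self.direction = pd.Series(self.direction).reindex(self.values.columns)
        if self.direction.isna().any():
            missing = self.direction.index[self.direction.isna()].tolist()
            raise ValueError(f"direction undefined for functions: {missing}")
        bad = set(self.direction.unique()) - {BENEFIT, LOSS}
        if bad:
            raise ValueError(f"unknown direction flags: {sorted(bad)}")

    @property
    def names(self) -> pd.Index:
        return self.values.columns

    @property
    def n_functions(self) -> int:
        return self.values.shape[1]

    def adjusted(self) -> pd.DataFrame:
        """Direction-adjusted values: loss-type functions negated so that
        larger always means better functioning."""
        sign = self.direction.map({BENEFIT: 1.0, LOSS: -1.0})
        return self.values * sign

    def copy(self) -> "FunctionTable":
        return FunctionTable(self.values.copy(), self.direction.copy())


@dataclass
class SupportEntry:
    """Selected taxa for one ecosystem function.

    Coefficients are on the direction-adjusted scale: positive means the
    taxon's abundance predicts improved functioning ("supporting"), negative
    the opposite ("inhibiting").
    """

    function: str
    coefficients: pd.Series
    alpha: float
    lam: float
    cv_mse: float

    @property
    def supporting(self) -> list:
        return self.coefficients.index[self.coefficients > 0].tolist()

    @property
    def inhibiting(self) -> list:
        return self.coefficients.index[self.coefficients < 0].tolist()

    @property
    def selected(self) -> list:
        return self.coefficients.index[self.coefficients != 0].tolist()


@dataclass
class SupportMap:
    """Per-function signed sets of selected OTUs (the "support map")."""

    entries: dict = field(default_factory=dict)

    def __getitem__(self, function: str) -> SupportEntry:
        return self.entries[function]

    def __iter__(self):
        return iter(self.entries.values())

    def __len__(self):
        return len(self.entries)

    @property
    def functions(self) -> list:
        return list(self.entries)

    def supporter_sets(self) -> dict:
        return {f: set(e.supporting) for f, e in self.entries.items()}

    def support_profiles(self, otu_ids) -> pd.DataFrame:
        """Binary OTUs x functions matrix: 1 where the OTU supports the
        function."""
        prof = pd.DataFrame(
            0, index=pd.Index(otu_ids), columns=pd.Index(self.functions), dtype=int
        )
        for f, e in self.entries.items():
            hit = [o for o in e.supporting if o in prof.index]
            prof.loc[hit, f] = 1
        return prof

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f, e in self.entries.items():
            for otu, coef in e.coefficients[e.coefficients != 0].items():
                rows.append(
                    {
                        "function": f,
                        "otu_id": otu,
                        "coefficient": coef,
                        "role": "support" if coef > 0 else "inhibit",
                        "alpha": e.alpha,
                        "lambda": e.lam,
                        "cv_mse": e.cv_mse,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "function", "otu_id", "coefficient", "role",
                "alpha", "lambda", "cv_mse",
            ],
        )


__all__ = [
    "OtuTable",
    "FunctionTable",
    "SupportEntry",
    "SupportMap",
    "kingdom_from_ids",
    "BACTERIA",
    "FUNGI",
    "BENEFIT",
    "LOSS",
]
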