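"""Feature schema: which observation columns feed the error model and how.

Numeric features are standardized with frozen training-set statistics,
categorical features are one-hot encoded against a frozen level list, and the
trinucleotide context is looked up in a 64-entry vocabulary and embedded by
the network itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

TRINUCLEOTIDES: tuple[str, ...] = tuple(
    "".join(p) for p in product("ACGT", repeat=3))
TNC_INDEX: dict[str, int] = {t: i for i, t in enumerate(TRINUCLEOTIDES)}

#: the eight features retained by stepwise selection on the clinical data;
#: seven read-level plus the trinucleotide context
DEFAULT_NUMERIC = ["read_position", "fragment_size", "seq_length",
                   "umi_group_size", "n_other_errors"]
DEFAULT_CATEGORICAL = ["strand", "first_in_pair"]

#: the full 14-feature set (adds UMI disagreement counts, indel counts and
#: the 11-bp window summaries)
FULL_NUMERIC = DEFAULT_NUMERIC + ["umi_errors", "n_insertions", "n_deletions",
                                  "gc_content", "entropy_1mer", "entropy_2mer"]
FULL_CATEGORICAL = DEFAULT_CATEGORICAL


class SchemaError(ValueError):
    pass


@dataclass
class FeatureSchema:
    numeric: list[str]
    numeric_stats: dict[str, tuple[float, float]]  # name -> (mean, sd)
    categorical: dict[str, list]  # name -> ordered levels
    embed_trinucleotide: bool = True
    embed_dim: int = 3

    def __post_init__(self):
        names = list(self.numeric) + list(self.categorical)
        if self.embed_trinucleotide:
            names.append("trinucleotide")
        if len(set(names)) != len(names):
            raise SchemaError("a feature appears in two groups")
        if not names:
            raise SchemaError("empty schema")

    @property
    def feature_names(self) -> list[str]:
        out = list(self.numeric) + list(self.categorical)
        if self.embed_trinucleotide:
            out.append("trinucleotide")
        return out

    @property
    def dense_width(self) -> int:
        return len(self.numeric) + sum(len(v) for v in self.categorical.values())

    @property
    def input_width(self) -> int:
        return self.dense_width + (self.embed_dim if self.embed_trinucleotide else 0)

    @classmethod
    def from_table(cls, df: pd.DataFrame,
                   numeric: list[str] | None = None,
                   categorical: list[str] | None = None,
                   embed_trinucleotide: bool = True,
                   embed_dim: int = 3) -> "FeatureSchema":
        """Freeze normalization statistics and category levels from data."""
        numeric = DEFAULT_NUMERIC if numeric is None else list(numeric)
        categorical = DEFAULT_CATEGORICAL if categorical is None else list(categorical)
        stats = {}
        for name in numeric:
            col = df[name].to_numpy(dtype=float)
            sd = float(col.std())
            stats[name] = (float(col.mean()), sd if sd > 0 else 1.0)
        levels = {name: sorted(df[name].unique().tolist())
                  for name in categorical}
        return cls(numeric=numeric, numeric_stats=stats, categorical=levels,
                   embed_trinucleotide=embed_trinucleotide, embed_dim=embed_dim)

    def encode(self, df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray | None]:
        """Return (dense design matrix, trinucleotide indices or None)."""
        n = len(df)
        cols = []
        for name in self.numeric:
            mean, sd = self.numeric_stats[name]
            cols.append((df[name].to_numpy(dtype=float) - mean) / sd)
        for name, levels in self.categorical.items():
            vals = df[name].to_numpy()
            for lev in levels:
                cols.append((vals == lev).astype(float))
        dense = (np.column_stack(cols) if cols
                 else np.empty((n, 0), dtype=float))
        tnc = None
        if self.embed_trinucleotide:
            tnc = df["trinucleotide"].map(TNC_INDEX).to_numpy()
            if np.any(pd.isna(tnc)):
                raise SchemaError("trinucleotide outside the ACGT 3-mer vocabulary")
            tnc = tnc.astype(np.int64)
        return dense, tnc

    def drop(self, feature: str) -> "FeatureSchema":
        """Schema without one feature.

        Dropping the trinucleotide context substitutes the central reference
        base as a plain categorical feature, so only the neighbour
        information is removed.
        """
        if feature == "trinucleotide":
            if not self.embed_trinucleotide:
                raise SchemaError("trinucleotide not in schema")
            cats = dict(self.categorical)
            cats["ref_base"] = ["A", "C", "G", "T"]
            return FeatureSchema(numeric=list(self.numeric),
                                 numeric_stats=dict(self.numeric_stats),
                                 categorical=cats,
                                 embed_trinucleotide=False,
                                 embed_dim=self.embed_dim)
        if feature in self.numeric:
            num = [f for f in self.numeric if f != feature]
            stats = {k: v for k, v in self.numeric_stats.items() if k != feature}
            return FeatureSchema(numeric=num, numeric_stats=stats,
                                 categorical=dict(self.categorical),
                                 embed_trinucleotide=self.embed_trinucleotide,
                                 embed_dim=self.embed_dim)
        if feature in self.categorical:
            cats = {k: v for k, v in self.categorical.items() if k != feature}
            return FeatureSchema(numeric=list(self.numeric),
                                 numeric_stats=dict(self.numeric_stats),
                                 categorical=cats,
                                 embed_trinucleotide=self.embed_trinucleotide,
                                 embed_dim=self.embed_dim)
        raise SchemaError(f"unknown feature {feature!r}")

    def to_dict(self) -> dict:
        return {
            "numeric": self.numeric,
            "numeric_stats": {k: list(v) for k, v in self.numeric_stats.items()},
            "categorical": self.categorical,
            "embed_trinucleotide": self.embed_trinucleotide,
            "embed_dim": self.embed_dim,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSchema":
        return cls(numeric=list(d["numeric"]),
                   numeric_stats={k: tuple(v) for k, v in d["numeric_stats"].items()},
                   categorical={k: list(v) for k, v in d["categorical"].items()},
                   embed_trinucleotide=bool(d["embed_trinucleotide"]),
                   embed_dim=int(d["embed_dim"]))


def prepare_design(df: pd.DataFrame, schema: FeatureSchema):
    """Encode a table, adding the derived ref_base column when required."""
    if "ref_base" in schema.categorical and "ref_base" not in df.columns:
        df = df.assign(ref_base=df["trinucleotide"].str[1])
    return schema.encode(df)
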