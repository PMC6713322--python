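"""In-memory container for per-fish tabular records.

A :class:`FishDataset` is an ordered table of individual fish, one row per
fish, carried as a :class:`pandas.DataFrame`.  Row order matters: the
reservoir consumes records as a sequence, so the stored order is the
presentation order during training and estimation.

Canonical columns (see :mod:`sgrnet.io` for the CSV contract):

========== =========================================================
column      meaning
========== =========================================================
id          record identifier (string)
species     species label
stage       growth-stage label (juvenile, post_smolt, adult, ...)
weight_g    body weight, grams
length_cm   fork/total length, centimetres (optional if cf present)
cf          condition factor, 100 * g * cm^-3
tc_ratio    trypsin/chymotrypsin activity ratio (dimensionless)
sgr         specific growth rate, % day^-1 (training/evaluation only)
sgr_true    noiseless ground-truth SGR (synthetic data only)
dataset     provenance label of the constituent dataset
========== =========================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["FishDataset", "FEATURES", "FEATURE_COLUMNS", "combine_datasets"]

#: Model-input feature names, in canonical order.
FEATURES: tuple[str, ...] = ("weight", "tc_ratio", "cf")

#: Mapping from feature name to dataframe column.
FEATURE_COLUMNS: dict[str, str] = {
    "weight": "weight_g",
    "tc_ratio": "tc_ratio",
    "cf": "cf",
}

_REQUIRED = ("weight_g", "tc_ratio", "cf")


@dataclass
class FishDataset:
    """Ordered collection of fish records with provenance metadata."""

    df: pd.DataFrame
    label: str = "unnamed"
    #: labels of constituent datasets, in concatenation order
    parts: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        missing = [c for c in _REQUIRED if c not in self.df.columns]
        if missing:
            raise ValidationError(f"dataset {self.label!r} lacks columns {missing}")
        self.df = self.df.reset_index(drop=True)
        if not self.parts:
            if "dataset" in self.df.columns:
                self.parts = tuple(pd.unique(self.df["dataset"]).astype(str))
            else:
                self.df = self.df.assign(dataset=self.label)
                self.parts = (self.label,)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n(self) -> int:
        return len(self.df)

    def has_sgr(self) -> bool:
        return "sgr" in self.df.columns and self.df["sgr"].notna().all()

    def feature_matrix(self, features: tuple[str, ...]) -> np.ndarray:
        """(n, M) array of the requested features, in the requested order."""
        cols = []
        for f in features:
            if f not in FEATURE_COLUMNS:
                raise ValidationError(f"unknown feature {f!r}")
            col = FEATURE_COLUMNS[f]
            if self.df[col].isna().any():
                bad = self.df.index[self.df[col].isna()].tolist()
                raise ValidationError(
                    f"dataset {self.label!r}: feature {f!r} missing in rows {bad}"
                )
            cols.append(self.df[col].to_numpy(dtype=float))
        return np.column_stack(cols)

    def sgr_values(self) -> np.ndarray:
        if "sgr" not in self.df.columns:
            raise ValidationError(f"dataset {self.label!r} carries no SGR column")
        s = self.df["sgr"]
        if s.isna().any():
            bad = self.df.index[s.isna()].tolist()
            raise ValidationError(f"dataset {self.label!r}: SGR missing in rows {bad}")
        return s.to_numpy(dtype=float)

    def take(self, indices: np.ndarray, label_suffix: str = "") -> "FishDataset":
        """Sub-dataset at the given positional indices (stored order kept)."""
        sub = self.df.iloc[np.asarray(indices, dtype=int)]
        return FishDataset(sub.copy(), label=self.label + label_suffix)


def combine_datasets(parts: list[FishDataset]) -> FishDataset:
    """Concatenate datasets in the given order, keeping provenance labels.

    All parts must share the model-input feature schema; a model trained on
    the combination normalizes with ranges spanning all parts.
    """
    if not parts:
        raise ValidationError("no datasets to combine")
    have_sgr = [("sgr" in p.df.columns) for p in parts]
    if any(have_sgr) and not all(have_sgr):
        raise ValidationError("cannot combine datasets with and without SGR")
    frames = [p.df for p in parts]
    labels: list[str] = []
    for p in parts:
        labels.extend(p.parts)
    combined = pd.concat(frames, ignore_index=True)
    label = "+".join(p.label for p in parts)
    return FishDataset(combined, label=label, parts=tuple(labels))
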