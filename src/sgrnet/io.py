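"""CSV ingestion, dataset writing, and model persistence.

Datasets travel as plain comma-separated UTF-8 files with a header and '.'
decimal separator.  Mandatory columns: ``weight_g``, ``tc_ratio``, and at
least one of ``length_cm`` / ``cf``; optional: ``id``, ``species``,
``stage``, ``sgr``, ``sgr_true``, ``dataset``.  When ``cf`` is absent it is
derived from weight and length; when both ``cf`` and ``length_cm`` are
present and disagree by more than 1% relative, the stored ``cf`` wins and a
warning is logged.

Models persist as a single self-describing JSON document with explicit
shape metadata and a format version.  JSON floats round-trip exactly
(shortest-repr encoding), and the writer is canonical (sorted keys, fixed
separators), so write -> read -> write is byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dataset import FishDataset
from .errors import ModelFileError, ValidationError
from .growth_metrics import FeatureRange, condition_factor
from .reservoir import ReservoirNetwork
from .training import InputSetDescriptor, NetConfig, TrainedModel

__all__ = ["read_dataset", "write_dataset", "write_model", "read_model",
           "model_to_json", "MODEL_FORMAT_VERSION"]

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1

_NUMERIC = ("weight_g", "length_cm", "cf", "tc_ratio", "sgr", "sgr_true")
_POSITIVE = ("weight_g", "length_cm", "cf", "tc_ratio")


def read_dataset(path: str | Path, label: str | None = None) -> FishDataset:
    """Read and validate a fish-record CSV; row order becomes stored order."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"id": str}, float_precision="round_trip")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValidationError(f"cannot read {path}: {exc}") from exc
    if "weight_g" not in df.columns or "tc_ratio" not in df.columns:
        raise ValidationError(
            f"{path}: missing mandatory column(s) "
            f"{[c for c in ('weight_g', 'tc_ratio') if c not in df.columns]}"
        )
    if "cf" not in df.columns and "length_cm" not in df.columns:
        raise ValidationError(f"{path}: need at least one of 'cf', 'length_cm'")

    for col in _NUMERIC:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ValidationError(
                f"{path}: non-numeric value in column {col!r}, row(s) "
                f"{[int(i) + 2 for i in bad]}"  # +2: header line and 1-based rows
            )
        df[col] = coerced

    for col in _POSITIVE:
        if col not in df.columns:
            continue
        vals = df[col]
        bad = vals.notna() & (vals <= 0)
        if bad.any():
            rows = [int(i) + 2 for i in df.index[bad]]
            raise ValidationError(
                f"{path}: non-positive value in column {col!r}, row(s) {rows}"
            )

    # derive CF from weight and length where absent; cross-check where both given
    if "cf" not in df.columns:
        df["cf"] = np.nan
    if "length_cm" in df.columns:
        needs_cf = df["cf"].isna() & df["length_cm"].notna()
        if needs_cf.any():
            df.loc[needs_cf, "cf"] = [
                condition_factor(w, l)
                for w, l in zip(df.loc[needs_cf, "weight_g"],
                                df.loc[needs_cf, "length_cm"])
            ]
        both = df["cf"].notna() & df["length_cm"].notna() & ~needs_cf
        if both.any():
            derived = 100.0 * df.loc[both, "weight_g"] / df.loc[both, "length_cm"] ** 3
            rel = np.abs(derived - df.loc[both, "cf"]) / np.abs(df.loc[both, "cf"])
            off = rel > 0.01
            if off.any():
                logger.warning(
                    "%s: stored cf and weight/length disagree by >1%% in %d row(s); "
                    "keeping the stored cf", path, int(off.sum()),
                )
    if df["cf"].isna().any():
        bad = df.index[df["cf"].isna()]
        raise ValidationError(
            f"{path}: cannot determine cf in row(s) {[int(i) + 2 for i in bad]}"
        )
    return FishDataset(df, label=label or path.stem)


def write_dataset(data: FishDataset, path: str | Path) -> None:
    """Write a dataset as CSV with full float precision (repr round-trip)."""
    data.df.to_csv(path, index=False)


def _range_to_dict(r: FeatureRange) -> dict:
    return {"name": r.name, "min": r.min, "max": r.max}


def model_to_json(model: TrainedModel) -> str:
    """Canonical JSON text of a trained model (used for persistence and
    byte-level equality checks)."""
    net = model.network
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "package_version": __version__,
        "network": {
            "n": net.n,
            "m": net.m,
            "lam": net.lam,
            "b0": net.b0,
            "seed": net.seed,
            "spectral_radius": net.spectral_radius,
            "sparsity": net.sparsity,
            "w_in": {"shape": list(net.w_in.shape),
                     "data": net.w_in.ravel().tolist()},
            "w_sys": {"shape": list(net.w_sys.shape),
                      "data": net.w_sys.ravel().tolist()},
        },
        "w_out": {"shape": list(model.w_out.shape),
                  "data": model.w_out.ravel().tolist()},
        "input_set": list(model.input_set.features),
        "feature_ranges": {f: _range_to_dict(r)
                           for f, r in model.feature_ranges.items()},
        "sgr_range": _range_to_dict(model.sgr_range),
        "config": {
            "n_neurons": model.config.n_neurons,
            "lam": model.config.lam,
            "b0": model.config.b0,
            "spectral_radius": model.config.spectral_radius,
            "sparsity": model.config.sparsity,
            "lam_rls": model.config.lam_rls,
            "beta": model.config.beta,
            "passes": model.config.passes,
        },
        "provenance": {
            "dataset_label": model.dataset_label,
            "seed": model.seed,
        },
    }
    return json.dumps(doc, sort_keys=True, separators=(",", ":"))


def write_model(model: TrainedModel, path: str | Path) -> None:
    Path(path).write_text(model_to_json(model), encoding="utf-8")


def _array(obj: dict) -> np.ndarray:
    return np.asarray(obj["data"], dtype=float).reshape(obj["shape"])


def read_model(path: str | Path) -> TrainedModel:
    """Load a model file; exact numeric round-trip of everything written."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except (OSError, json.JSONDecodeError) as exc:
        raise ModelFileError(f"cannot parse model file {path}: {exc}") from exc
    version = doc.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ModelFileError(
            f"{path}: unsupported model format version {version!r} "
            f"(this package reads version {MODEL_FORMAT_VERSION})"
        )
    try:
        n = doc["network"]
        net = ReservoirNetwork(
            n=n["n"], m=n["m"], lam=n["lam"], b0=n["b0"],
            w_in=_array(n["w_in"]), w_sys=_array(n["w_sys"]),
            seed=n["seed"], spectral_radius=n["spectral_radius"],
            sparsity=n["sparsity"],
        )
        cfg = NetConfig(**doc["config"])
        ranges = {f: FeatureRange(d["name"], d["min"], d["max"])
                  for f, d in doc["feature_ranges"].items()}
        sgr_d = doc["sgr_range"]
        return TrainedModel(
            network=net,
            w_out=_array(doc["w_out"]),
            input_set=InputSetDescriptor(tuple(doc["input_set"])),
            feature_ranges=ranges,
            sgr_range=FeatureRange(sgr_d["name"], sgr_d["min"], sgr_d["max"]),
            config=cfg,
            dataset_label=doc["provenance"]["dataset_label"],
            seed=doc["provenance"]["seed"],
        )
    except (KeyError, TypeError) as exc:
        raise ModelFileError(f"{path}: malformed model file ({exc})") from exc
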