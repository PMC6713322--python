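"""Training, evaluation and estimation protocols.

The experimental machinery around the reservoir: the seven input-feature
subsets, per-sample online training, the 85/15 train/test split, normalized
and real-unit mean-squared-error reporting, and SGR estimation for new
populations with a trained model.

Protocol choices (see docs/methods.md for rationale):

* Records are presented in stored dataset order; the reservoir state is
  carried across records within one training pass and reset to zero between
  passes and between the training and estimation phases.
* Normalization ranges (features and SGR) come from the *training* records
  only and are stored with the model; held-out and new data are normalized
  with those stored ranges, and normalized network outputs are mapped back
  to % day^-1 with the stored SGR range.
* MSE is reported as mean +/- SD of per-sample squared errors on the
  normalized scale (the scale on which the readout is trained), with the
  real-unit equivalent alongside.
* For a dataset combined from several constituent datasets, the test
  fraction is drawn per constituent, not from the pooled table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import FEATURES, FishDataset, combine_datasets  # noqa: F401
from .errors import ValidationError
from .growth_metrics import FeatureRange, denormalize_array, normalize_array
from .reservoir import (
    DEFAULTS,
    ReservoirNetwork,
    ReservoirState,
    RLSState,
    build_reservoir,
    readout,
    reservoir_step,
    rls_update,
)

__all__ = [
    "InputSetDescriptor",
    "INPUT_SETS",
    "NetConfig",
    "TrainedModel",
    "EvaluationReport",
    "train_model",
    "estimate_sgr",
    "split_train_test",
    "evaluate",
    "ablation_study",
    "combine_datasets",
]


@dataclass(frozen=True)
class InputSetDescriptor:
    """Ordered subset of the three model-input features."""

    features: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.features:
            raise ValidationError("input set must name at least one feature")
        bad = [f for f in self.features if f not in FEATURES]
        if bad:
            raise ValidationError(f"unknown features {bad}; choose from {FEATURES}")
        if len(set(self.features)) != len(self.features):
            raise ValidationError(f"duplicate features in input set {self.features}")

    @property
    def m(self) -> int:
        return len(self.features)

    def __str__(self) -> str:
        return "+".join(self.features)


#: The seven feature subsets studied per dataset: each single feature, each
#: pair, and the full triple {weight, T/C ratio, CF}.
INPUT_SETS: tuple[InputSetDescriptor, ...] = (
    InputSetDescriptor(("weight",)),
    InputSetDescriptor(("tc_ratio",)),
    InputSetDescriptor(("cf",)),
    InputSetDescriptor(("weight", "tc_ratio")),
    InputSetDescriptor(("tc_ratio", "cf")),
    InputSetDescriptor(("weight", "cf")),
    InputSetDescriptor(("weight", "tc_ratio", "cf")),
)


@dataclass(frozen=True)
class NetConfig:
    """User-tunable reservoir/training settings.

    ``lam`` follows the published convention: 0.3 when a model is evaluated
    on held-out data from its own dataset, 1.0 when applied across datasets
    or species.  The package does not auto-select it.
    """

    n_neurons: int = DEFAULTS["n_neurons"]
    lam: float = 0.3
    b0: float = DEFAULTS["bias"]
    spectral_radius: float = DEFAULTS["spectral_radius"]
    sparsity: float = DEFAULTS["sparsity"]
    lam_rls: float = DEFAULTS["lam_rls"]
    beta: float = DEFAULTS["beta"]
    passes: int = 1


@dataclass
class TrainedModel:
    """A reservoir, its trained readout, and everything needed to apply it."""

    network: ReservoirNetwork
    w_out: np.ndarray
    input_set: InputSetDescriptor
    feature_ranges: dict[str, FeatureRange]
    sgr_range: FeatureRange
    config: NetConfig
    dataset_label: str
    seed: int

    def normalize_features(self, data: FishDataset,
                           input_ranges: str = "model") -> np.ndarray:
        """(n, M) matrix of this model's inputs on the normalized scale.

        ``input_ranges="model"`` uses the stored training ranges (values
        outside them extrapolate beyond [-1, 1]); ``"data"`` rescales each
        feature by the min/max of ``data`` itself, the convention for
        applying a model across datasets or species whose sizes differ by
        orders of magnitude.
        """
        raw = data.feature_matrix(self.input_set.features)
        out = np.empty_like(raw)
        for j, f in enumerate(self.input_set.features):
            if input_ranges == "model":
                r = self.feature_ranges[f]
            elif input_ranges == "data":
                r = FeatureRange(f, float(raw[:, j].min()), float(raw[:, j].max()))
            else:
                raise ValidationError(
                    f"input_ranges must be 'model' or 'data', got {input_ranges!r}"
                )
            out[:, j] = normalize_array(raw[:, j], r)
        return out


@dataclass
class EvaluationReport:
    """Per-sample squared errors of a model on a labelled test set."""

    input_set: InputSetDescriptor
    squared_errors_norm: np.ndarray
    squared_errors_real: np.ndarray
    predicted_norm: np.ndarray
    target_norm: np.ndarray
    predicted_sgr: np.ndarray
    target_sgr: np.ndarray
    test_indices: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    seed: int | None = None

    @property
    def mse(self) -> float:
        """Mean squared error, normalized scale."""
        return float(self.squared_errors_norm.mean())

    @property
    def mse_sd(self) -> float:
        """SD of the per-sample squared errors, normalized scale."""
        return float(self.squared_errors_norm.std(ddof=0))

    @property
    def mse_real(self) -> float:
        """Mean squared error in (% day^-1)^2."""
        return float(self.squared_errors_real.mean())

    @property
    def mse_real_sd(self) -> float:
        return float(self.squared_errors_real.std(ddof=0))


def _feature_ranges(data: FishDataset,
                    inputs: InputSetDescriptor) -> dict[str, FeatureRange]:
    raw = data.feature_matrix(inputs.features)
    return {
        f: FeatureRange(f, float(raw[:, j].min()), float(raw[:, j].max()))
        for j, f in enumerate(inputs.features)
    }


def train_model(
    data: FishDataset,
    inputs: InputSetDescriptor,
    config: NetConfig = NetConfig(),
    seed: int = 0,
) -> TrainedModel:
    """Train a readout online on one dataset, one (state, target) pair at a time.

    Normalization ranges for the inputs and for SGR are computed from
    ``data`` (the training records) and stored with the model.  Records are
    presented in stored order for ``config.passes`` passes (default one —
    the strict online reading); the readout weights after the final pair are
    the model.
    """
    if len(data) < 2:
        raise ValidationError(
            f"dataset {data.label!r} has {len(data)} record(s); need at least 2"
        )
    targets_real = data.sgr_values()
    ranges = _feature_ranges(data, inputs)
    sgr_range = FeatureRange("sgr", float(targets_real.min()), float(targets_real.max()))

    net = build_reservoir(
        n=config.n_neurons, m=inputs.m, lam=config.lam, seed=seed,
        b0=config.b0, spectral_radius=config.spectral_radius,
        sparsity=config.sparsity,
    )
    raw = data.feature_matrix(inputs.features)
    u_all = np.column_stack(
        [normalize_array(raw[:, j], ranges[f]) for j, f in enumerate(inputs.features)]
    )
    d_all = normalize_array(targets_real, sgr_range)

    rls = RLSState.initial(net.n, lam_rls=config.lam_rls, beta=config.beta)
    for _ in range(config.passes):
        state = ReservoirState.zeros(net.n)
        for u, d in zip(u_all, d_all):
            state = reservoir_step(net, state, u)
            rls = rls_update(rls, state, d)

    return TrainedModel(
        network=net, w_out=rls.w_out.copy(), input_set=inputs,
        feature_ranges=ranges, sgr_range=sgr_range, config=config,
        dataset_label=data.label, seed=seed,
    )


def estimate_sgr(model: TrainedModel, records: FishDataset,
                 input_ranges: str = "model") -> tuple[np.ndarray, np.ndarray]:
    """Estimate SGR for each record; returns ``(sgr_percent_per_day, normalized)``.

    Features are normalized with the model's stored training ranges by
    default (``input_ranges="model"``; out-of-range values extrapolate, no
    clipping anywhere).  With ``input_ranges="data"`` each feature is
    instead rescaled by the min/max of ``records`` itself — the convention
    for cross-dataset and cross-species application, where body sizes far
    outside the training envelope would otherwise saturate the tanh
    neurons.  The reservoir runs from a zero state over the record
    sequence; normalized outputs are mapped to % day^-1 with the stored
    (training) SGR range either way.
    """
    u_all = model.normalize_features(records, input_ranges)
    net = model.network
    rls = RLSState(w_out=model.w_out, p=np.eye(net.n), lam_rls=1.0)
    state = ReservoirState.zeros(net.n)
    y_norm = np.empty(len(records))
    for i, u in enumerate(u_all):
        state = reservoir_step(net, state, u)
        y_norm[i] = readout(rls, state)
    sgr = denormalize_array(y_norm, model.sgr_range)
    return sgr, y_norm


def _split_indices(n: int, test_fraction: float,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    n_test = max(1, round(n * test_fraction))
    if n - n_test < 1:
        raise ValidationError(
            f"n={n} leaves no training records at test fraction {test_fraction}"
        )
    test = np.sort(rng.choice(n, size=n_test, replace=False))
    train = np.setdiff1d(np.arange(n), test)
    return train, test


def split_train_test(
    data: FishDataset, test_fraction: float = 0.15, seed: int = 0,
) -> tuple[FishDataset, FishDataset]:
    """Random held-out split, 15% test by default, nearest-integer sizing.

    The test count is ``round(n * fraction)`` with a minimum of one record.
    For a combined dataset the fraction is drawn independently from each
    constituent dataset, so every constituent is represented in the test
    set.  Records keep their stored relative order on both sides.
    """
    if not 0 < test_fraction < 1:
        raise ValidationError(f"test fraction must be in (0, 1), got {test_fraction}")
    labels = data.df["dataset"].to_numpy()
    groups = list(dict.fromkeys(labels))  # stored order, unique
    ss = np.random.SeedSequence(seed).spawn(len(groups))
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for g, child in zip(groups, ss):
        pos = np.flatnonzero(labels == g)
        tr, te = _split_indices(len(pos), test_fraction,
                                np.random.default_rng(child))
        train_idx.append(pos[tr])
        test_idx.append(pos[te])
    train = np.sort(np.concatenate(train_idx))
    test = np.sort(np.concatenate(test_idx))
    return data.take(train, "/train"), data.take(test, "/test")


def evaluate(model: TrainedModel, test: FishDataset,
             seed: int | None = None) -> EvaluationReport:
    """Squared-error report of a model on records with known SGR."""
    if len(test) == 0:
        raise ValidationError("empty test set")
    target_real = test.sgr_values()
    pred_real, pred_norm = estimate_sgr(model, test)
    target_norm = normalize_array(target_real, model.sgr_range)
    return EvaluationReport(
        input_set=model.input_set,
        squared_errors_norm=(pred_norm - target_norm) ** 2,
        squared_errors_real=(pred_real - target_real) ** 2,
        predicted_norm=pred_norm,
        target_norm=target_norm,
        predicted_sgr=pred_real,
        target_sgr=target_real,
        seed=seed,
    )


def ablation_study(
    data: FishDataset,
    config: NetConfig = NetConfig(),
    seed: int = 0,
    test_fraction: float = 0.15,
) -> pd.DataFrame:
    """Train and evaluate one model per input subset on a shared split.

    All seven models see the identical train/test partition and reservoir
    seed, so rows differ only in which features drive the network.  Returns
    a table ranked by normalized MSE with a flag on the full three-input
    set when it attains the minimum.
    """
    train, test = split_train_test(data, test_fraction, seed)
    rows = []
    for inputs in INPUT_SETS:
        model = train_model(train, inputs, config, seed)
        rep = evaluate(model, test, seed=seed)
        rows.append({
            "inputs": str(inputs),
            "n_inputs": inputs.m,
            "mse": rep.mse,
            "mse_sd": rep.mse_sd,
            "mse_real": rep.mse_real,
            "mse_real_sd": rep.mse_real_sd,
        })
    table = pd.DataFrame(rows).sort_values("mse", kind="stable").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    full = str(INPUT_SETS[-1])
    table["is_full_set"] = table["inputs"] == full
    table.attrs["full_set_is_best"] = bool(table.loc[0, "inputs"] == full)
    return table
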