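"""The fixed random reservoir, its dynamics, and the online RLS readout.

An echo state network: ``N`` tanh neurons with fixed sparse random
recurrent weights ``W_sys`` (spectral radius 0.9) and fixed sparse random
input weights ``W_in``; only the linear readout ``W_out`` is trained.  The
leaky-integrator state update is

    x(t+1) = (1 - lam) x(t) + lam * tanh(W_in u(t+1) + W_sys x(t) + b0)

with network time scale ``0 < lam <= 1`` and constant bias ``b0`` applied to
every hidden neuron.  The readout is linear, ``y(t) = W_out x(t)``, and is
trained online by recursive least squares (RLS) with a fixed forgetting
factor:

    e(t) = d(t) - y(t)
    K(t) = p(t-1) x(t) / (lam_rls + x(t)^T p(t-1) x(t))
    p(t) = [p(t-1) - K(t) x(t)^T p(t-1)] / lam_rls
    W_out(t) = W_out(t-1) + K(t) e(t)

with ``W_out(0) = 0`` and ``p(0) = I / beta``.  With ``lam_rls = 1`` a single
pass is algebraically identical to ridge regression with penalty ``beta``,
which is the oracle used in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import NumericalError, ValidationError

__all__ = [
    "ReservoirNetwork",
    "ReservoirState",
    "RLSState",
    "build_reservoir",
    "reservoir_step",
    "readout",
    "rls_update",
    "DEFAULTS",
]

#: Fixed architecture settings: 50 hidden neurons, one output, tanh hidden
#: activation, bias 0.001, 50% sparsity on both weight matrices, spectral
#: radius 0.9, RLS forgetting factor 0.99 with p(0) = I / 1e-4.
DEFAULTS = {
    "n_neurons": 50,
    "bias": 0.001,
    "spectral_radius": 0.9,
    "sparsity": 0.5,
    "w_in_scale": 0.1,
    "w_sys_scale": 1.0,
    "lam_rls": 0.99,
    "beta": 1e-4,
}


@dataclass(frozen=True)
class ReservoirNetwork:
    """Immutable fixed part of the network: weights plus dynamics parameters."""

    n: int
    m: int
    lam: float
    b0: float
    w_in: np.ndarray  # (N, M)
    w_sys: np.ndarray  # (N, N)
    seed: int
    spectral_radius: float
    sparsity: float

    def __post_init__(self) -> None:
        self.w_in.setflags(write=False)
        self.w_sys.setflags(write=False)


@dataclass
class ReservoirState:
    """Hidden activations and a step counter."""

    x: np.ndarray
    t: int = 0

    @classmethod
    def zeros(cls, n: int) -> "ReservoirState":
        return cls(x=np.zeros(n), t=0)


@dataclass
class RLSState:
    """Readout weights plus the RLS auto-correlation matrix and gain."""

    w_out: np.ndarray  # (N,)
    p: np.ndarray  # (N, N)
    lam_rls: float
    k: np.ndarray = field(default_factory=lambda: np.zeros(0))
    e: float = 0.0

    @classmethod
    def initial(cls, n: int, lam_rls: float = DEFAULTS["lam_rls"],
                beta: float = DEFAULTS["beta"]) -> "RLSState":
        """Zero readout and p(0) = I / beta."""
        if not 0 < lam_rls <= 1:
            raise ValidationError(f"forgetting factor must be in (0, 1], got {lam_rls}")
        if beta <= 0:
            raise ValidationError(f"beta must be positive, got {beta}")
        return cls(w_out=np.zeros(n), p=np.eye(n) / beta, lam_rls=lam_rls,
                   k=np.zeros(n))


def _sparsify(w: np.ndarray, sparsity: float, rng: np.random.Generator) -> np.ndarray:
    # zero out a uniformly random subset of exactly round(sparsity * size)
    # entries, so the realized sparsity is the nominal one to within one
    # entry; applied before any spectral scaling
    n_zero = round(sparsity * w.size)
    flat = w.ravel().copy()
    flat[rng.choice(w.size, size=n_zero, replace=False)] = 0.0
    return flat.reshape(w.shape)


def _scale_to_radius(w: np.ndarray, rho: float) -> np.ndarray:
    """Rescale a square matrix so its spectral radius is exactly ``rho``."""
    current = np.max(np.abs(np.linalg.eigvals(w)))
    if current == 0:
        raise NumericalError(
            "sparsified recurrent matrix is nilpotent (spectral radius 0); "
            "rebuild the reservoir with a different seed"
        )
    return w * (rho / current)


def build_reservoir(
    n: int = DEFAULTS["n_neurons"],
    m: int = 3,
    lam: float = 0.3,
    seed: int = 0,
    *,
    b0: float = DEFAULTS["bias"],
    spectral_radius: float = DEFAULTS["spectral_radius"],
    sparsity: float = DEFAULTS["sparsity"],
) -> ReservoirNetwork:
    """Construct the fixed random network, a pure function of the seed.

    ``W_in`` entries are uniform on [-0.1, 0.1], ``W_sys`` entries uniform on
    [-1, 1]; both are sparsified entrywise to the requested sparsity, and
    ``W_sys`` is then rescaled to the requested spectral radius.
    """
    if n < 1:
        raise ValidationError(f"need at least one hidden neuron, got {n}")
    if m < 1:
        raise ValidationError(f"need at least one input neuron, got {m}")
    if not 0 < lam <= 1:
        raise ValidationError(f"network time scale must be in (0, 1], got {lam}")
    rng = np.random.default_rng(seed)
    w_in = rng.uniform(-DEFAULTS["w_in_scale"], DEFAULTS["w_in_scale"], size=(n, m))
    w_in = _sparsify(w_in, sparsity, rng)
    w_sys = rng.uniform(-DEFAULTS["w_sys_scale"], DEFAULTS["w_sys_scale"], size=(n, n))
    w_sys = _sparsify(w_sys, sparsity, rng)
    w_sys = _scale_to_radius(w_sys, spectral_radius)
    return ReservoirNetwork(
        n=n, m=m, lam=lam, b0=b0, w_in=w_in, w_sys=w_sys, seed=seed,
        spectral_radius=spectral_radius, sparsity=sparsity,
    )


def reservoir_step(net: ReservoirNetwork, state: ReservoirState,
                   u: np.ndarray) -> ReservoirState:
    """One leaky-integrator update driven by the normalized input vector."""
    u = np.atleast_1d(np.asarray(u, dtype=float))
    if u.shape != (net.m,):
        raise ValidationError(
            f"input has shape {u.shape}, network expects ({net.m},)"
        )
    drive = net.w_in @ u + net.w_sys @ state.x + net.b0
    x_new = (1.0 - net.lam) * state.x + net.lam * np.tanh(drive)
    return ReservoirState(x=x_new, t=state.t + 1)


def readout(rls: RLSState, state: ReservoirState) -> float:
    """Linear output y(t) = W_out x(t)."""
    if rls.w_out.shape != state.x.shape:
        raise ValidationError(
            f"readout dimension {rls.w_out.shape} != state dimension {state.x.shape}"
        )
    return float(rls.w_out @ state.x)


def rls_update(rls: RLSState, state: ReservoirState, d: float) -> RLSState:
    """One recursive-least-squares step on the (state, target) pair.

    Returns a new :class:`RLSState`; the auto-correlation matrix is
    re-symmetrized after the rank-one update to stop floating-point drift
    from breaking positive-definiteness over long runs.
    """
    x = state.x
    y = float(rls.w_out @ x)
    e = float(d) - y
    px = rls.p @ x
    denom = rls.lam_rls + float(x @ px)
    k = px / denom
    p = (rls.p - np.outer(k, px)) / rls.lam_rls
    p = 0.5 * (p + p.T)
    w_out = rls.w_out + k * e
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(w_out))):
        raise NumericalError(
            f"RLS update diverged at step {state.t} (non-finite gain or weights)"
        )
    return RLSState(w_out=w_out, p=p, lam_rls=rls.lam_rls, k=k, e=e)
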