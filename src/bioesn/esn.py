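"""Leaky echo state network: dynamics, readout training, model/results API.

The reservoir is a fixed recurrent network with state r(t) in R^{N_r} driven
by an input x(t) in R^{N_x}:

    r'(t) = f(W_in (eps * x(t)) + W r(t-1) + b)
    r(t)  = alpha r'(t) + (1 - alpha) r(t-1)

with f = tanh (states bounded to [-1, 1]), leakage alpha in (0, 1], constant
bias vector b, and input scaling eps applied before the input weights. States
start at r = 0, which produces an input-unrelated initial transient; the
first ``transient`` steps (default 100) are discarded from both fitting and
scoring. Only the linear readout is trained:

    y(t) = g(W_out [x(t); r(t)])

by least squares on the post-transient regressor matrix Z = [x; r] via a
rank-revealing pseudoinverse (minimum-norm least-squares solution). The
readout regressors use the *unscaled* input — least squares is invariant to
regressor scaling and conditioning is far better when eps is tiny.

:class:`BioESN` wraps these pieces as a model object: construct it from a
reservoir matrix and a config, ``fit(x, y)`` returns a
:class:`BioESNResults` carrying the readout, fitted values and diagnostics,
with ``predict()`` and ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .errors import DegenerateInputError, ValidationError
from .surrogates import ReservoirMatrix, scale_spectral_radius

__all__ = [
    "ESNConfig",
    "StateTrajectory",
    "Readout",
    "init_input_weights",
    "run_reservoir",
    "fit_readout",
    "predict",
    "BioESN",
    "BioESNResults",
]

RESERVOIR_ACTIVATIONS = ("tanh", "identity")
OUTPUT_ACTIVATIONS = ("identity", "relu")
LEAK_FORMS = ("standard", "as-printed")


@dataclass(frozen=True)
class ESNConfig:
    """Hyperparameter record for a BioESN.

    Defaults are the fixed constellation used for all main experiments:
    spectral radius rho = 0.99, input scaling eps = 1e-5, leakage alpha = 1
    (no leakage), bias b = 1, tanh reservoir, 100-step transient.

    ``leak_integration`` selects the leaky-integration form:
    ``"standard"`` uses r(t) = a r'(t) + (1-a) r(t-1);
    ``"as-printed"`` uses r(t) = a r'(t) + (1-a) W r(t-1) (a variant that
    re-applies the recurrent weights to the carried-over state). With
    alpha = 1 the two are identical.
    """

    spectral_radius: float = 0.99
    input_scaling: float = 1e-5
    leakage: float = 1.0
    bias: float = 1.0
    reservoir_activation: str = "tanh"
    output_activation: str = "identity"
    transient: int = 100
    seed: Optional[int] = None
    leak_integration: str = "standard"

    def __post_init__(self) -> None:
        if self.spectral_radius <= 0:
            raise ValidationError("spectral_radius must be positive")
        if self.input_scaling <= 0:
            raise ValidationError("input_scaling must be positive")
        if not 0 < self.leakage <= 1:
            raise ValidationError("leakage must be in (0, 1]")
        if self.reservoir_activation not in RESERVOIR_ACTIVATIONS:
            raise ValidationError(
                f"reservoir_activation must be one of {RESERVOIR_ACTIVATIONS}"
            )
        if self.output_activation not in OUTPUT_ACTIVATIONS:
            raise ValidationError(
                f"output_activation must be one of {OUTPUT_ACTIVATIONS}"
            )
        if self.transient < 0:
            raise ValidationError("transient must be >= 0")
        if self.leak_integration not in LEAK_FORMS:
            raise ValidationError(f"leak_integration must be one of {LEAK_FORMS}")

    def replace(self, **kwargs) -> "ESNConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class StateTrajectory:
    """Reservoir activations r(t) (T x N_r) with the unscaled inputs x(t)."""

    states: np.ndarray
    inputs: np.ndarray


@dataclass(frozen=True)
class Readout:
    """Trained readout: W_out is N_y x (N_x + N_r), applied to [x(t); r(t)]."""

    W_out: np.ndarray
    output_activation: str = "identity"


def _activation(name: str):
    if name == "tanh":
        return np.tanh
    if name == "identity":
        return lambda a: a
    if name == "relu":
        return lambda a: np.maximum(a, 0.0)
    raise ValidationError(f"unknown activation {name!r}")


def _as_2d(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2:
        raise ValidationError(f"{name} must be 1- or 2-dimensional, got ndim={x.ndim}")
    return x


def init_input_weights(
    n_reservoir: int, n_inputs: int, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Dense input weight matrix W_in (N_r x N_x), i.i.d. Uniform[-1, 1].

    Dense because every reservoir neuron receives the (weighted) input signal.
    """
    if n_reservoir < 1 or n_inputs < 1:
        raise ValidationError("n_reservoir and n_inputs must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.uniform(-1.0, 1.0, size=(n_reservoir, n_inputs))


def run_reservoir(
    x: np.ndarray,
    W: np.ndarray | ReservoirMatrix,
    W_in: np.ndarray,
    cfg: ESNConfig,
    initial_state: np.ndarray | None = None,
) -> StateTrajectory:
    """Drive the reservoir with input ``x`` from a zero initial state.

    ``initial_state`` overrides the zero start (useful for probing the echo
    state property). Returns all T states; transient handling happens
    downstream in fitting and scoring. NaNs in ``x`` are treated as
    validation errors.
    """
    x = _as_2d(x, "x")
    if not np.all(np.isfinite(x)):
        raise ValidationError("inputs must be finite")
    W = W.weights if isinstance(W, ReservoirMatrix) else np.asarray(W, dtype=float)
    W_in = np.asarray(W_in, dtype=float)
    n_r = W.shape[0]
    if W.ndim != 2 or W.shape[1] != n_r:
        raise ValidationError(f"W must be square, got {W.shape}")
    if W_in.shape != (n_r, x.shape[1]):
        raise ValidationError(
            f"W_in shape {W_in.shape} incompatible with reservoir {n_r} "
            f"and inputs {x.shape[1]}"
        )
    f = _activation(cfg.reservoir_activation)
    alpha = cfg.leakage
    bias = cfg.bias * np.ones(n_r)
    scaled_in = (cfg.input_scaling * x) @ W_in.T  # (T, N_r)
    states = np.empty((x.shape[0], n_r))
    if initial_state is None:
        r = np.zeros(n_r)
    else:
        r = np.asarray(initial_state, dtype=float).copy()
        if r.shape != (n_r,):
            raise ValidationError(f"initial_state must have shape ({n_r},)")
    for t in range(x.shape[0]):
        r_new = f(scaled_in[t] + W @ r + bias)
        if cfg.leak_integration == "standard":
            r = alpha * r_new + (1.0 - alpha) * r
        else:
            r = alpha * r_new + (1.0 - alpha) * (W @ r)
        states[t] = r
    return StateTrajectory(states=states, inputs=x)


def _design_matrix(x: np.ndarray, states: np.ndarray) -> np.ndarray:
    if x.shape[0] != states.shape[0]:
        raise ValidationError("inputs and states must cover the same time steps")
    return np.hstack([x, states])


def fit_readout(
    x: np.ndarray,
    states: np.ndarray,
    y_target: np.ndarray,
    cfg: ESNConfig,
) -> Readout:
    """Solve W_out = Z^+ Y on the post-transient steps.

    Z = [x(t); r(t)] row-wise; the first ``cfg.transient`` rows are dropped,
    as are any remaining rows whose target contains NaN (undefined leading
    entries of lagged targets). The solution is the minimum-norm least-squares
    solution via a rank-revealing SVD (singular values below
    max(T, N_x + N_r) * eps * sigma_max are treated as zero).
    """
    x = _as_2d(x, "x")
    y = _as_2d(y_target, "y_target")
    z = _design_matrix(x, states)
    if y.shape[0] != z.shape[0]:
        raise ValidationError("targets must cover the same time steps as inputs")
    if z.shape[0] <= cfg.transient:
        raise DegenerateInputError(
            f"need more than transient={cfg.transient} time steps, got {z.shape[0]}"
        )
    z = z[cfg.transient:]
    y = y[cfg.transient:]
    defined = ~np.any(np.isnan(y), axis=1)
    z, y = z[defined], y[defined]
    if z.shape[0] == 0:
        raise DegenerateInputError("no defined target rows left after the transient")
    if not np.all(np.isfinite(y)):
        raise ValidationError("targets must be finite where defined")
    coef, *_ = np.linalg.lstsq(z, y, rcond=None)
    return Readout(W_out=coef.T, output_activation=cfg.output_activation)


def predict(x: np.ndarray, states: np.ndarray, readout: Readout) -> np.ndarray:
    """Apply the readout: y_hat(t) = g(W_out [x(t); r(t)]) for every step."""
    x = _as_2d(x, "x")
    z = _design_matrix(x, states)
    if z.shape[1] != readout.W_out.shape[1]:
        raise ValidationError(
            f"readout expects {readout.W_out.shape[1]} regressors, got {z.shape[1]}"
        )
    g = _activation(readout.output_activation)
    return g(z @ readout.W_out.T)


class BioESN:
    """An echo state network whose reservoir wiring comes from a connectome.

    Parameters
    ----------
    reservoir
        A :class:`ReservoirMatrix` (any surrogate condition) or a raw square
        weight matrix. The matrix is spectrally rescaled to
        ``config.spectral_radius`` at construction.
    n_inputs
        Number of input channels (1 for memory capacity, 2 for sequence
        recall).
    config
        Hyperparameters; defaults to the fixed constellation.
    input_weights
        Optional explicit W_in (N_r x N_x); drawn Uniform[-1, 1] from
        ``config.seed`` when omitted.
    """

    def __init__(
        self,
        reservoir: ReservoirMatrix | np.ndarray,
        n_inputs: int = 1,
        config: ESNConfig | None = None,
        input_weights: np.ndarray | None = None,
    ) -> None:
        self.config = config if config is not None else ESNConfig()
        scaled = scale_spectral_radius(reservoir, self.config.spectral_radius)
        self.reservoir = scaled if isinstance(scaled, ReservoirMatrix) else None
        self.W = scaled.weights if isinstance(scaled, ReservoirMatrix) else scaled
        self.n_reservoir = self.W.shape[0]
        self.n_inputs = int(n_inputs)
        if input_weights is not None:
            input_weights = np.asarray(input_weights, dtype=float)
            if input_weights.shape != (self.n_reservoir, self.n_inputs):
                raise ValidationError(
                    f"input_weights must be {(self.n_reservoir, self.n_inputs)}, "
                    f"got {input_weights.shape}"
                )
            self.W_in = input_weights
        else:
            self.W_in = init_input_weights(
                self.n_reservoir, self.n_inputs, self.config.seed
            )

    @classmethod
    def from_condition(
        cls,
        source,
        condition: str,
        n_inputs: int = 1,
        config: ESNConfig | None = None,
        seed: int | None = None,
        random_k: int = 10,
    ) -> "BioESN":
        """Build a BioESN by applying a surrogate condition to a connectome.

        ``source`` is a Connectome or UpscaledConnectome; ``condition`` is one
        of the five condition names (underscored or hyphenated).
        """
        from . import surrogates

        name = condition.replace("-", "_")
        n = np.asarray(source.weights).shape[0]
        builders = {
            "bio_rank": lambda: surrogates.make_bio_rank(source, seed),
            "bio_no_rank": lambda: surrogates.make_bio_no_rank(source, seed),
            "random_density": lambda: surrogates.make_random_density(source, seed),
            "random_k": lambda: surrogates.make_random_k(n, random_k, seed),
            "random_full": lambda: surrogates.make_random_full(n, seed),
        }
        if name not in builders:
            raise ValidationError(
                f"unknown condition {condition!r}; valid: {sorted(builders)}"
            )
        return cls(builders[name](), n_inputs=n_inputs, config=config)

    def run(self, x: np.ndarray) -> StateTrajectory:
        """Harvest reservoir states for input ``x`` from a zero initial state."""
        return run_reservoir(x, self.W, self.W_in, self.config)

    def fit(self, x: np.ndarray, y: np.ndarray) -> "BioESNResults":
        """Train the linear readout on (x, y) and return the results object."""
        traj = self.run(x)
        readout = fit_readout(traj.inputs, traj.states, y, self.config)
        return BioESNResults(self, readout, traj, _as_2d(y, "y"))


class BioESNResults:
    """Fitted readout plus training diagnostics for a :class:`BioESN`.

    ``predict(x)`` re-runs the reservoir from a zero state on new input (the
    first ``transient`` steps of any evaluation span should be excluded from
    scoring, which the task scorers do).
    """

    def __init__(
        self,
        model: BioESN,
        readout: Readout,
        trajectory: StateTrajectory,
        y: np.ndarray,
    ) -> None:
        self.model = model
        self.readout = readout
        self.trajectory = trajectory
        self.y = y
        self.fittedvalues = predict(trajectory.inputs, trajectory.states, readout)
        t0 = model.config.transient
        resid = self.fittedvalues[t0:] - y[t0:]
        resid = resid[~np.any(np.isnan(resid), axis=1)]
        self.train_rmse = float(np.sqrt(np.mean(resid**2))) if resid.size else np.nan
        self.n_train_steps = int(resid.shape[0])

    def predict(self, x: np.ndarray) -> np.ndarray:
        traj = self.model.run(x)
        return predict(traj.inputs, traj.states, self.readout)

    def summary(self) -> str:
        cfg = self.model.config
        condition = (
            self.model.reservoir.condition if self.model.reservoir is not None else "custom"
        )
        lines = [
            "BioESN results",
            "=" * 46,
            f"{'reservoir size':<28}{self.model.n_reservoir}",
            f"{'condition':<28}{condition}",
            f"{'inputs':<28}{self.model.n_inputs}",
            f"{'outputs':<28}{self.readout.W_out.shape[0]}",
            f"{'spectral radius':<28}{cfg.spectral_radius}",
            f"{'input scaling':<28}{cfg.input_scaling}",
            f"{'leakage':<28}{cfg.leakage}",
            f"{'bias':<28}{cfg.bias}",
            f"{'output activation':<28}{cfg.output_activation}",
            f"{'transient (discarded)':<28}{cfg.transient}",
            f"{'training steps scored':<28}{self.n_train_steps}",
            f"{'training RMSE':<28}{self.train_rmse:.6g}",
            "=" * 46,
        ]
        return "\n".join(lines)
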