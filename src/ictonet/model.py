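"""Stochastic theta-model of seizure transitions on a weighted network.

Each region of interest (ROI) is a phase oscillator

    dtheta_i/dt = (1 - cos theta_i) + (1 + cos theta_i) * I_i(t),

with input current

    I_i(t) = I0 + sigma * xi_i(t) + (K/N) * sum_{j != i} a_ji * [1 - cos(theta_j - theta_s)],

where ``I0`` is the cortical excitability shared by all nodes, ``xi_i`` is
zero-mean unit-variance Gaussian noise, ``A = (a_ji)`` is the (symmetric)
functional connectivity matrix and ``theta_s`` is the stable resting phase.
For I0 < 0 the single-node system has a stable fixed point (rest) and a
saddle on the circle; the two collide at I0 = 0 in a saddle-node on invariant
circle (SNIC) bifurcation, beyond which the phase rotates (seizure state).
Noise drives transitions between rest and rotation for sub-threshold I0.

Integration uses the Euler--Maruyama scheme; the kernel is JIT-compiled and
consumes pre-generated Gaussian increments so trajectories are reproducible
(PCG64 streams) and noise can be supplied explicitly when needed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numba import njit
from scipy.ndimage import uniform_filter1d

__all__ = [
    "WeightedNetwork",
    "ModelParams",
    "PhaseTrajectories",
    "SeizureTimes",
    "NoFixedPointError",
    "stable_phase",
    "drift",
    "simulate",
    "classify_seizure",
    "seizure_times",
    "seizure_fraction",
]

_SYMMETRY_TOL = 1e-12


class NoFixedPointError(ValueError):
    """Raised when a resting fixed point is requested for I0 > 0."""


@dataclass(frozen=True)
class WeightedNetwork:
    """Symmetric, zero-diagonal, non-negative coupling matrix over N ROIs.

    Entry ``weights[j, i]`` is the strength a_ji with which node j drives
    node i; symmetry makes the orientation convention moot but it is fixed.
    """

    weights: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"adjacency must be square, got shape {w.shape}")
        if w.shape[0] < 1:
            raise ValueError("network needs at least one node")
        if not np.all(np.isfinite(w)):
            raise ValueError("adjacency contains non-finite weights")
        if np.any(w < 0):
            raise ValueError("adjacency contains negative weights")
        asym = np.abs(w - w.T)
        if asym.max(initial=0.0) > _SYMMETRY_TOL:
            j, i = np.unravel_index(np.argmax(asym), asym.shape)
            raise ValueError(
                f"adjacency not symmetric: entry ({j}, {i}) = {w[j, i]!r} "
                f"vs ({i}, {j}) = {w[i, j]!r}"
            )
        np.fill_diagonal(w, 0.0)
        object.__setattr__(self, "weights", w)
        labels = tuple(self.labels) if self.labels else tuple(
            f"ROI{k}" for k in range(w.shape[0])
        )
        if len(labels) != w.shape[0]:
            raise ValueError("label count does not match node count")
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    def remove_node(self, i: int) -> "WeightedNetwork":
        """Network with node ``i`` and all its connections deleted."""
        keep = [k for k in range(self.n) if k != i]
        return WeightedNetwork(
            self.weights[np.ix_(keep, keep)].copy(),
            tuple(self.labels[k] for k in keep),
        )

    def permute(self, order: Sequence[int]) -> "WeightedNetwork":
        idx = np.asarray(order)
        return WeightedNetwork(
            self.weights[np.ix_(idx, idx)].copy(),
            tuple(self.labels[k] for k in idx),
        )


@dataclass(frozen=True)
class ModelParams:
    """Simulation parameters.

    Standard values follow the reference operating point of the model
    (K = 10, sigma = 6, dt = 1e-2, T = 4e6 steps); tests and desk-scale runs
    use shorter horizons (``n_steps = 1e5``) set explicitly.

    ``noise_scaling`` selects the discretization of the noise term:
    ``"sqrt_dt"`` (Euler--Maruyama, increment (1+cos)*sigma*sqrt(dt)*z) or
    ``"dt"`` (noise folded into the input current, increment
    (1+cos)*sigma*dt*z).
    """

    i0: float
    k: float = 10.0
    sigma: float = 6.0
    dt: float = 1e-2
    n_steps: int = 4_000_000
    burn_in: int | None = None
    noise_scaling: str = "sqrt_dt"
    seizure_window: float = 1.0  # smoothing window for the classifier, time units
    seizure_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.burn_in is None:
            object.__setattr__(self, "burn_in", int(0.05 * self.n_steps))
        if not (0 <= self.burn_in < self.n_steps):
            raise ValueError("need n_steps > burn_in >= 0")
        if self.noise_scaling not in ("sqrt_dt", "dt"):
            raise ValueError(f"unknown noise_scaling {self.noise_scaling!r}")

    @property
    def theta_s(self) -> float:
        """Stable resting phase; defined only for i0 <= 0."""
        return stable_phase(self.i0)

    def with_i0(self, i0: float) -> "ModelParams":
        return replace(self, i0=i0)


@dataclass(frozen=True)
class PhaseTrajectories:
    """Unwrapped phases, shape (N, n_steps + 1); column 0 is the initial state."""

    phases: np.ndarray
    params: ModelParams
    seed: int | None = None

    @property
    def n(self) -> int:
        return self.phases.shape[0]


@dataclass(frozen=True)
class SeizureTimes:
    """Per-node time spent in the rotating (seizure) state after burn-in."""

    t_sz: np.ndarray
    t_scored: float


def stable_phase(i0: float) -> float:
    """Stable resting phase theta_s = -arccos((1 + i0) / (1 - i0)).

    The arccos has two preimages on the circle; the negative branch is the
    attracting fixed point of the drift for i0 < 0 (the positive branch is
    the saddle). Raises :class:`NoFixedPointError` for i0 > 0, where the
    fixed points have vanished and the phase rotates.
    """
    if i0 > 0:
        raise NoFixedPointError(f"no resting fixed point for i0 = {i0} > 0")
    return -math.acos((1.0 + i0) / (1.0 - i0))


def drift(theta, i):
    """Deterministic phase velocity (1 - cos theta) + (1 + cos theta) * i."""
    theta = np.asarray(theta, dtype=float)
    c = np.cos(theta)
    out = (1.0 - c) + (1.0 + c) * np.asarray(i, dtype=float)
    return out if out.ndim else float(out)


@njit(cache=True, fastmath=True)
def _euler_chunk(
    theta, indptr, indices, data, i0, k_over_n, noise_coef, dt, theta_s, noise, out
):
    """Advance ``theta`` through ``noise.shape[0]`` Euler-Maruyama steps.

    ``noise`` holds standard-normal increments, one row per step; rows of
    ``out`` receive the post-step phases. The coupling matrix is given in
    compressed form: for node i, ``indices[indptr[i]:indptr[i+1]]`` are the
    presynaptic nodes j and ``data`` the weights a_ji.
    """
    n_sub, n = noise.shape
    rot = np.empty(n)
    cs = math.cos(theta_s)
    ss = math.sin(theta_s)
    for t in range(n_sub):
        for j in range(n):
            # 1 - cos(theta_j - theta_s), one trig pair per node
            rot[j] = 1.0 - (math.cos(theta[j]) * cs + math.sin(theta[j]) * ss)
        for i in range(n):
            coupling = 0.0
            for ptr in range(indptr[i], indptr[i + 1]):
                coupling += data[ptr] * rot[indices[ptr]]
            c = math.cos(theta[i])
            current = i0 + k_over_n * coupling
            d = (1.0 - c) + (1.0 + c) * current
            theta[i] = theta[i] + dt * d + noise_coef * (1.0 + c) * noise[t, i]
        out[t] = theta


@njit(cache=True, fastmath=True)
def _indicator_chunk(
    theta, c, s, rot, indptr, indices, data, i0, k_over_n, noise_coef, dt, cs, ss, noise, out
):
    """Euler-Maruyama steps emitting only the raw rotation indicator.

    ``c``, ``s``, ``rot`` carry cos(theta), sin(theta) and
    1 - cos(theta - theta_s) across chunk boundaries; ``out[t, i]`` is the
    indicator of node i after step t (phase more than pi/2 from rest).
    """
    n_sub, n = noise.shape
    for t in range(n_sub):
        for i in range(n):
            coupling = 0.0
            for ptr in range(indptr[i], indptr[i + 1]):
                coupling += data[ptr] * rot[indices[ptr]]
            current = i0 + k_over_n * coupling
            d = (1.0 - c[i]) + (1.0 + c[i]) * current
            theta[i] = theta[i] + dt * d + noise_coef * (1.0 + c[i]) * noise[t, i]
        for j in range(n):
            c[j] = math.cos(theta[j])
            s[j] = math.sin(theta[j])
            rot[j] = 1.0 - (c[j] * cs + s[j] * ss)
            out[t, j] = rot[j] > 1.0


def seizure_times(
    network: WeightedNetwork,
    params: ModelParams,
    seed: int | None = None,
    *,
    coupling_n: int | None = None,
    chunk_steps: int = 50_000,
) -> SeizureTimes:
    """Seizure times without storing the phase trajectory.

    Equivalent to ``classify_seizure(simulate(...))`` with the same seed and
    classifier settings, but memory-light; used by the excitability sweep.
    """
    if params.i0 > 0:
        raise NoFixedPointError("seizure scoring requires a resting phase (i0 <= 0)")
    n = network.n
    theta_s = stable_phase(params.i0)
    theta = np.full(n, theta_s)
    c, s = np.cos(theta), np.sin(theta)
    cs, ss = math.cos(theta_s), math.sin(theta_s)
    rot = 1.0 - (c * cs + s * ss)

    n_coupling = coupling_n if coupling_n is not None else n
    k_over_n = params.k / n_coupling
    coef = _noise_coef(params)
    indptr, indices, data = _csc_arrays(network.weights)
    rng = np.random.default_rng(seed)

    n_steps = params.n_steps
    raw = np.empty((n_steps + 1, n), dtype=np.float32)
    raw[0] = rot > 1.0
    pos = 0
    while pos < n_steps:
        m = min(chunk_steps, n_steps - pos)
        z = rng.standard_normal((m, n)) if params.sigma > 0 else np.zeros((m, n))
        _indicator_chunk(
            theta, c, s, rot, indptr, indices, data, params.i0, k_over_n,
            coef, params.dt, cs, ss, z, raw[pos + 1 :],
        )
        pos += m
    if not np.all(np.isfinite(theta)):
        raise FloatingPointError("trajectory diverged (non-finite phases)")
    return _score_indicator(raw.T, params)


def _score_indicator(raw: np.ndarray, params: ModelParams) -> SeizureTimes:
    """Smooth the raw (N, T+1) indicator and sum scored seizure time."""
    n_scored = raw.shape[1] - 1 - params.burn_in
    if n_scored <= 0:
        raise ValueError("no samples left after burn-in")
    window = max(1, int(round(params.seizure_window / params.dt)))
    smooth = uniform_filter1d(raw, size=window, axis=1, mode="nearest") if window > 1 else raw
    seizing = smooth >= params.seizure_threshold
    t_sz = seizing[:, params.burn_in + 1 :].sum(axis=1) * params.dt
    return SeizureTimes(t_sz=t_sz, t_scored=n_scored * params.dt)


def _csc_arrays(weights: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-target-node neighbor lists (a_ji: column i lists its drivers j)."""
    n = weights.shape[0]
    indptr = np.zeros(n + 1, dtype=np.int64)
    cols = []
    vals = []
    for i in range(n):
        j = np.nonzero(weights[:, i])[0]
        cols.append(j)
        vals.append(weights[j, i])
        indptr[i + 1] = indptr[i] + j.size
    indices = np.concatenate(cols) if cols else np.empty(0, dtype=np.int64)
    data = np.concatenate(vals) if vals else np.empty(0)
    return indptr, indices.astype(np.int64), data.astype(float)


def _noise_coef(params: ModelParams) -> float:
    if params.noise_scaling == "sqrt_dt":
        return params.sigma * math.sqrt(params.dt)
    return params.sigma * params.dt


def simulate(
    network: WeightedNetwork,
    params: ModelParams,
    seed: int | None = None,
    *,
    theta0: np.ndarray | float | None = None,
    noise: np.ndarray | None = None,
    coupling_n: int | None = None,
    chunk_steps: int = 50_000,
) -> PhaseTrajectories:
    """Integrate the stochastic theta-model on ``network``.

    All nodes share the excitability ``params.i0`` and start at the resting
    phase theta_s unless ``theta0`` is given. ``noise`` may supply the full
    (n_steps, N) matrix of standard-normal increments explicitly (used e.g.
    to check permutation equivariance); otherwise increments are drawn from
    ``default_rng(seed)`` in chunks, which yields the identical stream.

    ``coupling_n`` overrides the N in the K/N coupling normalization (the
    node-removal analysis can hold it at the original network size).
    """
    n = network.n
    if params.i0 <= 0:
        theta_s = stable_phase(params.i0)
    else:
        if params.k != 0 and np.any(network.weights != 0):
            raise NoFixedPointError(
                "i0 > 0 has no resting phase; coupled simulations require i0 <= 0"
            )
        theta_s = 0.0  # unused: coupling term is identically zero

    if theta0 is None:
        if params.i0 > 0:
            raise NoFixedPointError(
                "i0 > 0: supply theta0 explicitly (no resting initial condition)"
            )
        theta = np.full(n, theta_s)
    else:
        theta = np.broadcast_to(np.asarray(theta0, dtype=float), (n,)).copy()

    n_steps = params.n_steps
    if noise is not None:
        noise = np.ascontiguousarray(noise, dtype=float)
        if noise.shape != (n_steps, n):
            raise ValueError(f"noise must have shape {(n_steps, n)}, got {noise.shape}")
    rng = np.random.default_rng(seed)

    n_coupling = coupling_n if coupling_n is not None else n
    k_over_n = params.k / n_coupling
    coef = _noise_coef(params)
    indptr, indices, data = _csc_arrays(network.weights)

    out = np.empty((n_steps + 1, n))
    out[0] = theta
    pos = 0
    while pos < n_steps:
        m = min(chunk_steps, n_steps - pos)
        if noise is None:
            z = rng.standard_normal((m, n)) if params.sigma > 0 else np.zeros((m, n))
        else:
            z = noise[pos : pos + m]
        _euler_chunk(
            theta, indptr, indices, data, params.i0, k_over_n, coef,
            params.dt, theta_s, z, out[pos + 1 :],
        )
        pos += m

    if not np.all(np.isfinite(out)):
        raise FloatingPointError("trajectory diverged (non-finite phases)")
    return PhaseTrajectories(out.T, params, seed)


def rotation_indicator(phases: np.ndarray, theta_s: float) -> np.ndarray:
    """Raw per-step seizure indicator: phase more than pi/2 from rest.

    True where 1 - cos(theta - theta_s) > 1, i.e. the oscillator is on the
    far side of the circle from the resting phase.
    """
    return (1.0 - np.cos(phases - theta_s)) > 1.0


def classify_seizure(traj: PhaseTrajectories, params: ModelParams | None = None) -> SeizureTimes:
    """Score per-node time in the rotating state.

    The raw indicator is smoothed with a centered moving average over
    ``seizure_window`` time units and thresholded at ``seizure_threshold``,
    so brief noise excursions are not scored while sustained rotations are.
    The first ``burn_in`` steps are discarded.
    """
    params = params if params is not None else traj.params
    phases = traj.phases
    if not np.all(np.isfinite(phases)):
        raise ValueError("trajectory contains non-finite phases")
    if params.i0 > 0:
        # supra-threshold: the resting fixed point no longer exists, so the
        # node is in the rotating regime at every sample
        raw = np.ones(phases.shape, dtype=np.float32)
    else:
        raw = rotation_indicator(phases, stable_phase(params.i0)).astype(np.float32)
    return _score_indicator(raw, params)


def seizure_fraction(times: SeizureTimes) -> float:
    """Average proportion of scored time spent in seizures,
    P_sz = (1/N) * sum_i t_sz[i] / T_scored, in [0, 1]."""
    if times.t_scored <= 0:
        raise ValueError("t_scored must be positive")
    frac = float(np.mean(times.t_sz) / times.t_scored)
    if not -1e-9 <= frac <= 1 + 1e-9:
        warnings.warn(f"seizure fraction {frac} outside [0, 1]")
    return min(max(frac, 0.0), 1.0)
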