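"""Synthetic networks, theta-band ROI signals, and two-group cohorts.

The study's EEG is not publicly deposited, so this module generates data with
the statistical structure the analysis assumes: planted coupling graphs,
multichannel oscillatory signals in the 4-8 Hz band whose pairwise phase
locking follows the planted graph (with a nonzero imposed phase lag so
genuine edges survive zero-lag rejection), and two-group cohorts in which
group b's edge weights are scaled by a factor gamma, planting higher
network-level seizure propensity for gamma > 1 (total coupling input is
monotone in edge mass, which lowers the noise-driven escape threshold).

The planted group effect is a device for testing the pipeline end to end; it
is explicitly not a claim about what differs in real AD functional networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._rng import derive_seed
from .model import WeightedNetwork
from .networks import ROITimeSeriesSet

__all__ = [
    "CohortSpec",
    "GroupDataset",
    "make_topology",
    "simulate_roi_signals",
    "make_group_dataset",
]


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort specification.

    Group sizes default to 26 vs 21 (control-sized vs patient-sized groups);
    ``effect`` is the multiplicative edge-weight scaling applied to group b.
    """

    n_group_a: int = 26
    n_group_b: int = 21
    n_rois: int = 40
    effect: float = 1.3
    topology: str = "uniform-random"
    base_weight: float = 0.5
    density: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group_a < 1 or self.n_group_b < 1:
            raise ValueError("group sizes must be >= 1")
        if not (0 < self.density <= 1):
            raise ValueError("density must be in (0, 1]")
        if self.effect < 0:
            raise ValueError("effect scaling must be >= 0")


@dataclass(frozen=True)
class GroupDataset:
    networks: tuple[WeightedNetwork, ...]
    labels: tuple[str, ...]
    spec: CohortSpec
    subject_seeds: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.networks) != len(self.labels):
            raise ValueError("label count must match network count")

    def group(self, tag: str) -> list[WeightedNetwork]:
        return [n for n, g in zip(self.networks, self.labels) if g == tag]


def make_topology(
    n: int,
    family: str = "uniform-random",
    *,
    base_weight: float = 0.5,
    density: float = 0.3,
    within_density: float = 0.8,
    between_density: float = 0.05,
    n_modules: int = 2,
    weights: np.ndarray | None = None,
    seed: int | None = None,
) -> WeightedNetwork:
    """Symmetric zero-diagonal weighted graph of one of several families.

    ``uniform-random``: Bernoulli(density) edges with weights uniform in
    [base_weight/2, min(1, 3*base_weight/2)]. ``modular``: dense within
    ``n_modules`` equal blocks, sparse between. ``star``: hub node 0 linked
    to every leaf at ``base_weight``, no leaf-leaf edges. ``custom``: use
    the supplied matrix.
    """
    if n < 2:
        raise ValueError("topology needs at least 2 nodes")
    rng = np.random.default_rng(seed)
    w = np.zeros((n, n))

    def _draw(mask: np.ndarray) -> None:
        lo, hi = base_weight / 2.0, min(1.0, 1.5 * base_weight)
        vals = rng.uniform(lo, hi, size=mask.shape)
        w[mask] = vals[mask]

    iu = np.triu_indices(n, k=1)
    if family == "uniform-random":
        mask = np.zeros((n, n), dtype=bool)
        mask[iu] = rng.random(len(iu[0])) < density
        _draw(mask)
    elif family == "modular":
        module = np.arange(n) % n_modules
        same = module[:, None] == module[None, :]
        p = np.where(same, within_density, between_density)
        mask = np.zeros((n, n), dtype=bool)
        mask[iu] = rng.random(len(iu[0])) < p[iu]
        _draw(mask)
    elif family == "star":
        w[0, 1:] = base_weight
    elif family == "custom":
        if weights is None:
            raise ValueError("family 'custom' requires a weights matrix")
        return WeightedNetwork(np.asarray(weights, dtype=float))
    else:
        raise ValueError(f"unknown topology family {family!r}")

    w = np.maximum(w, w.T)
    np.fill_diagonal(w, 0.0)
    return WeightedNetwork(np.clip(w, 0.0, 1.0))


def simulate_roi_signals(
    net: WeightedNetwork,
    fs: float = 1000.0,
    duration: float = 20.0,
    osc_freq: float = 6.0,
    freq_jitter: float = 0.5,
    coupling: float = 5.0,
    phase_noise: float = 2.5,
    measurement_noise: float = 0.2,
    lag_range: tuple[float, float] = (0.02 * np.pi, 0.1 * np.pi),
    seed: int | None = None,
) -> ROITimeSeriesSet:
    """Coupled noisy phase oscillators observed as amplitude * cos(phase).

    Natural frequencies are uniform in ``osc_freq +- freq_jitter`` (inside
    the 4-8 Hz theta band by default). Pairwise interactions follow a
    Sakaguchi-Kuramoto rule with strength ``coupling * weight`` (rad/s) and
    an antisymmetric per-edge phase lag drawn from ``lag_range``, so locked
    pairs settle at a nonzero mean phase difference and survive zero-lag
    rejection. ``phase_noise`` is the phase diffusion (rad/sqrt(s));
    ``measurement_noise`` is white observation noise (signal amplitude 1).
    """
    n = net.n
    n_samples = int(round(fs * duration))
    if n_samples < 16:
        raise ValueError("duration * fs too short for downstream analysis")
    rng = np.random.default_rng(seed)

    freqs = osc_freq + rng.uniform(-freq_jitter, freq_jitter, n)
    omega = 2.0 * np.pi * freqs

    # antisymmetric lag matrix: locked pairs sit at phase difference alpha_ij
    lag_mag = rng.uniform(lag_range[0], lag_range[1], (n, n))
    alpha = np.triu(lag_mag, k=1)
    alpha = alpha - alpha.T
    cmat = net.weights * np.exp(1j * alpha)  # row i: drive on oscillator i

    dt = 1.0 / fs
    sq = np.sqrt(dt)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    noise = rng.standard_normal((n_samples, n))
    phases = np.empty((n, n_samples))
    for t in range(n_samples):
        z = np.exp(1j * phi)
        pull = np.imag(np.conj(z) * (cmat @ z))  # sum_j w_ij sin(phi_j - phi_i + a_ij)
        phi = phi + dt * (omega + coupling * pull) + phase_noise * sq * noise[t]
        phases[:, t] = phi

    data = np.cos(phases) + measurement_noise * rng.standard_normal((n, n_samples))
    return ROITimeSeriesSet(data, fs, net.labels)


def make_group_dataset(spec: CohortSpec) -> GroupDataset:
    """Two-group cohort of planted networks.

    Group a subjects are drawn from the base topology distribution; group b
    subjects are drawn the same way and then have all edge weights scaled by
    ``spec.effect`` (clipped to [0, 1] with a warning if the scaling
    saturates any weight). Per-subject seeds are derived from ``spec.seed``
    and recorded, so regeneration is bit-identical.
    """
    networks: list[WeightedNetwork] = []
    labels: list[str] = []
    seeds: list[int] = []
    clipped = False
    n_total = spec.n_group_a + spec.n_group_b
    for subj in range(n_total):
        s = derive_seed(spec.seed, "subject", subj)
        net = make_topology(
            spec.n_rois,
            spec.topology,
            base_weight=spec.base_weight,
            density=spec.density,
            seed=s,
        )
        group = "a" if subj < spec.n_group_a else "b"
        if group == "b" and spec.effect != 1.0:
            w = net.weights * spec.effect
            if np.any(w > 1.0):
                clipped = True
                w = np.clip(w, 0.0, 1.0)
            net = WeightedNetwork(w, net.labels)
        networks.append(net)
        labels.append(group)
        seeds.append(s)
    if clipped:
        warnings.warn("effect scaling pushed some weights above 1; clipped")
    return GroupDataset(tuple(networks), tuple(labels), spec, tuple(seeds))
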