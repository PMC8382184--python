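"""Brain network ictogenicity (BNI) and node ictogenicity (NI).

BNI summarizes how readily a network transitions into seizures as cortical
excitability is raised: P_sz (the average proportion of time the simulated
dynamics spend in the rotating/seizure state) is computed on a grid of
excitability values I0 in [lambda1, lambda2] and integrated,

    BNI = integral_{lambda1}^{lambda2} P_sz(lambda) dlambda.

NI quantifies each node's contribution by virtual resection: remove the node
and all its connections, recompute BNI, and report the relative drop

    NI_i = (BNI_pre - BNI_post_i) / BNI_pre,

so NI = 1 means the node was entirely responsible for simulated seizures and
NI < 0 means removing it makes the network *more* ictogenic. nNI rescales NI
to unit sum within a subject so spatial profiles are comparable across
subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._rng import derive_seed
from .model import ModelParams, WeightedNetwork, seizure_fraction, seizure_times

__all__ = [
    "BNIGrid",
    "PszCurve",
    "BNIResult",
    "NIProfile",
    "psz_curve",
    "bni_from_curve",
    "bni",
    "node_ictogenicity",
    "normalise_ni",
]


@dataclass(frozen=True)
class BNIGrid:
    """Excitability grid for the BNI integral.

    Defaults cover [-1.7, -0.5] at step 0.1 (13 points); the range is chosen
    so P_sz sweeps from ~0 to ~1 for the networks being compared, and must be
    identical (together with K) across subjects for BNI to be comparable.
    """

    lambda1: float = -1.7
    lambda2: float = -0.5
    n_points: int = 13

    def __post_init__(self) -> None:
        if not self.lambda1 < self.lambda2:
            raise ValueError("need lambda1 < lambda2")
        if self.n_points < 2:
            raise ValueError("grid needs at least 2 points")

    @property
    def points(self) -> np.ndarray:
        return np.linspace(self.lambda1, self.lambda2, self.n_points)

    @property
    def width(self) -> float:
        return self.lambda2 - self.lambda1


@dataclass(frozen=True)
class PszCurve:
    grid: BNIGrid
    values: np.ndarray
    seeds: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.grid.n_points,):
            raise ValueError("values length must match grid")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class BNIResult:
    """Area under the P_sz curve (``bni``) and its range-normalized variant."""

    bni: float
    normalized: float
    curve: PszCurve | None = None


@dataclass(frozen=True)
class NIProfile:
    """Node-removal ictogenicity profile for one network."""

    bni_pre: BNIResult
    bni_post: tuple[BNIResult, ...]
    ni: np.ndarray
    nni: np.ndarray | None
    labels: tuple[str, ...] = ()


def _point_seeds(master: int | None, n: int) -> list[int | None]:
    if master is None:
        return [None] * n
    return [derive_seed(master, "psz", k) for k in range(n)]


def psz_curve(
    network: WeightedNetwork,
    grid: BNIGrid,
    params: ModelParams,
    seed: int | None = None,
    *,
    coupling_n: int | None = None,
) -> PszCurve:
    """P_sz at each grid excitability; one simulation per grid point.

    Per-point seeds are derived deterministically from ``seed`` so the same
    master seed always reproduces the same curve, and so node-removal runs
    can share noise realizations with the intact-network run.
    """
    seeds = _point_seeds(seed, grid.n_points)
    values = np.empty(grid.n_points)
    for k, (i0, s) in enumerate(zip(grid.points, seeds)):
        p = params.with_i0(float(i0))
        values[k] = seizure_fraction(seizure_times(network, p, s, coupling_n=coupling_n))
    return PszCurve(grid, values, tuple(s if s is not None else -1 for s in seeds))


def bni_from_curve(curve: PszCurve) -> BNIResult:
    """Trapezoidal quadrature of P_sz over [lambda1, lambda2]."""
    area = float(np.trapezoid(curve.values, curve.grid.points))
    return BNIResult(bni=area, normalized=area / curve.grid.width, curve=curve)


def bni(
    network: WeightedNetwork,
    grid: BNIGrid,
    params: ModelParams,
    seed: int | None = None,
    *,
    coupling_n: int | None = None,
) -> BNIResult:
    """Convenience: simulate the P_sz curve and integrate it."""
    return bni_from_curve(psz_curve(network, grid, params, seed, coupling_n=coupling_n))


def normalise_ni(ni: np.ndarray) -> np.ndarray:
    """nNI_i = NI_i / sum_j NI_j; sums to 1 exactly (zero total is an error)."""
    ni = np.asarray(ni, dtype=float)
    total = ni.sum()
    if total == 0:
        raise ValueError("NI values sum to zero; nNI undefined")
    return ni / total


def node_ictogenicity(
    network: WeightedNetwork,
    grid: BNIGrid,
    params: ModelParams,
    seed: int | None = None,
    *,
    coupling_n_mode: str = "current",
) -> NIProfile:
    """NI and nNI by removing each node in turn and recomputing BNI.

    The same per-grid-point seeds are reused for the intact network and every
    reduced network (common random numbers), so node-removal differences are
    not swamped by noise-realization variance. ``coupling_n_mode`` selects
    the N in the K/N coupling term after removal: ``"current"`` (the reduced
    network's size, the literal model definition) or ``"original"``.
    """
    if network.n < 2:
        raise ValueError("node ictogenicity needs at least 2 nodes")
    if coupling_n_mode not in ("current", "original"):
        raise ValueError(f"unknown coupling_n_mode {coupling_n_mode!r}")

    pre = bni(network, grid, params, seed)
    if pre.bni <= 0:
        raise ValueError(
            "BNI of the intact network is zero: NI undefined "
            "(network never seizes on this grid)"
        )
    posts = []
    ni = np.empty(network.n)
    for i in range(network.n):
        reduced = network.remove_node(i)
        cn = network.n if coupling_n_mode == "original" else None
        post = bni(reduced, grid, params, seed, coupling_n=cn)
        posts.append(post)
        ni[i] = (pre.bni - post.bni) / pre.bni

    nni: np.ndarray | None
    if ni.sum() == 0:
        warnings.warn("NI values sum to zero; nNI undefined for this network")
        nni = None
    else:
        nni = normalise_ni(ni)
    return NIProfile(pre, tuple(posts), ni, nni, network.labels)
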